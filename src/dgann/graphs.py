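"""Residue-level contact graphs over whole docking models.

Nodes are all residues of the model; an undirected edge joins two residues
whenever any inter-atomic distance is strictly below the edge cutoff
(default 5 A). The interface mask marks residues with any atom within the
(same, by default) cutoff of the opposite partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structure import LIGAND, RECEPTOR, Structure

__all__ = ["ResidueGraph", "build_graph", "interface_mask", "save_graph", "load_graph"]

EDGE_CUTOFF = 5.0
N_FEATURES = 26
FORMAT_VERSION = 1


@dataclass
class ResidueGraph:
    """Contact graph with 26-D node features and an interface mask."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int, i < j, deduplicated
    interface_mask: np.ndarray  # (n,) bool
    partition_tag: np.ndarray  # (n,) str, receptor|ligand
    node_features: np.ndarray | None = None  # (n, 26) float
    label: str = "unlabeled"  # positive | negative | unlabeled
    target_id: str = ""
    model_id: str = ""
    aa: tuple[str, ...] = field(default_factory=tuple)
    chain_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size and (
            np.any(self.edges[:, 0] == self.edges[:, 1])
            or np.any(self.edges >= self.n_nodes)
        ):
            raise ValueError("edges must be valid non-self node pairs")
        if self.node_features is not None:
            feats = np.asarray(self.node_features, dtype=float)
            if feats.shape != (self.n_nodes, N_FEATURES):
                raise ValueError(
                    f"node_features must be ({self.n_nodes}, {N_FEATURES})"
                )
            self.node_features = feats

    def neighbors(self) -> list[np.ndarray]:
        """Adjacency lists (no self-loops; those are the model's concern)."""
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [np.asarray(sorted(a), dtype=int) for a in adj]

    def with_features(self, features: np.ndarray) -> "ResidueGraph":
        return replace(self, node_features=np.asarray(features, dtype=float))

    def with_label(self, label: str) -> "ResidueGraph":
        if label not in ("positive", "negative", "unlabeled"):
            raise ValueError(f"bad label {label!r}")
        return replace(self, label=label)


def _residue_atom_coords(s: Structure):
    coords, owner = [], []
    for i, res in enumerate(s.residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            owner.append(i)
    return np.asarray(coords), np.asarray(owner, dtype=int)


def build_graph(s: Structure, edge_cutoff: float = EDGE_CUTOFF) -> ResidueGraph:
    """Contact graph of the whole model (intra- and inter-partition edges).

    Neighbor search uses a KD-tree over all atoms; the strict ``< cutoff``
    rule matches the brute-force all-pairs definition exactly.
    """
    if edge_cutoff <= 0:
        raise ValueError("edge_cutoff must be positive")
    coords, owner = _residue_atom_coords(s)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=edge_cutoff, output_type="ndarray")
    edge_set = set()
    for a, b in pairs:
        # query_pairs is closed (<= r); enforce the strict inequality
        if owner[a] != owner[b] and np.linalg.norm(coords[a] - coords[b]) < edge_cutoff:
            i, j = sorted((int(owner[a]), int(owner[b])))
            edge_set.add((i, j))
    edges = np.asarray(sorted(edge_set), dtype=int).reshape(-1, 2)

    tags = s.residue_partition()
    mask = interface_mask(s, cutoff=edge_cutoff)
    return ResidueGraph(
        n_nodes=len(s.residues),
        edges=edges,
        interface_mask=mask,
        partition_tag=tags,
        target_id=s.target_id,
        model_id=s.model_id,
        aa=tuple(r.aa for r in s.residues),
        chain_ids=tuple(r.chain_id for r in s.residues),
    )


def interface_mask(s: Structure, cutoff: float = EDGE_CUTOFF) -> np.ndarray:
    """True where a residue has any atom strictly within cutoff of the
    opposite partition."""
    tags = s.residue_partition()
    coords, owner = _residue_atom_coords(s)
    atom_role = tags[owner]
    rec_idx = np.flatnonzero(atom_role == RECEPTOR)
    lig_idx = np.flatnonzero(atom_role == LIGAND)
    mask = np.zeros(len(s.residues), dtype=bool)
    if rec_idx.size == 0 or lig_idx.size == 0:
        return mask
    hits = cKDTree(coords[rec_idx]).query_ball_tree(
        cKDTree(coords[lig_idx]), r=cutoff
    )
    for ai, js in enumerate(hits):
        for bj in js:
            a, b = rec_idx[ai], lig_idx[bj]
            if np.linalg.norm(coords[a] - coords[b]) < cutoff:
                mask[owner[a]] = True
                mask[owner[b]] = True
    return mask


def save_graph(g: ResidueGraph, path) -> None:
    """Serialize to the versioned JSON container (lossless round-trip)."""
    payload = {
        "format_version": FORMAT_VERSION,
        "target_id": g.target_id,
        "model_id": g.model_id,
        "n_nodes": g.n_nodes,
        "edges": g.edges.tolist(),
        "interface_mask": g.interface_mask.astype(int).tolist(),
        "partition_tag": list(g.partition_tag),
        "label": g.label,
        "aa": list(g.aa),
        "chain_ids": list(g.chain_ids),
        "node_features": None
        if g.node_features is None
        else g.node_features.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_graph(path) -> ResidueGraph:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported graph format {payload.get('format_version')}")
    feats = payload["node_features"]
    return ResidueGraph(
        n_nodes=payload["n_nodes"],
        edges=np.asarray(payload["edges"], dtype=int).reshape(-1, 2),
        interface_mask=np.asarray(payload["interface_mask"], dtype=bool),
        partition_tag=np.asarray(payload["partition_tag"]),
        node_features=None if feats is None else np.asarray(feats, dtype=float),
        label=payload["label"],
        target_id=payload["target_id"],
        model_id=payload["model_id"],
        aa=tuple(payload["aa"]),
        chain_ids=tuple(payload["chain_ids"]),
    )
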