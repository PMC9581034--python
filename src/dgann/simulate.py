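"""Synthetic native complexes and rigid-body decoys with known ground truth.

Natives are pairs of idealised helical pseudo-peptides (N/CA/C atoms at
3.8 A CA spacing) docked side by side with a guaranteed number of
cross-chain contacts. Decoys move the ligand chain by a sampled rigid
transform: small motions stay near-native, large ones are incorrect, and
the applied transform is recorded so the ligand RMSD of a pure translation
is analytically checkable.

An optional planted feature signal (an additive shift on chosen feature
columns of interface residues of positive decoys) makes the classes
separable for learnability tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .structure import Atom, Residue, Structure, assign_partition
from .quality import evaluate_decoy

__all__ = ["SimConfig", "make_native", "make_decoys", "apply_rigid",
           "plant_signal", "simulate_target", "AA20"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# helix geometry: ~100 deg twist and 1.5 A rise per residue, 2.3 A radius
_TWIST = np.deg2rad(100.0)
_RISE = 1.5
_RADIUS = 2.3
_N_OFFSET = np.array([-0.5, 0.4, -0.3])
_C_OFFSET = np.array([0.5, -0.4, 0.3])


@dataclass(frozen=True)
class SimConfig:
    n_targets: int = 5
    receptor_len: int = 40
    ligand_len: int = 25
    decoys_per_target: int = 200
    positive_fraction: float = 0.05
    pos_trans_max: float = 1.0
    pos_rot_max_deg: float = 3.0
    neg_trans_range: tuple[float, float] = (15.0, 60.0)
    neg_rot_max_deg: float = 180.0
    signal_strength: float = 0.0
    signal_columns: tuple[int, ...] = (0, 1, 2)
    min_contacts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in [0, 1)")
        if self.receptor_len < 5 or self.ligand_len < 5:
            raise ValueError("need >= 5 residues per chain")
        if self.pos_trans_max < 0 or self.neg_trans_range[0] < 0:
            raise ValueError("displacements must be non-negative")


def _helix(n: int, axis_x: float, phase: float) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack(
        [
            axis_x + _RADIUS * np.cos(_TWIST * t + phase),
            _RADIUS * np.sin(_TWIST * t + phase),
            _RISE * t,
        ]
    )


def _chain(ca: np.ndarray, chain_id: str, aa_seq: str, start_index: int):
    residues = []
    for i, pos in enumerate(ca):
        idx = start_index + i
        atoms = (
            Atom("N", "N", pos + _N_OFFSET, idx),
            Atom("CA", "C", pos, idx),
            Atom("C", "C", pos + _C_OFFSET, idx),
        )
        residues.append(
            Residue(chain_id=chain_id, seq_position=str(i + 1),
                    aa=aa_seq[i], atoms=atoms)
        )
    return residues


def make_native(cfg: SimConfig, target_index: int) -> Structure:
    """A two-chain docked pseudo-complex, deterministic per (seed, index)."""
    rng = np.random.default_rng((cfg.seed, target_index, 0xD0C))
    seq_a = "".join(rng.choice(list(AA20), size=cfg.receptor_len))
    seq_b = "".join(rng.choice(list(AA20), size=cfg.ligand_len))
    ca_a = _helix(cfg.receptor_len, 0.0, 0.0)
    phase_b = float(rng.uniform(0, 2 * np.pi))

    # slide the ligand helix in until enough contacts form without clashes
    for dx in np.arange(12.0, 6.0, -0.1):
        ca_b = _helix(cfg.ligand_len, dx, phase_b)
        zmid = (ca_a[:, 2].mean() - ca_b[:, 2].mean())
        ca_b = ca_b + np.array([0.0, 0.0, zmid])
        d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=-1)
        if d.min() < 3.5:
            ca_b = _helix(cfg.ligand_len, dx + 0.1, phase_b) + np.array(
                [0.0, 0.0, zmid]
            )
            break
        if (d < 4.5).sum() >= cfg.min_contacts:
            break

    jitter = rng.normal(scale=0.03, size=(cfg.receptor_len + cfg.ligand_len, 3))
    ca_a = ca_a + jitter[: cfg.receptor_len]
    ca_b = ca_b + jitter[cfg.receptor_len :]

    residues = _chain(ca_a, "A", seq_a, 0) + _chain(
        ca_b, "B", seq_b, cfg.receptor_len
    )
    s = Structure(
        target_id=f"T{target_index:03d}",
        model_id="native",
        chains=("A", "B"),
        residues=tuple(residues),
    )
    return assign_partition(s, receptor_chains=["A"])


def apply_rigid(native: Structure, rotation: np.ndarray, translation: np.ndarray,
                model_id: str) -> Structure:
    """Move the ligand partition rigidly (rotation about its centroid)."""
    lig_chains = set(native.partition_chains("ligand"))
    lig_coords = np.concatenate(
        [r.coords() for r in native.residues if r.chain_id in lig_chains]
    )
    centroid = lig_coords.mean(axis=0)
    new_residues = []
    for res in native.residues:
        if res.chain_id in lig_chains:
            atoms = tuple(
                replace(
                    a,
                    coord=rotation @ (a.coord - centroid) + centroid + translation,
                )
                for a in res.atoms
            )
            new_residues.append(replace(res, atoms=atoms))
        else:
            new_residues.append(res)
    return replace(native, residues=tuple(new_residues), model_id=model_id)


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0, max_deg))
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def make_decoys(native: Structure, cfg: SimConfig):
    """Rigid-body decoys; returns [(decoy, rotation, translation), ...]."""
    tkey = zlib.crc32(native.target_id.encode())  # stable across processes
    rng = np.random.default_rng((cfg.seed, tkey, 0xDEC))
    out = []
    for d in range(cfg.decoys_per_target):
        near = rng.random() < cfg.positive_fraction
        if near:
            rot = _random_rotation(rng, cfg.pos_rot_max_deg)
            mag = rng.uniform(0, cfg.pos_trans_max)
        else:
            rot = _random_rotation(rng, cfg.neg_rot_max_deg)
            mag = rng.uniform(*cfg.neg_trans_range)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        trans = mag * direction
        decoy = apply_rigid(native, rot, trans, model_id=f"decoy_{d:04d}")
        out.append((decoy, rot, trans))
    return out


def simulate_target(cfg: SimConfig, target_index: int):
    """Native + labeled decoys for one target.

    Returns (native, [(decoy, metrics, rotation, translation), ...]).
    """
    native = make_native(cfg, target_index)
    labeled = []
    for decoy, rot, trans in make_decoys(native, cfg):
        metrics = evaluate_decoy(native, decoy)
        labeled.append((decoy, metrics, rot, trans))
    return native, labeled


def plant_signal(graphs, sigma: float, columns=None, seed: int = 0):
    """Shift the given feature columns of interface nodes on positive graphs.

    Negative and unlabeled graphs pass through untouched; sigma = 0 is the
    identity. Returns new graph objects; inputs are not mutated.
    """
    columns = list(columns if columns is not None else (0, 1, 2))
    out = []
    for g in graphs:
        if g.label != "positive" or sigma == 0.0:
            out.append(g)
            continue
        if g.node_features is None:
            raise ValueError("plant_signal requires featurized graphs")
        feats = g.node_features.copy()
        feats[np.ix_(np.flatnonzero(g.interface_mask), columns)] += sigma
        out.append(g.with_features(feats))
    return out
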