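"""CAPRI-derived decoy quality metrics and the binary near-native label.

A decoy is *incorrect* (negative) iff ``fnat < 0.1`` or
(``lRMSD > 10.0`` and ``iRMSD > 4.0``); every other decoy is a positive,
near-native sample. Thresholds are strict inequalities, so boundary values
are positive.

Contact cutoff for fnat defaults to 5.0 A (heavy-atom, same as the graph
edge threshold); the iRMSD interface is defined at 10.0 A. Both are
configurable. RMSDs use N/CA/C/O backbone atoms when present, with a
CA-only fallback for sparse models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import LIGAND, RECEPTOR, Structure

__all__ = [
    "QualityMetrics",
    "ContactSet",
    "SequenceInconsistencyError",
    "native_contacts",
    "fnat",
    "kabsch_superpose",
    "lrmsd",
    "irmsd",
    "classify",
    "evaluate_decoy",
]

FNAT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0
BACKBONE_ATOMS = ("N", "CA", "C", "O")

FNAT_INCORRECT = 0.1
LRMSD_INCORRECT = 10.0
IRMSD_INCORRECT = 4.0


class SequenceInconsistencyError(ValueError):
    """Decoy residues cannot be mapped 1:1 onto the native numbering."""


@dataclass(frozen=True)
class QualityMetrics:
    fnat: float
    irmsd: float
    lrmsd: float
    label: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        for v in (self.fnat, self.irmsd, self.lrmsd):
            if not np.isfinite(v):
                raise ValueError("quality metrics must be finite")


@dataclass(frozen=True)
class ContactSet:
    """Cross-partition residue contacts: (receptor ordinal, ligand ordinal)."""

    pairs: frozenset


def _heavy_coords(structure: Structure, residue_indices):
    coords, owner = [], []
    for i in residue_indices:
        for atom in structure.residues[i].atoms:
            coords.append(atom.coord)
            owner.append(i)
    return np.asarray(coords), np.asarray(owner)


def _role_indices(s: Structure, role: str):
    tags = s.residue_partition()
    return np.flatnonzero(tags == role)


def _contacts(s: Structure, cutoff: float) -> frozenset:
    rec = _role_indices(s, RECEPTOR)
    lig = _role_indices(s, LIGAND)
    if rec.size == 0 or lig.size == 0:
        raise ValueError("both partitions must be non-empty")
    rc, ro = _heavy_coords(s, rec)
    lc, lo = _heavy_coords(s, lig)
    pairs = cKDTree(rc).query_ball_tree(cKDTree(lc), r=cutoff)
    out = set()
    for ai, hits in enumerate(pairs):
        for bj in hits:
            # query_ball_tree is closed (<= r); the contact rule is strict <
            if np.linalg.norm(rc[ai] - lc[bj]) < cutoff:
                out.add((int(ro[ai]), int(lo[bj])))
    return frozenset(out)


def native_contacts(native: Structure, cutoff: float = FNAT_CUTOFF) -> ContactSet:
    """Residue pairs across the interface with any atom-atom distance < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return ContactSet(pairs=_contacts(native, cutoff))


def _residue_map(native: Structure, decoy: Structure) -> dict[int, int]:
    """native ordinal -> decoy ordinal, by (chain, seq_position); strict."""
    decoy_by_key = {r.key: i for i, r in enumerate(decoy.residues)}
    if len(decoy_by_key) != len(decoy.residues):
        raise SequenceInconsistencyError("duplicate residue keys in decoy")
    mapping = {}
    for i, res in enumerate(native.residues):
        j = decoy_by_key.get(res.key)
        if j is None or decoy.residues[j].aa != res.aa:
            raise SequenceInconsistencyError(
                f"sequence inconsistency at {res.chain_id}{res.seq_position}"
            )
        mapping[i] = j
    return mapping


def fnat(native: Structure, decoy: Structure, cutoff: float = FNAT_CUTOFF) -> float:
    """Fraction of native cross-partition contacts reproduced in the decoy."""
    mapping = _residue_map(native, decoy)
    ncon = _contacts(native, cutoff)
    if not ncon:
        raise ValueError("native structure has no interface contacts")
    if not decoy.partition:
        decoy = _copy_partition(native, decoy)
    dcon = _contacts(decoy, cutoff)
    kept = sum(1 for (i, j) in ncon if (mapping[i], mapping[j]) in dcon)
    return kept / len(ncon)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise ValueError("need at least 3 points for superposition")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def _backbone_coords(s: Structure, residue_indices) -> np.ndarray:
    """Backbone coordinates with a per-pair consistent atom selection."""
    rows = []
    for i in residue_indices:
        atoms = {a.name: a.coord for a in s.residues[i].atoms}
        rows.append(atoms)
    return rows


def _paired_backbone(native: Structure, decoy: Structure, indices, mapping):
    nat_rows = _backbone_coords(native, indices)
    dec_rows = _backbone_coords(decoy, [mapping[i] for i in indices])
    nat_pts, dec_pts = [], []
    for nat, dec in zip(nat_rows, dec_rows):
        names = [a for a in BACKBONE_ATOMS if a in nat and a in dec]
        if not names and "CA" in nat and "CA" in dec:
            names = ["CA"]
        for name in names:
            nat_pts.append(nat[name])
            dec_pts.append(dec[name])
    if not nat_pts:
        raise ValueError("no shared backbone atoms between native and decoy")
    return np.asarray(nat_pts), np.asarray(dec_pts)


def lrmsd(native: Structure, decoy: Structure) -> float:
    """Backbone RMSD of ligand residues after receptor superposition."""
    mapping = _residue_map(native, decoy)
    rec = _role_indices(native, RECEPTOR)
    lig = _role_indices(native, LIGAND)
    nat_rec, dec_rec = _paired_backbone(native, decoy, rec, mapping)
    rot, trans, _ = kabsch_superpose(dec_rec, nat_rec)
    nat_lig, dec_lig = _paired_backbone(native, decoy, lig, mapping)
    moved = dec_lig @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - nat_lig) ** 2, axis=1))))


def interface_residues(native: Structure, cutoff: float = INTERFACE_CUTOFF):
    """Native residue ordinals with any atom within cutoff of the other side."""
    tags = native.residue_partition()
    rec = np.flatnonzero(tags == RECEPTOR)
    lig = np.flatnonzero(tags == LIGAND)
    rc, ro = _heavy_coords(native, rec)
    lc, lo = _heavy_coords(native, lig)
    hits = cKDTree(rc).query_ball_tree(cKDTree(lc), r=cutoff)
    out = set()
    for ai, js in enumerate(hits):
        for bj in js:
            if np.linalg.norm(rc[ai] - lc[bj]) < cutoff:
                out.add(int(ro[ai]))
                out.add(int(lo[bj]))
    return sorted(out)


def irmsd(
    native: Structure,
    decoy: Structure,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> float:
    """Backbone RMSD of native-defined interface residues after their own
    superposition."""
    mapping = _residue_map(native, decoy)
    iface = interface_residues(native, interface_cutoff)
    if len(iface) < 3:
        raise ValueError(f"only {len(iface)} interface residues (<3)")
    nat_pts, dec_pts = _paired_backbone(native, decoy, iface, mapping)
    _, _, rms = kabsch_superpose(dec_pts, nat_pts)
    return rms


def classify(fnat_value: float, irmsd_value: float, lrmsd_value: float) -> str:
    """Binary near-native label; negatives are the CAPRI 'incorrect' class."""
    incorrect = fnat_value < FNAT_INCORRECT or (
        lrmsd_value > LRMSD_INCORRECT and irmsd_value > IRMSD_INCORRECT
    )
    return "negative" if incorrect else "positive"


def evaluate_decoy(
    native: Structure,
    decoy: Structure,
    contact_cutoff: float = FNAT_CUTOFF,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> QualityMetrics:
    """All three metrics plus the label for one decoy against its native."""
    if not decoy.partition:
        decoy = _copy_partition(native, decoy)
    f = fnat(native, decoy, cutoff=contact_cutoff)
    i = irmsd(native, decoy, interface_cutoff=interface_cutoff)
    l = lrmsd(native, decoy)
    return QualityMetrics(fnat=f, irmsd=i, lrmsd=l, label=classify(f, i, l))


def _copy_partition(native: Structure, decoy: Structure) -> Structure:
    from dataclasses import replace

    return replace(decoy, partition=dict(native.partition))
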