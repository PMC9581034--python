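"""26-D residue node features: 5 physico-chemical factors + 21-D profile.

Column layout (fixed): columns 0-4 are the five multidimensional-scaling
factor scores of the residue type; columns 5-24 are the 20 per-position
profile scores (PSSM log-odds, amino-acid order ARNDCQEGHILKMFPSTWYV);
column 25 is the per-position information content in bits.

Profiles come either from PSI-BLAST ``-out_ascii_pssm`` files or, when no
profile is supplied, from a deterministic single-sequence fallback built on
BLOSUM62 rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from .graphs import N_FEATURES, ResidueGraph
from .structure import Structure

__all__ = [
    "AA_ORDER",
    "PhysChemTable",
    "SequenceProfile",
    "physchem_encode",
    "read_pssm_ascii",
    "compute_ic",
    "fallback_profile",
    "featurize",
]

#: PSSM column order, as printed by PSI-BLAST
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SequenceProfile:
    """Per-position 20 profile scores + 1 information-content score."""

    scores: np.ndarray  # (L, 20)
    ic: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, float)
        ic = np.asarray(self.ic, float)
        if scores.ndim != 2 or scores.shape[1] != 20 or ic.shape != (len(scores),):
            raise ValueError("profile must be (L, 20) scores with (L,) IC")
        if not (np.all(np.isfinite(scores)) and np.all(np.isfinite(ic))):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "ic", ic)

    def __len__(self) -> int:
        return len(self.scores)

    def row(self, position: int) -> np.ndarray:
        return np.concatenate([self.scores[position], [self.ic[position]]])


class PhysChemTable:
    """The packaged 20x5 factor table; UNK maps to the zero vector."""

    def __init__(self, rows: dict[str, np.ndarray]):
        if sorted(rows) != sorted(AA_ORDER):
            raise ValueError("table must cover exactly the 20 standard residues")
        self._rows = {aa: np.asarray(v, float) for aa, v in rows.items()}
        for aa, v in self._rows.items():
            if v.shape != (5,) or not np.all(np.isfinite(v)):
                raise ValueError(f"bad factor row for {aa}")

    def __getitem__(self, aa: str) -> np.ndarray:
        if aa == "UNK":
            return np.zeros(5)
        return self._rows[aa].copy()


def _load_table() -> PhysChemTable:
    rows = {}
    text = resources.files("dgann.data").joinpath("five_factor.csv").read_text()
    for line in text.strip().splitlines()[1:]:
        aa, *vals = line.split(",")
        rows[aa] = np.array([float(v) for v in vals])
    return PhysChemTable(rows)


_TABLE: PhysChemTable | None = None


def physchem_encode(aa: str) -> np.ndarray:
    """Five factor scores for a residue type (zeros for UNK)."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return _TABLE[aa]


def read_pssm_ascii(path, expected_length: int | None = None) -> SequenceProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Uses the 20 log-odds columns; IC is taken from the file's per-position
    information column when present, else computed from the percentage
    columns against a uniform background.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and toks[:20] == list(AA_ORDER):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: not a PSI-BLAST ASCII PSSM (no header row)")

    scores, ic, pct = [], [], []
    for line in lines[header_idx + 1 :]:
        toks = line.split()
        if len(toks) < 22:
            break  # footer (K/lambda block) or blank line
        try:
            int(toks[0])
        except ValueError:
            break
        vals = [float(t) for t in toks[2:]]
        scores.append(vals[:20])
        if len(vals) >= 40:
            pct.append(vals[20:40])
        if len(vals) >= 41:
            ic.append(vals[40])

    if not scores:
        raise ValueError(f"{path}: no PSSM rows parsed")
    scores = np.asarray(scores)
    if len(ic) == len(scores):
        ic_arr = np.asarray(ic)
    elif len(pct) == len(scores):
        probs = np.asarray(pct) / 100.0
        sums = probs.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        probs = probs / sums
        ic_arr = np.array([compute_ic(p) for p in probs])
    else:
        raise ValueError(f"{path}: neither IC nor percentage columns present")
    if expected_length is not None and len(scores) != expected_length:
        raise ValueError(
            f"{path}: profile has {len(scores)} positions, chain has "
            f"{expected_length}"
        )
    return SequenceProfile(scores=scores, ic=ic_arr)


def compute_ic(probabilities, background=None) -> float:
    """Relative entropy (bits) of one position: sum p * log2(p/q)."""
    p = np.asarray(probabilities, float)
    if p.shape != (20,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be a 20-vector summing to 1")
    q = np.full(20, 1 / 20) if background is None else np.asarray(background, float)
    if np.any(q <= 0):
        raise ValueError("background must be strictly positive")
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))


_BLOSUM62 = None


def fallback_profile(sequence: str) -> SequenceProfile:
    """Deterministic pseudo-profile: per position the BLOSUM62 row of the
    observed residue, with IC log2(20) (a single-sequence point mass)."""
    global _BLOSUM62
    if not sequence:
        raise ValueError("empty sequence")
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    point_ic = math.log2(20)
    scores = np.zeros((len(sequence), 20))
    ic = np.zeros(len(sequence))
    for i, aa in enumerate(sequence):
        if aa in AA_ORDER:
            scores[i] = [_BLOSUM62[aa][b] for b in AA_ORDER]
            ic[i] = point_ic
        # UNK/X positions stay all-zero with zero IC
    return SequenceProfile(scores=scores, ic=ic)


def featurize(
    g: ResidueGraph,
    s: Structure,
    profiles: dict[str, SequenceProfile] | None = None,
    allow_fallback: bool = True,
) -> ResidueGraph:
    """Attach the n x 26 feature matrix: 5 factors, 20 profile scores, IC."""
    profiles = dict(profiles or {})
    chain_pos: dict[str, int] = {}
    feats = np.zeros((g.n_nodes, N_FEATURES))
    for i, res in enumerate(s.residues):
        pos = chain_pos.get(res.chain_id, 0)
        chain_pos[res.chain_id] = pos + 1
        profile = profiles.get(res.chain_id)
        if profile is None:
            if not allow_fallback:
                raise ValueError(f"no profile for chain {res.chain_id}")
            profile = fallback_profile(s.chain_sequence(res.chain_id))
            profiles[res.chain_id] = profile
        if len(profile) != sum(1 for r in s.residues if r.chain_id == res.chain_id):
            raise ValueError(
                f"profile length {len(profile)} != chain {res.chain_id} length"
            )
        feats[i, :5] = physchem_encode(res.aa)
        feats[i, 5:] = profile.row(pos)
    return g.with_features(feats)
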