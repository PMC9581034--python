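"""Structural model: PDB reading/writing and receptor/ligand partitioning.

The internal model is deliberately minimal: ordered chains of residues, each
residue an ordered list of atoms with Cartesian coordinates in angstroms.
Parsing is delegated to Biopython; altloc records are resolved to the
highest-occupancy conformer and only the first MODEL of multi-model files is
kept (decoy sets are single-model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1_extended
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "NotAComplexError",
    "read_pdb",
    "write_pdb",
    "assign_partition",
]

#: residue classes for chain partitioning
RECEPTOR = "receptor"
LIGAND = "ligand"

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class NotAComplexError(ValueError):
    """Raised when a coordinate file contains fewer than two chains."""


@dataclass(frozen=True)
class Atom:
    """One atom: label, element, 3-D coordinate and parent residue ordinal."""

    name: str
    element: str
    coord: np.ndarray
    residue_index: int
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name!r}: coord must be 3 finite values")
        object.__setattr__(self, "coord", coord)


@dataclass(frozen=True)
class Residue:
    """One residue: chain, author position (with insertion code), aa, atoms."""

    chain_id: str
    seq_position: str
    aa: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("residue must contain at least one atom")
        if self.aa != "UNK" and self.aa not in _STANDARD_AA:
            raise ValueError(f"unknown residue code {self.aa!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.seq_position)

    def coords(self) -> np.ndarray:
        return np.stack([a.coord for a in self.atoms])


@dataclass(frozen=True)
class Structure:
    """A parsed multi-chain model with a receptor/ligand chain partition."""

    target_id: str
    model_id: str
    chains: tuple[str, ...]
    residues: tuple[Residue, ...]
    partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chains) < 2:
            raise NotAComplexError(
                f"{self.target_id}/{self.model_id}: not a complex "
                f"({len(self.chains)} chain)"
            )
        if self.partition:
            if set(self.partition) != set(self.chains):
                raise ValueError("partition must cover all chains exactly")
            roles = set(self.partition.values())
            if roles != {RECEPTOR, LIGAND}:
                raise ValueError("both receptor and ligand must be non-empty")

    def residue_partition(self) -> np.ndarray:
        """Per-residue role tags ('receptor'/'ligand'), in residue order."""
        if not self.partition:
            raise ValueError("partition not assigned; call assign_partition")
        return np.array([self.partition[r.chain_id] for r in self.residues])

    def partition_chains(self, role: str) -> tuple[str, ...]:
        return tuple(c for c in self.chains if self.partition.get(c) == role)

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(
            ("X" if r.aa == "UNK" else r.aa)
            for r in self.residues
            if r.chain_id == chain_id
        )


def _one_letter(resname: str) -> str:
    code = protein_letters_3to1_extended.get(resname.strip().upper(), "X")
    if len(code) != 1 or code not in _STANDARD_AA:
        return "UNK"
    return code


def read_pdb(path, target_id: str, model_id: str | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure` (partition left unassigned).

    Residues are ordered by (chain, file order); insertion codes are folded
    into ``seq_position``; altlocs resolve to the highest-occupancy atom;
    hydrogens are kept but flagged. Raises :class:`NotAComplexError` for
    single-chain files and ``ValueError`` (with the offending line) for
    malformed records.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    if model_id is None:
        model_id = _stem(path)
    try:
        bio = parser.get_structure(target_id, str(path))
    except PDBConstructionException as exc:
        raise ValueError(f"{path}: unparseable PDB record ({exc})") from exc
    models = list(bio.get_models())
    if not models:
        raise ValueError(f"{path}: no coordinate model found")
    model = models[0]  # decoys are single-model files

    residues: list[Residue] = []
    chains: list[str] = []
    for chain in model:
        chain_added = False
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag != " " and _one_letter(res.get_resname()) == "UNK":
                continue  # waters, ions, ligands — not graph nodes
            atoms = []
            for atom in res.get_atoms():  # DisorderedAtom -> best occupancy
                element = (atom.element or "").strip() or atom.get_name()[:1]
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=element,
                        coord=np.asarray(atom.get_coord(), dtype=float),
                        residue_index=len(residues),
                        is_hydrogen=element.upper() == "H",
                    )
                )
            if not atoms:
                continue
            seq_position = f"{resseq}{icode.strip()}"
            residues.append(
                Residue(
                    chain_id=chain.id,
                    seq_position=seq_position,
                    aa=_one_letter(res.get_resname()),
                    atoms=tuple(atoms),
                )
            )
            chain_added = True
        if chain_added:
            chains.append(chain.id)

    if len(chains) < 2:
        raise NotAComplexError(f"{path}: not a complex ({len(chains)} chain)")
    return Structure(
        target_id=target_id,
        model_id=model_id,
        chains=tuple(chains),
        residues=tuple(residues),
    )


def write_pdb(s: Structure, path) -> None:
    """Write the structure back out as fixed-column ATOM records."""
    with open(path, "w") as fh:
        serial = 1
        for res in s.residues:
            icode = " "
            pos = res.seq_position
            if pos and pos[-1].isalpha():
                icode, pos = pos[-1], pos[:-1]
            resname = _THREE_LETTER.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name
                # PDB column 13-16 convention: 1-char elements start col 14
                aname = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:5d} {aname}{'':1s}{resname:>3s} "
                    f"{res.chain_id:1s}{int(pos):4d}{icode:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def assign_partition(s: Structure, receptor_chains=None) -> Structure:
    """Return a copy of ``s`` with chains assigned to receptor/ligand.

    Without an explicit ``receptor_chains`` list the larger chain group (by
    residue count) becomes the receptor; ties break lexicographically by
    chain id so the assignment is deterministic.
    """
    counts = {c: sum(1 for r in s.residues if r.chain_id == c) for c in s.chains}
    if receptor_chains is not None:
        receptor = set(receptor_chains)
        if not receptor or not receptor < set(s.chains):
            raise ValueError(
                "receptor_chains must be a non-empty proper subset of chains"
            )
    else:
        # largest single chain seeds the receptor; ties by chain id
        best = max(s.chains, key=lambda c: (counts[c], _neg_lex(c)))
        receptor = {best}
    partition = {c: (RECEPTOR if c in receptor else LIGAND) for c in s.chains}
    return replace(s, partition=partition)


def _neg_lex(chain_id: str):
    # max() prefers high values; we want lexicographically *smallest* id
    return tuple(-ord(ch) for ch in chain_id)


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

warnings.filterwarnings("ignore", module="Bio.PDB")
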