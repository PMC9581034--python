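"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately avoid the library code paths they
check: contacts/edges by exhaustive atom-pair loops, superposition by
Horn's quaternion method (vs the SVD route in the package), EF by direct
counting.
"""

from __future__ import annotations

import numpy as np
import pytest

from dgann.structure import Atom, Residue, Structure, assign_partition


# ---------------------------------------------------------------------------
# structure construction helpers


def make_residue(chain, pos, aa, atom_coords, start_index=0, names=None):
    atoms = []
    for i, xyz in enumerate(atom_coords):
        name = names[i] if names else ("CA" if i == 0 else f"C{i}")
        atoms.append(Atom(name=name, element=name[0], coord=np.asarray(xyz, float),
                          residue_index=start_index))
    return Residue(chain_id=chain, seq_position=str(pos), aa=aa, atoms=tuple(atoms))


def make_structure(residue_specs, target_id="toy", model_id="m0",
                   receptor_chains=None):
    """residue_specs: list of (chain, pos, aa, [atom xyz...])."""
    residues = []
    chains = []
    for i, (chain, pos, aa, coords) in enumerate(residue_specs):
        residues.append(make_residue(chain, pos, aa, coords, start_index=i))
        if chain not in chains:
            chains.append(chain)
    s = Structure(target_id=target_id, model_id=model_id,
                  chains=tuple(chains), residues=tuple(residues))
    return assign_partition(s, receptor_chains)


def pdb_line(serial, name, resname, chain, resseq, xyz, altloc=" ", icode=" ",
             occ=1.0, element=None, record="ATOM"):
    element = element or name[0]
    aname = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (f"{record:<6s}{serial:5d} {aname}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def toy_pdb_text():
    """2 chains x 2 residues, 1 atom each."""
    lines = [
        pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0)),
        pdb_line(2, "CA", "GLY", "A", 2, (3.8, 0, 0)),
        pdb_line(3, "CA", "SER", "B", 1, (0, 4, 0)),
        pdb_line(4, "CA", "VAL", "B", 2, (3.8, 4, 0)),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def random_complex():
    """A randomly docked ~30-residue two-chain structure (not simulator)."""
    rng = np.random.default_rng(42)

    def build(seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        specs = []
        for chain, n, offset in (("A", 18, 0.0), ("B", 12, 6.0)):
            base = r.uniform(-5, 5, size=3) + np.array([offset, 0, 0])
            pos = base
            for i in range(n):
                pos = pos + r.normal(scale=2.0, size=3)
                n_atoms = int(r.integers(1, 4))
                coords = pos + r.normal(scale=0.8, size=(n_atoms, 3))
                specs.append((chain, i + 1, "ACDEFGHIKLMNPQRSTVWY"[int(r.integers(20))],
                              coords))
        return make_structure(specs)

    return build


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_contacts(s, cutoff, cross_only=True):
    """Exhaustive O(N^2 M^2) atom-pair scan."""
    tags = s.residue_partition() if cross_only else None
    pairs = set()
    n = len(s.residues)
    for i in range(n):
        for j in range(n):
            if cross_only and not (tags[i] == "receptor" and tags[j] == "ligand"):
                continue
            if not cross_only and j <= i:
                continue
            found = False
            for a in s.residues[i].atoms:
                for b in s.residues[j].atoms:
                    if np.linalg.norm(a.coord - b.coord) < cutoff:
                        found = True
                        break
                if found:
                    break
            if found:
                pairs.add((i, j))
    return pairs


def brute_force_edges(s, cutoff):
    """All residue pairs (i<j) with any atom-pair distance < cutoff."""
    edges = set()
    n = len(s.residues)
    for i in range(n):
        for j in range(i + 1, n):
            if any(
                np.linalg.norm(a.coord - b.coord) < cutoff
                for a in s.residues[i].atoms
                for b in s.residues[j].atoms
            ):
                edges.add((i, j))
    return edges


def quaternion_superpose(mobile, reference):
    """Horn's closed-form quaternion superposition; returns (R, t, rmsd).

    Independent of the SVD-based implementation under test.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    S = P.T @ Q
    K = np.array(
        [
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ]
    )
    vals, vecs = np.linalg.eigh(K)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, t, rmsd


def brute_force_ef(scores, labels, model_ids, x_percent):
    """EF by direct counting, per the printed formula."""
    n = len(scores)
    n_top = max(1, round(x_percent / 100.0 * n))
    order = sorted(range(n), key=lambda i: (-scores[i], model_ids[i]))
    hits = sum(labels[i] for i in order[:n_top])
    total_pos = sum(labels)
    return (hits / n_top) * (n / total_pos)


def rotation_matrix(axis, angle_deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def transform_structure(s, R, t, chains=None):
    """Apply x -> R x + t to all atoms (or only the given chains)."""
    from dataclasses import replace

    new_res = []
    for res in s.residues:
        if chains is None or res.chain_id in chains:
            atoms = tuple(
                replace(a, coord=R @ a.coord + np.asarray(t, float))
                for a in res.atoms
            )
            new_res.append(replace(res, atoms=atoms))
        else:
            new_res.append(res)
    return replace(s, residues=tuple(new_res))
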