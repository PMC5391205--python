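"""Rigid-domain coordinate handling: PDB I/O, Cα RMSD, clash detection.

A :class:`RigidDomain` is a flat atom table (chain, residue number, residue
name, atom name, element, xyz) treated as a single rigid body. PDB parsing
and writing go through gemmi; altloc groups are reduced to the
highest-occupancy conformer and insertion codes are rejected so that a
residue is always addressable as (chain, integer number).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, kabsch_superpose

__all__ = ["RigidDomain", "read_pdb", "write_pdb", "ca_rmsd", "clash_count"]


@dataclass(frozen=True)
class RigidDomain:
    """Atomic coordinates of one rigid body.

    Fields are parallel arrays of length n_atoms; `coords` is (n, 3) in
    Angstrom in the PDB orthogonal frame. Residue numbering is kept as in
    the source file.
    """

    chain: np.ndarray      # unicode
    resnum: np.ndarray     # int
    resname: np.ndarray    # unicode
    atom_name: np.ndarray  # unicode
    element: np.ndarray    # unicode
    coords: np.ndarray     # (n, 3) float
    label: str = "domain"

    def __post_init__(self):
        n = len(self.chain)
        if n < 1:
            raise ValueError("no atoms")
        if self.coords.shape != (n, 3):
            raise ValueError("coordinate array shape mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.chain)

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def ca_mask(self) -> np.ndarray:
        return self.atom_name == "CA"

    def ca_coords(self) -> np.ndarray:
        m = self.ca_mask()
        if not m.any():
            raise ValueError("domain has no CA atoms")
        return self.coords[m]

    def ca_keys(self) -> list[tuple[str, int]]:
        m = self.ca_mask()
        return list(zip(self.chain[m].tolist(), self.resnum[m].tolist()))

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.element != "H"]

    def has_residue(self, chain: str, resnum: int) -> bool:
        return bool(np.any((self.chain == chain) & (self.resnum == resnum)))

    def atom_coord(self, chain: str, resnum: int, atom_name: str) -> np.ndarray:
        sel = (self.chain == chain) & (self.resnum == resnum) & (self.atom_name == atom_name)
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            raise KeyError(f"atom {atom_name} of {chain}:{resnum} not found")
        return self.coords[idx[0]].copy()

    def residue_mask(self, chain: str, resnum: int) -> np.ndarray:
        return (self.chain == chain) & (self.resnum == resnum)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, t: RigidTransform) -> "RigidDomain":
        return replace(self, coords=t.apply(self.coords))

    def with_label(self, label: str) -> "RigidDomain":
        return replace(self, label=label)

    @classmethod
    def from_atoms(cls, atoms, label: str = "domain") -> "RigidDomain":
        """Build from an iterable of (chain, resnum, resname, atom_name, element, xyz)."""
        rows = list(atoms)
        if not rows:
            raise ValueError("no atoms")
        return cls(
            chain=np.array([r[0] for r in rows]),
            resnum=np.array([int(r[1]) for r in rows]),
            resname=np.array([r[2] for r in rows]),
            atom_name=np.array([r[3] for r in rows]),
            element=np.array([r[4] for r in rows]),
            coords=np.array([r[5] for r in rows], dtype=float).reshape(-1, 3),
            label=label,
        )


def read_pdb(path) -> RigidDomain:
    """Read ATOM/HETATM records of a PDB file into a :class:`RigidDomain`.

    Altloc groups keep only the highest-occupancy conformer; insertion
    codes raise (the rigid-body machinery indexes residues by integer).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    rows = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.seqid.icode not in ("", " ", "\x00"):
                    raise ValueError(
                        f"insertion code {res.seqid.icode!r} at {chain.name}:{res.seqid.num} "
                        "not supported; renumber the file first")
                # reduce altlocs to the highest-occupancy conformer per atom name
                best: dict[str, gemmi.Atom] = {}
                for atom in res:
                    prev = best.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        best[atom.name] = atom
                for atom in best.values():
                    rows.append((chain.name, res.seqid.num, res.name, atom.name,
                                 atom.element.name,
                                 (atom.pos.x, atom.pos.y, atom.pos.z)))
        break  # first model only: one rigid body per file
    if not rows:
        raise ValueError(f"no atoms in {path}")
    return RigidDomain.from_atoms(rows, label=os.path.splitext(os.path.basename(str(path)))[0])


def write_pdb(domain: RigidDomain, path) -> None:
    """Write a domain as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = domain.label
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for i in range(domain.n_atoms):
        cname = str(domain.chain[i])
        if cname not in chain_map:
            chain_map[cname] = gemmi.Chain(cname)
        ch = chain_map[cname]
        rnum = int(domain.resnum[i])
        if len(ch) == 0 or ch[-1].seqid.num != rnum:
            res = gemmi.Residue()
            res.name = str(domain.resname[i])
            res.seqid = gemmi.SeqId(rnum, " ")
            ch.add_residue(res)
        atom = gemmi.Atom()
        atom.name = str(domain.atom_name[i])
        atom.element = gemmi.Element(str(domain.element[i]))
        x, y, z = domain.coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        ch[-1].add_atom(atom)
    for ch in chain_map.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def ca_rmsd(a: RigidDomain, b: RigidDomain, superpose: bool = False) -> float:
    """Cα RMSD between two domains with matching residue sets.

    With `superpose` the movable set (a) is first Kabsch-fitted onto b;
    otherwise the raw coordinate RMSD in the common frame is returned.
    """
    ka, kb = a.ca_keys(), b.ca_keys()
    if ka != kb:
        raise ValueError("mismatched residue sets between domains")
    xa, xb = a.ca_coords(), b.ca_coords()
    if superpose:
        return kabsch_superpose(xa, xb).rmsd
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def clash_count(a: np.ndarray, b: np.ndarray, cutoff: float) -> int:
    """Number of cross-set point pairs closer than `cutoff` Angstrom.

    Symmetric in (a, b); kd-tree accelerated.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = np.asarray(a, float).reshape(-1, 3)
    b = np.asarray(b, float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty coordinate set")
    ta, tb = cKDTree(a), cKDTree(b)
    # strictly-closer-than semantics: shrink by epsilon relative to scale
    return int(ta.count_neighbors(tb, cutoff * (1 - 1e-12)))
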