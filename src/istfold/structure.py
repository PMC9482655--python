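"""Minimal hierarchical coordinate model and PDB/mmCIF I/O.

The model keeps author residue numbering throughout, because every residue
reference in the literature on these proteins (Cys41, Arg37, the 27-246
ectodomain) uses author numbers.  Parsing is delegated to gemmi; only the
first model is kept, waters and non-polymer heteroatoms are dropped, and
alternate locations are resolved to the highest-occupancy conformer (ties
broken by first occurrence).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_structure",
    "write_structure",
    "chain_sequence",
    "StructureError",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for unreadable files, missing chains, or empty models."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # xyz in Angstroms

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("atom position must be finite")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_num: int
    res_name: str
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    ins_code: str = ""

    @property
    def is_standard(self) -> bool:
        return self.res_name in THREE_TO_ONE

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __getitem__(self, name: str) -> Atom:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"{self.res_name}{self.seq_num} has no atom {name!r}")
        return a

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.ins_code)


class Structure:
    """Chains of residues in author numbering, ordered N to C."""

    def __init__(self, sid: str, residues: Iterable[Residue] = ()):
        self.id = sid
        self._chains: dict[str, list[Residue]] = {}
        for r in residues:
            self._chains.setdefault(r.chain_id, []).append(r)
        for residues_ in self._chains.values():
            residues_.sort(key=lambda r: (r.seq_num, r.ins_code))
        seen: set[tuple] = set()
        for r in self.residues():
            if r.key in seen:
                raise StructureError(f"duplicate residue {r.key}")
            seen.add(r.key)

    @property
    def chain_ids(self) -> list[str]:
        return list(self._chains)

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self._chains:
            raise StructureError(
                f"no chain {chain_id!r} in {self.id} (have {self.chain_ids})")
        return self._chains[chain_id]

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        if chain_id is not None:
            yield from self.chain(chain_id)
        else:
            for residues in self._chains.values():
                yield from residues

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self, chain_id: str | None = None,
               atom_name: str | None = None) -> np.ndarray:
        """Stacked coordinates, optionally restricted to one atom name."""
        pts = [a.pos for r in self.residues(chain_id) for a in r.atoms
               if atom_name is None or a.name == atom_name]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "Structure":
        """Rigidly moved deep copy: x -> R @ x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new = []
        for r in self.residues():
            atoms = [Atom(a.name, a.element, R @ a.pos + t) for a in r.atoms]
            new.append(Residue(r.chain_id, r.seq_num, r.res_name, atoms,
                               r.ins_code))
        return Structure(self.id, new)


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy altloc per atom name, first listed on ties."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            best[atom.name] = atom
    # preserve file order of the winners
    winners = set(id(a) for a in best.values())
    return [a for a in res if id(a) in winners]


def read_structure(path: str | Path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the internal model.

    Keeps all ATOM records of the first model; waters and other non-polymer
    HETATM records are discarded, but modified polymer residues (HETATM
    within the polymer) are kept and later surface as 'X' in sequences.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except StructureError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no atoms in {path}")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_polymer = res.name in THREE_TO_ONE or (
                info is not None and info.is_amino_acid())
            if not is_polymer:
                continue
            atoms = [Atom(a.name, a.element.name,
                          np.array([a.pos.x, a.pos.y, a.pos.z]))
                     for a in _resolve_altlocs(res)]
            if not atoms:
                continue
            residues.append(Residue(chain.name, res.seqid.num, res.name,
                                    atoms, res.seqid.icode.strip()))
    if not residues:
        raise StructureError(f"no polymer atoms in {path}")
    return Structure(path.stem, residues)


_PDB_ATOM = ("{rec:<6s}{serial:>5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
             "{seq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}"
             "{b:>6.2f}          {elem:>2s}\n")


def _pdb_atom_name(name: str, element: str) -> str:
    # PDB alignment rule: 1-2 char element symbols start in column 13/14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_structure(s: Structure, path: str | Path) -> Path:
    """Write fixed-width PDB ATOM records, one TER per chain."""
    path = Path(path)
    if any(len(r.atoms) == 0 for r in s.residues()):
        raise StructureError("cannot write residue with no atoms")
    lines = []
    serial = 0
    for chain_id in s.chain_ids:
        res = None
        for res in s.chain(chain_id):
            for a in res.atoms:
                if np.any(np.abs(a.pos) >= 10000) or np.any(a.pos <= -1000):
                    raise StructureError(
                        f"coordinate out of PDB field range: {a.pos}")
                serial += 1
                lines.append(_PDB_ATOM.format(
                    rec="ATOM", serial=serial,
                    name=_pdb_atom_name(a.name, a.element), altloc=" ",
                    res=res.res_name[:3], chain=chain_id[:1],
                    seq=res.seq_num, icode=res.ins_code or " ",
                    x=a.pos[0], y=a.pos[1], z=a.pos[2], occ=1.0, b=0.0,
                    elem=a.element[:2].upper()))
        serial += 1
        lines.append(f"TER   {serial:>5d}      {res.res_name:<3s} "
                     f"{chain_id[:1]}{res.seq_num:>4d}\n")
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


def chain_sequence(s: Structure, chain_id: str) -> tuple[str, list[int]]:
    """One-letter sequence of a chain with the parallel author numbers.

    Non-standard residues map to 'X'.
    """
    seq, nums = [], []
    for r in s.chain(chain_id):
        seq.append(THREE_TO_ONE.get(r.res_name, "X"))
        nums.append(r.seq_num)
    return "".join(seq), nums
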