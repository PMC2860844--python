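"""Read and write PDB-format coordinate files and select MHC / peptide chains.

The in-memory model is a small hierarchy (:class:`Structure` -> chains ->
:class:`Residue` -> :class:`Atom`) holding heavy-atom coordinates in
angstroms.  Hydrogens are dropped at parse time and alternate locations are
resolved to the 'A' (or blank) conformer, the common convention for crystal
structures.  :func:`split_pmhc` partitions a parsed complex into the MHC
receptor chains and the single short peptide bound in the cleft.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    AmbiguousPeptideError,
    IncompleteBackboneError,
    PDBParseError,
    PDBWriteError,
    PmhcError,
)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PMHCComplex",
    "read_pdb",
    "write_pdb",
    "split_pmhc",
    "read_fasta",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "BACKBONE_ATOMS",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Water residue names never considered part of a protein chain.
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Residue name of synthetic scaffold pseudo-atoms (toy-cleft walls/floor).
#: Scaffold atoms occlude and repel real atoms but are inert among themselves.
SCAFFOLD_RESNAME = "PSD"

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """A heavy atom: label, element and position in angstroms."""

    name: str
    element: str
    pos: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise PmhcError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise PmhcError(f"atom {self.name}: element must be non-empty")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(), self.altloc, self.occupancy)


@dataclass
class Residue:
    code3: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def code1(self) -> str:
        """One-letter code, 'X' for non-canonical residues."""
        return THREE_TO_ONE.get(self.code3, "X")

    @property
    def is_canonical(self) -> bool:
        return self.code3 in THREE_TO_ONE

    @property
    def is_water(self) -> bool:
        return self.code3 in WATER_NAMES

    @property
    def has_complete_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(b in names for b in BACKBONE_ATOMS)

    def get(self, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    def coords(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        """Stacked coordinates of the named atoms (all heavy atoms if None)."""
        atoms = self.atoms if names is None else [self.get(n) for n in names]
        missing = [n for n, a in zip(names or (), atoms) if a is None]
        if missing:
            raise PmhcError(f"residue {self.code3}{self.seqnum}: missing atoms {missing}")
        return np.array([a.pos for a in atoms], dtype=float).reshape(-1, 3)

    def copy(self) -> "Residue":
        return Residue(self.code3, self.seqnum, self.icode, [a.copy() for a in self.atoms])


@dataclass
class Structure:
    """An ordered set of chains, each an ordered list of residues."""

    id: str = ""
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [c for c, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise PmhcError(f"structure {self.id}: duplicate chain ids {ids}")

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(chain_id)

    @property
    def residues(self) -> list[Residue]:
        return [r for _, rs in self.chains for r in rs]

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        out = np.array([a.pos for a in self.atoms], dtype=float)
        return out.reshape(-1, 3)

    def set_coords(self, coords: np.ndarray) -> None:
        atoms = self.atoms
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise PmhcError("coordinate array shape does not match atom count")
        for a, p in zip(atoms, coords):
            a.pos = p.copy()

    def copy(self) -> "Structure":
        return Structure(
            self.id,
            [(cid, [r.copy() for r in rs]) for cid, rs in self.chains],
            dict(self.metadata),
        )


@dataclass
class PMHCComplex:
    """An MHC receptor with a bound 8-12-mer peptide.

    The peptide is a single-chain :class:`Structure`; its residues are
    indexed p1..pn from the N terminus (list order), with the author
    numbering preserved in ``Residue.seqnum``.
    """

    mhc: Structure
    peptide: Structure
    provenance: dict = field(default_factory=dict)
    energy: object | None = None

    def __post_init__(self):
        if len(self.peptide.chains) != 1:
            raise PmhcError("peptide must be a single chain")
        n = len(self.peptide_residues)
        if not 8 <= n <= 12:
            raise PmhcError(f"peptide length {n} outside 8..12")
        for i, r in enumerate(self.peptide_residues, start=1):
            if not r.has_complete_backbone:
                raise IncompleteBackboneError(
                    f"peptide residue p{i} ({r.code3}) lacks a complete N/CA/C/O backbone"
                )
        pep_id = self.peptide.chains[0][0]
        if pep_id in {c for c, _ in self.mhc.chains}:
            raise PmhcError(f"peptide chain id {pep_id!r} collides with an MHC chain")

    @property
    def peptide_residues(self) -> list[Residue]:
        return self.peptide.chains[0][1]

    @property
    def peptide_sequence(self) -> str:
        return "".join(r.code1 for r in self.peptide_residues)

    @property
    def alpha_chain(self) -> list[Residue]:
        """The MHC alpha chain: the longest receptor chain."""
        return max((rs for _, rs in self.mhc.chains), key=len)

    def mhc_ca(self) -> dict[tuple[int, str], np.ndarray]:
        """Alpha-chain C-alpha coordinates keyed by (seqnum, icode)."""
        out = {}
        for r in self.alpha_chain:
            ca = r.get("CA")
            if ca is not None:
                out[(r.seqnum, r.icode)] = ca.pos
        return out

    def peptide_heavy_coords(self) -> np.ndarray:
        return self.peptide.coords()

    def to_structure(self, id: str | None = None) -> Structure:
        """Merge receptor and peptide chains into one serializable structure."""
        chains = [(cid, [r.copy() for r in rs]) for cid, rs in self.mhc.chains]
        pid, prs = self.peptide.chains[0]
        chains.append((pid, [r.copy() for r in prs]))
        return Structure(id or self.mhc.id, chains, dict(self.mhc.metadata))

    def copy(self) -> "PMHCComplex":
        return PMHCComplex(self.mhc.copy(), self.peptide.copy(), dict(self.provenance), self.energy)


# ---------------------------------------------------------------------------
# PDB fixed-column reader / writer


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:2].upper() in {"FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR"} and len(stripped) > 1:
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text.strip()!r}", lineno) from None


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text.strip()!r}", lineno) from None


def read_pdb(source: str | Path) -> Structure:
    """Parse fixed-column ATOM/HETATM records into a :class:`Structure`.

    ``source`` may be a path or the file content itself (recognized by an
    embedded newline or a leading record keyword).  Hydrogens and deuteriums
    are dropped; alternate locations other than 'A'/blank are dropped.
    """
    if isinstance(source, Path):
        label, text = source.stem, source.read_text()
    else:
        s = str(source)
        if "\n" in s or s[:6].rstrip() in {"ATOM", "HETATM", "HEADER", "MODEL", "REMARK", "TER", "END"}:
            label, text = "", s
        else:
            p = Path(s)
            label, text = p.stem, p.read_text()

    chains: list[tuple[str, list[Residue]]] = []
    chain_map: dict[str, list[Residue]] = {}
    current: Residue | None = None
    current_key: tuple | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].rstrip()
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError("coordinate record shorter than 54 columns", lineno)
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        seqnum = _parse_int(line[22:26], "residue number", lineno)
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        occ = line[54:60].strip()
        occupancy = _parse_float(occ, "occupancy", lineno) if occ else 1.0
        element = line[76:78].strip().capitalize() if len(line) >= 77 else ""
        if not element:
            element = _guess_element(name)
        if element in ("H", "D"):
            continue
        if altloc not in ("", "A"):
            continue

        key = (chain_id, seqnum, icode, resname)
        if key != current_key:
            current = Residue(resname, seqnum, icode)
            current_key = key
            if chain_id not in chain_map:
                chain_map[chain_id] = []
                chains.append((chain_id, chain_map[chain_id]))
            chain_map[chain_id].append(current)
        assert current is not None
        if current.get(name) is None:  # duplicate atom names (altloc remnants) ignored
            current.atoms.append(Atom(name, element, np.array([x, y, z]), "", occupancy))

    if not chain_map:
        raise PDBParseError("no ATOM/HETATM records found (empty or non-coordinate file)")
    return Structure(label, chains)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise PDBWriteError(f"atom name {name!r} exceeds the 4-column field")
    if len(name) == 4:
        return name
    # single-letter elements are left-padded by one column (PDB convention)
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, dest: str | Path | io.TextIOBase) -> None:
    """Serialize a structure as standard ATOM records, TER per chain, END."""
    lines = []
    serial = 1
    for chain_id, residues in structure.chains:
        for res in residues:
            record = "ATOM  " if res.is_canonical else "HETATM"
            for atom in res.atoms:
                x, y, z = atom.pos
                if not (-999.999 < x < 9999.999 and -999.999 < y < 9999.999 and -999.999 < z < 9999.999):
                    raise PDBWriteError(f"coordinate out of format range: {atom.pos}")
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc or ' '}{res.code3:>3s} {chain_id if chain_id.strip() else ' '}"
                    f"{res.seqnum:4d}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        if residues:
            lines.append(f"TER   {serial:5d}      {residues[-1].code3:>3s} "
                         f"{chain_id if chain_id.strip() else ' '}{residues[-1].seqnum:4d}")
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# pMHC splitting


def _is_protein_chain(residues: list[Residue]) -> bool:
    non_water = [r for r in residues if not r.is_water]
    if not non_water:
        return False
    # a chain is protein-like if most residues carry a CA atom
    with_ca = sum(1 for r in non_water if r.get("CA") is not None)
    return with_ca >= max(1, len(non_water) // 2)


def split_pmhc(structure: Structure) -> PMHCComplex:
    """Partition a parsed complex into receptor and bound peptide.

    The peptide is the unique protein chain of 8-12 residues with complete
    backbones; every other protein chain becomes the receptor.  Waters and
    non-protein ligands are dropped.
    """
    protein_chains = [(cid, [r for r in rs if not r.is_water])
                      for cid, rs in structure.chains if _is_protein_chain(rs)]
    candidates = [cid for cid, rs in protein_chains if 8 <= len(rs) <= 12]
    if len(candidates) != 1:
        raise AmbiguousPeptideError(
            f"expected exactly one 8-12-residue peptide chain, found {len(candidates)}",
            candidates,
        )
    pep_id = candidates[0]
    pep_residues = dict(protein_chains)[pep_id]
    for i, r in enumerate(pep_residues, start=1):
        if not r.has_complete_backbone:
            raise IncompleteBackboneError(
                f"peptide residue p{i} ({r.code3}{r.seqnum}) has an incomplete backbone; "
                "structures with incomplete epitopes are excluded"
            )
    mhc_chains = [(cid, [r.copy() for r in rs]) for cid, rs in protein_chains if cid != pep_id]
    mhc = Structure(structure.id, mhc_chains, dict(structure.metadata))
    peptide = Structure(structure.id + "_pep", [(pep_id, [r.copy() for r in pep_residues])])
    return PMHCComplex(mhc, peptide, provenance={"source": structure.id})


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file or FASTA-formatted text."""
    from Bio import SeqIO  # delegated to Biopython; local import keeps startup light

    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and not source.startswith(">")):
        handle = io.StringIO(Path(source).read_text())
    else:
        handle = io.StringIO(str(source))
    entries = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    if not entries:
        raise PmhcError("no FASTA entries found")
    return entries
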