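"""Atomic structure model and PDB input/output.

The hierarchy is Structure -> Chain -> Residue -> Atom, mirroring the wwPDB
coordinate model.  Parsing is delegated to gemmi (with a fixed-column
pre-validation pass so malformed records are rejected with a line number);
writing is a fixed-column wwPDB v3.3 formatter that places a TER record after
the polymer part of each chain and END at the end of the file.

Only the first MODEL of a multi-model file is read.  Alternate locations are
resolved to a single conformer: the altloc with the highest occupancy wins,
ties go to the first one in the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "PDBParseError",
    "PDBWriteError",
    "parse_pdb",
    "write_pdb",
    "backbone_atoms",
    "structures_equal",
    "BACKBONE_ATOM_NAMES",
]

#: Backbone atom names in canonical order (amide nitrogen, alpha carbon,
#: carbonyl carbon, carbonyl oxygen).  OXT is deliberately not included.
BACKBONE_ATOM_NAMES: tuple[str, ...] = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a PDB character stream cannot be parsed."""


class PDBWriteError(ValueError):
    """Raised when a Structure cannot be serialized to PDB."""


@dataclass(eq=False)
class Atom:
    """A single atom site.

    Coordinates are orthogonal Angstroms.  ``is_hetero`` records whether the
    atom came from a HETATM record.
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name or len(self.name) > 4:
            raise ValueError(f"atom name must be 1-4 characters, got {self.name!r}")


@dataclass(eq=False)
class Residue:
    """One residue (chemical component instance) with its atoms in file order."""

    name: str
    number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_hetero(self) -> bool:
        return bool(self.atoms) and all(a.is_hetero for a in self.atoms)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)


@dataclass(eq=False)
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_hetero]


@dataclass(eq=False)
class Structure:
    chains: list[Chain] = field(default_factory=list)
    title: str = ""

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def residues(self) -> Iterator[tuple[Chain, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c, r

    def atoms(self) -> Iterator[Atom]:
        for _, r in self.residues():
            yield from r.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Structure":
        return Structure(
            chains=[
                Chain(
                    id=c.id,
                    residues=[
                        Residue(
                            name=r.name,
                            number=r.number,
                            insertion_code=r.insertion_code,
                            atoms=[
                                Atom(
                                    name=a.name,
                                    element=a.element,
                                    position=a.position.copy(),
                                    occupancy=a.occupancy,
                                    b_factor=a.b_factor,
                                    is_hetero=a.is_hetero,
                                    altloc=a.altloc,
                                )
                                for a in r.atoms
                            ],
                        )
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ],
            title=self.title,
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _validate_record_line(line: str, lineno: int) -> None:
    """Reject malformed fixed-column ATOM/HETATM records with a line number.

    gemmi is deliberately forgiving (an unparsable coordinate silently becomes
    0.0), which would corrupt geometry downstream, so the numeric fields are
    checked here first.
    """
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: record shorter than 54 columns")
    for start, stop, what in (
        (30, 38, "x coordinate"),
        (38, 46, "y coordinate"),
        (46, 54, "z coordinate"),
    ):
        text = line[start:stop].strip()
        try:
            value = float(text)
        except ValueError:
            raise PDBParseError(f"line {lineno}: unparsable {what} {text!r}") from None
        if not math.isfinite(value):
            raise PDBParseError(f"line {lineno}: non-finite {what} {text!r}")
    for start, stop, what in ((54, 60, "occupancy"), (60, 66, "B-factor")):
        text = line[start:stop].strip()
        if text:
            try:
                float(text)
            except ValueError:
                raise PDBParseError(f"line {lineno}: unparsable {what} {text!r}") from None
    if not line[12:16].strip():
        raise PDBParseError(f"line {lineno}: empty atom name field")
    try:
        int(line[22:26].strip() or "0")
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: unparsable residue number {line[22:26].strip()!r}"
        ) from None


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties to the first in file."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[name] for name in order]


def parse_pdb(text: str) -> Structure:
    """Parse a PDB-format character stream into a :class:`Structure`.

    Only ATOM/HETATM coordinate records are interpreted; MODEL entries after
    the first are ignored.  Raises :class:`PDBParseError` on empty input or a
    malformed fixed-column record (the error names the offending line).
    """
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_records += 1
            _validate_record_line(line, lineno)
    if n_records == 0:
        raise PDBParseError("no ATOM or HETATM records in input")

    try:
        gst = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(exc)) from exc
    if len(gst) == 0:
        raise PDBParseError("no coordinate model in input")

    model = gst[0]
    chains: list[Chain] = []
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    b_factor=ga.b_iso,
                    is_hetero=(gres.het_flag == "H"),
                    altloc="" if ga.altloc == "\0" else ga.altloc,
                )
                for ga in gres
            ]
            chain.residues.append(
                Residue(
                    name=gres.name,
                    number=gres.seqid.num,
                    insertion_code=gres.seqid.icode.strip(),
                    atoms=_resolve_altlocs(atoms),
                )
            )
        chains.append(chain)
    return Structure(chains=chains, title=gst.name if gst.name != "unknown" else "")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str) -> str:
    # wwPDB convention: 1-2 letter element names start in column 14 unless the
    # name is 4 characters long or starts with a digit.
    if len(name) >= 4 or name[:1].isdigit():
        return name.ljust(4)
    return f" {name:<3}"


def _format_record(serial: int, atom: Atom, res: Residue, chain_id: str) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    x, y, z = atom.position
    element = atom.element.strip().upper()[:2]
    return (
        f"{record}{serial:>5} {_format_atom_name(atom.name)}{atom.altloc or ' '}"
        f"{res.name:>3} {chain_id:1}{res.number:>4}{res.insertion_code or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {element:>2}"
    )


def write_pdb(s: Structure) -> str:
    """Serialize a :class:`Structure` to wwPDB v3.3 fixed-column text.

    Coordinates are printed to 3 decimals, a TER record follows the polymer
    part of each chain, and END terminates the file.
    """
    if not s.chains:
        raise PDBWriteError("cannot write a structure with no chains")
    lines: list[str] = []
    serial = 0
    for chain in s.chains:
        last_polymer: Residue | None = None
        for res in chain.residues:
            for atom in res.atoms:
                if len(atom.name) > 4:
                    raise PDBWriteError(f"atom name longer than 4 characters: {atom.name!r}")
                serial += 1
                lines.append(_format_record(serial, atom, res, chain.id))
            if not res.is_hetero:
                last_polymer = res
        if last_polymer is not None:
            serial += 1
            lines.append(
                f"TER   {serial:>5}      {last_polymer.name:>3} {chain.id:1}"
                f"{last_polymer.number:>4}{last_polymer.insertion_code or ' '}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Backbone access
# ---------------------------------------------------------------------------

def backbone_atoms(r: Residue) -> list[Atom]:
    """Return the backbone atoms of ``r`` in N, CA, C, O order.

    Atoms absent from the residue are omitted; a residue with no backbone
    atoms yields an empty list.  Hydrogens and side-chain atoms never appear.
    """
    return [a for name in BACKBONE_ATOM_NAMES if (a := r.atom(name)) is not None]


def structures_equal(a: Structure, b: Structure, tol: float = 0.0) -> bool:
    """Field-by-field equality of two structures (coordinates within ``tol``)."""
    if len(a.chains) != len(b.chains):
        return False
    for ca_, cb in zip(a.chains, b.chains):
        if ca_.id != cb.id or len(ca_.residues) != len(cb.residues):
            return False
        for ra, rb in zip(ca_.residues, cb.residues):
            if (ra.name, ra.number, ra.insertion_code) != (rb.name, rb.number, rb.insertion_code):
                return False
            if len(ra.atoms) != len(rb.atoms):
                return False
            for aa, ab in zip(ra.atoms, rb.atoms):
                if (aa.name, aa.element, aa.is_hetero) != (ab.name, ab.element, ab.is_hetero):
                    return False
                if np.any(np.abs(aa.position - ab.position) > tol):
                    return False
    return True
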