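"""Template-based ligand placement: copy ligand residues from the reference
structure into the merged model, coordinates untouched.

Ligand identification replaces a chemical-component-dictionary lookup with an
explicit rule set: a residue is a ligand iff it is a hetero (HETATM) residue,
is not water (unless waters are requested), is not a standard amino acid or
nucleotide, and passes the user's include/exclude code sets.  Single-atom
hetero residues (metal ions such as MG, NA, ZN) are included by default and
can be switched off.

Because the predicted backbone was superimposed onto the reference frame
upstream, the reference ligand coordinates are already in the merged model's
frame and are appended verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .backbone_merge import MergedStructure
from .structure_io import Chain, Residue, Structure

__all__ = [
    "LigandPolicy",
    "LigandTransferError",
    "is_ligand",
    "transfer_ligands",
    "STANDARD_AMINO_ACIDS",
    "STANDARD_NUCLEOTIDES",
    "WATER_CODES",
]

logger = logging.getLogger(__name__)

STANDARD_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine: modelled as part of the polymer
})
STANDARD_NUCLEOTIDES = frozenset({"A", "C", "G", "U", "DA", "DC", "DG", "DT"})
WATER_CODES = frozenset({"HOH", "WAT"})


class LigandTransferError(ValueError):
    pass


@dataclass
class LigandPolicy:
    """Rules deciding which reference residues count as ligands."""

    exclude_water: bool = True
    include_ions: bool = True
    explicit_include: frozenset[str] = field(default_factory=frozenset)
    explicit_exclude: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.explicit_include = frozenset(self.explicit_include)
        self.explicit_exclude = frozenset(self.explicit_exclude)
        if self.explicit_include & self.explicit_exclude:
            raise ValueError("include and exclude sets must be disjoint")


def is_ligand(r: Residue, policy: LigandPolicy | None = None) -> bool:
    """True iff residue ``r`` should be transferred as a ligand under ``policy``."""
    if policy is None:
        policy = LigandPolicy()
    if not r.is_hetero:
        return False
    if r.name in policy.explicit_exclude:
        return False
    if r.name in policy.explicit_include:
        return True
    if r.name in WATER_CODES:
        return not policy.exclude_water
    if r.name in STANDARD_AMINO_ACIDS or r.name in STANDARD_NUCLEOTIDES:
        return False
    if len(r.atoms) == 1:
        return policy.include_ions
    return True


def transfer_ligands(
    ref: Structure,
    merged: MergedStructure | Structure,
    policy: LigandPolicy | None = None,
) -> Structure:
    """Append every reference ligand residue to (a copy of) the merged model.

    Coordinates, atom and residue names, numbering and chain labels are taken
    from the reference exactly; the appended atoms are flagged as HETATM.
    A ligand whose (chain, number, insertion code) key already exists in the
    merged model raises :class:`LigandTransferError` (re-running the transfer
    never duplicates ligands silently).
    """
    if policy is None:
        policy = LigandPolicy()
    base = merged.structure if isinstance(merged, MergedStructure) else merged
    out = base.copy()
    existing = {
        (c.id, r.number, r.insertion_code) for c, r in out.residues()
    }
    n_transferred = 0
    for chain in ref.chains:
        for res in chain.residues:
            if not is_ligand(res, policy):
                continue
            key = (chain.id, res.number, res.insertion_code)
            if key in existing:
                raise LigandTransferError(
                    f"residue {res.name} {chain.id}{res.number}{res.insertion_code} "
                    "already present in the merged model"
                )
            copied = Residue(
                name=res.name,
                number=res.number,
                insertion_code=res.insertion_code,
                atoms=[
                    type(a)(
                        name=a.name,
                        element=a.element,
                        position=a.position.copy(),
                        occupancy=a.occupancy,
                        b_factor=a.b_factor,
                        is_hetero=True,
                        altloc=a.altloc,
                    )
                    for a in res.atoms
                ],
            )
            target = out.chain(chain.id)
            if target is None:
                target = Chain(id=chain.id)
                out.chains.append(target)
            target.residues.append(copied)
            existing.add(key)
            n_transferred += 1
            logger.info("transferred ligand %s %s%d%s (%d atoms)",
                        res.name, chain.id, res.number, res.insertion_code, len(res.atoms))
    if n_transferred == 0:
        logger.info("no ligand residues found in reference")
    return out
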