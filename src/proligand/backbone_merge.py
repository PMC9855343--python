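"""Backbone coordinate averaging of a reference structure with a superimposed
predicted backbone.

For every polymer residue of the reference structure, the closest predicted
CA atom is found across *all* predicted chains.  If its Euclidean distance to
the reference CA is strictly below the chain's threshold (default 1 A,
overridable per chain), each backbone atom (N, CA, C, O) present in both
residues is replaced by the componentwise arithmetic mean of the two
positions; otherwise the reference coordinates are kept unchanged.  Hetero
residues (ligands, waters, ions) are never averaged.  The output keeps the
reference structure's chain labels, residue names, numbering and order.

The merge report tallies, per chain, how many polymer residues were averaged,
with the percentage rounded to 1 decimal; the overall figure is the mean of
the per-chain percentages, reported to 2 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .structure_io import BACKBONE_ATOM_NAMES, Residue, Structure

__all__ = [
    "MergeParams",
    "ChainMergeStats",
    "MergeReport",
    "MergedStructure",
    "MergeError",
    "ca_distance",
    "nearest_predicted_ca",
    "average_backbone",
    "report_summary",
]

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)
Provenance = Literal["averaged", "reference_only"]


class MergeError(ValueError):
    pass


@dataclass
class MergeParams:
    """Distance thresholds (A) controlling which residues are averaged."""

    default_threshold: float = 1.0
    per_chain_threshold: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in (self.default_threshold, *self.per_chain_threshold.values()):
            if not (t > 0):
                raise ValueError("thresholds must be positive")

    def threshold_for(self, chain_id: str) -> float:
        return self.per_chain_threshold.get(chain_id, self.default_threshold)


@dataclass(frozen=True)
class ChainMergeStats:
    chain_id: str
    total_residues: int
    averaged_residues: int

    def __post_init__(self) -> None:
        if not (0 <= self.averaged_residues <= self.total_residues):
            raise ValueError("averaged residue count out of range")

    @property
    def percent_averaged(self) -> float:
        if self.total_residues == 0:
            return 0.0
        return round(100.0 * self.averaged_residues / self.total_residues, 1)


@dataclass
class MergeReport:
    """Per-chain averaging tallies and the per-target overall percentage."""

    chains: list[ChainMergeStats]

    @property
    def overall_percent(self) -> float:
        # mean of the per-chain percentages as printed (1 decimal each),
        # reported to 2 decimals
        if not self.chains:
            return 0.0
        return round(sum(c.percent_averaged for c in self.chains) / len(self.chains), 2)

    @classmethod
    def from_counts(cls, counts: Iterable[tuple[str, int, int]]) -> "MergeReport":
        """Build a report from (chain id, total residues, averaged residues)
        rows, e.g. published per-chain tallies."""
        return cls(chains=[ChainMergeStats(c, t, a) for c, t, a in counts])


@dataclass
class MergedStructure:
    """The averaged structure plus per-residue provenance.

    The residue set, numbering and chain labels are identical to the
    reference structure the merge started from.
    """

    structure: Structure
    provenance: dict[ResidueKey, Provenance]


def ca_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance (A) between two CA positions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - b))


class _PredCAIndex:
    """Predicted CA positions sorted by (chain id, residue number, insertion
    code) so that the first argmin breaks distance ties toward the lowest key."""

    def __init__(self, pred: Structure):
        entries = []
        for chain in pred.chains:
            for res in chain.polymer_residues():
                ca = res.atom("CA")
                if ca is not None:
                    entries.append(((chain.id, res.number, res.insertion_code), ca.position))
        entries.sort(key=lambda e: e[0])
        self.keys = [k for k, _ in entries]
        self.coords = np.array([p for _, p in entries]) if entries else np.empty((0, 3))

    def nearest(self, point: np.ndarray) -> tuple[ResidueKey, float] | None:
        if len(self.keys) == 0:
            return None
        d = np.linalg.norm(self.coords - point, axis=1)
        i = int(np.argmin(d))  # ties resolve to the lowest key (sorted order)
        return self.keys[i], float(d[i])


def nearest_predicted_ca(
    ref_residue: Residue, pred: Structure
) -> tuple[ResidueKey, float] | None:
    """Closest predicted CA to the reference residue's CA, searched over all
    predicted chains; ties broken by ascending (chain id, residue number).

    Returns None if the reference residue has no CA atom (the caller then
    keeps the reference coordinates) or the prediction has no CA atoms.
    """
    ca = ref_residue.atom("CA")
    if ca is None:
        return None
    return _PredCAIndex(pred).nearest(ca.position)


def average_backbone(
    ref: Structure,
    pred_superimposed: Structure,
    params: MergeParams | None = None,
) -> tuple[MergedStructure, MergeReport]:
    """Merge reference and superimposed predicted backbones by distance-gated
    coordinate averaging.

    ``pred_superimposed`` must already be in the reference coordinate frame.
    Residues of the prediction that match no reference residue are dropped
    (the iteration runs over reference residues only).  Hetero residues
    (ligands, waters, ions) are not carried into the merged structure: the
    ligand-transfer step appends them from the reference afterwards.
    """
    if params is None:
        params = MergeParams()
    if not ref.chains or all(not c.residues for c in ref.chains):
        raise MergeError("reference structure is empty")

    index = _PredCAIndex(pred_superimposed)
    merged = ref.copy()
    provenance: dict[ResidueKey, Provenance] = {}
    stats: list[ChainMergeStats] = []
    used_pred_keys: set[ResidueKey] = set()

    pred_lookup: dict[ResidueKey, Residue] = {
        (c.id, r.number, r.insertion_code): r
        for c in pred_superimposed.chains
        for r in c.polymer_residues()
    }

    for chain in merged.chains:
        total = 0
        averaged = 0
        threshold = params.threshold_for(chain.id)
        kept: list[Residue] = []
        for res in chain.residues:
            if res.is_hetero:
                continue  # ligands/waters/ions: re-appended by ligand transfer
            kept.append(res)
            total += 1
            key: ResidueKey = (chain.id, res.number, res.insertion_code)
            ca = res.atom("CA")
            hit = index.nearest(ca.position) if ca is not None else None
            if hit is not None and hit[1] < threshold:  # strict: equality keeps reference
                pred_res = pred_lookup[hit[0]]
                used_pred_keys.add(hit[0])
                for name in BACKBONE_ATOM_NAMES:
                    ref_atom = res.atom(name)
                    pred_atom = pred_res.atom(name)
                    if ref_atom is not None and pred_atom is not None:
                        ref_atom.position = (ref_atom.position + pred_atom.position) / 2.0
                averaged += 1
                provenance[key] = "averaged"
            else:
                provenance[key] = "reference_only"
        chain.residues = kept
        stats.append(ChainMergeStats(chain.id, total, averaged))

    unused = len(pred_lookup) - len(used_pred_keys)
    if unused:
        logger.warning("%d predicted residues were not used for any reference residue", unused)
    report = MergeReport(chains=stats)
    for c in report.chains:
        logger.info("chain %s: %d/%d residues averaged (%.1f%%)",
                    c.chain_id, c.averaged_residues, c.total_residues, c.percent_averaged)
    return MergedStructure(structure=merged, provenance=provenance), report


def report_summary(report: MergeReport) -> str:
    """TSV summary: one row per chain plus a final ``#overall`` line with the
    mean of the per-chain percentages."""
    if not report.chains:
        raise MergeError("report has no chains")
    lines = ["chain\ttotal\taveraged\tpercent"]
    for c in report.chains:
        lines.append(f"{c.chain_id}\t{c.total_residues}\t{c.averaged_residues}\t{c.percent_averaged:.1f}")
    lines.append(f"#overall\t\t\t{report.overall_percent:.2f}")
    return "\n".join(lines) + "\n"
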