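"""Rigid-body superposition of a predicted backbone onto a reference structure.

Chain correspondence is established by global pairwise sequence alignment
(Needleman-Wunsch, BLOSUM62, gap open -11 / extend -1) with a greedy
one-to-one assignment; residue correspondence is the set of aligned columns
whose residues both carry a CA atom.  The least-squares rotation/translation
over all matched CA pairs (one global fit per structure, not per chain) is
computed with the Kabsch algorithm, reflection branch corrected so the
rotation is always proper.

Optional iterative pruning (drop pairs further than 2 A after fitting, at
most 5 rounds) is available but off by default: the downstream merge step
applies its own per-residue distance threshold, which already rejects
outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import Chain, Structure

__all__ = [
    "ResiduePair",
    "RigidTransform",
    "ChainMatching",
    "SuperpositionError",
    "match_chains",
    "match_residues",
    "kabsch_fit",
    "apply_transform",
    "superpose_structures",
    "one_letter_sequence",
]

logger = logging.getLogger(__name__)

MIN_CHAIN_IDENTITY = 0.30
PRUNE_DISTANCE = 2.0
PRUNE_MAX_ITER = 5

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine behaves as polymer methionine
}


class SuperpositionError(RuntimeError):
    """Raised when no confident correspondence or fit can be established."""


@dataclass(frozen=True)
class ResiduePair:
    """A matched (reference, predicted) residue, identified by
    (chain id, residue number, insertion code) keys."""

    ref_residue: tuple[str, int, str]
    pred_residue: tuple[str, int, str]
    ca_distance_after_fit: float | None = None


@dataclass
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation, with the RMSD of
    the fit and the residue pairs it was computed from."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    pairs: tuple[ResiduePair, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation matrix must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation, self.rmsd)


@dataclass
class ChainMatching:
    """One-to-one chain assignment plus the chains left unmatched."""

    mapping: dict[str, str]
    unmatched_ref: list[str] = field(default_factory=list)
    unmatched_pred: list[str] = field(default_factory=list)

    def __getitem__(self, ref_chain_id: str) -> str:
        return self.mapping[ref_chain_id]

    def items(self):
        return self.mapping.items()


def one_letter_sequence(chain: Chain) -> str:
    """One-letter amino-acid sequence of the chain's polymer residues;
    residues outside the standard set map to X."""
    return "".join(_THREE_TO_ONE.get(r.name, "X") for r in chain.polymer_residues())


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    return al


def _align(seq_a: str, seq_b: str):
    """Best global alignment, or None if either sequence is empty."""
    if not seq_a or not seq_b:
        return None
    return _aligner().align(seq_a, seq_b)[0]


def _alignment_identity(alignment) -> float:
    counts = alignment.counts()
    aligned = counts.aligned
    return counts.identities / aligned if aligned else 0.0


def match_chains(ref: Structure, pred: Structure) -> ChainMatching:
    """Greedy one-to-one chain pairing maximizing global alignment score.

    Raises :class:`SuperpositionError` if no chain pair reaches 30% sequence
    identity over its aligned columns.
    """
    if not ref.chains or not pred.chains:
        raise SuperpositionError("both structures must contain at least one chain")
    candidates = []
    for rc in ref.chains:
        for pc in pred.chains:
            aln = _align(one_letter_sequence(rc), one_letter_sequence(pc))
            if aln is None:
                continue
            identity = _alignment_identity(aln)
            if identity >= MIN_CHAIN_IDENTITY:
                candidates.append((aln.score, rc.id, pc.id, identity))
    if not candidates:
        raise SuperpositionError("no confident chain correspondence")
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    mapping: dict[str, str] = {}
    used_pred: set[str] = set()
    for score, ref_id, pred_id, identity in candidates:
        if ref_id in mapping or pred_id in used_pred:
            continue
        mapping[ref_id] = pred_id
        used_pred.add(pred_id)
        logger.debug("chain %s -> %s (score %.1f, identity %.0f%%)",
                     ref_id, pred_id, score, 100 * identity)
    matching = ChainMatching(
        mapping=mapping,
        unmatched_ref=[c.id for c in ref.chains if c.id not in mapping],
        unmatched_pred=[c.id for c in pred.chains if c.id not in used_pred],
    )
    if matching.unmatched_ref or matching.unmatched_pred:
        logger.info("unmatched chains: ref=%s pred=%s",
                    matching.unmatched_ref, matching.unmatched_pred)
    return matching


def match_residues(ref_chain: Chain, pred_chain: Chain) -> list[ResiduePair]:
    """Residue pairs from the aligned (non-gap) columns of the global sequence
    alignment, restricted to residues with CA atoms on both sides."""
    ref_res = ref_chain.polymer_residues()
    pred_res = pred_chain.polymer_residues()
    aln = _align(
        "".join(_THREE_TO_ONE.get(r.name, "X") for r in ref_res),
        "".join(_THREE_TO_ONE.get(r.name, "X") for r in pred_res),
    )
    if aln is None:
        return []
    pairs: list[ResiduePair] = []
    for (r0, r1), (p0, p1) in zip(*aln.aligned):
        for i, j in zip(range(r0, r1), range(p0, p1)):
            rr, pr = ref_res[i], pred_res[j]
            if rr.atom("CA") is None or pr.atom("CA") is None:
                continue
            pairs.append(ResiduePair(
                ref_residue=(ref_chain.id, rr.number, rr.insertion_code),
                pred_residue=(pred_chain.id, pr.number, pr.insertion_code),
            ))
    return pairs


def kabsch_fit(ref_points: np.ndarray, pred_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``pred_points`` onto
    ``ref_points`` (Kabsch, via SVD of the cross-covariance).

    Requires at least 3 non-collinear point pairs.  The reflection branch is
    corrected so the returned rotation has determinant +1.
    """
    ref = np.asarray(ref_points, dtype=float)
    pred = np.asarray(pred_points, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise SuperpositionError("at least 3 point pairs are required")
    ref_c = ref - ref.mean(axis=0)
    pred_c = pred - pred.mean(axis=0)
    # collinear (or coincident) points leave the rotation under-determined
    if np.linalg.matrix_rank(pred_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise SuperpositionError("points are collinear; superposition is under-determined")
    h = pred_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ref.mean(axis=0) - rotation @ pred.mean(axis=0)
    fitted = pred @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return RigidTransform(rotation=rotation, translation=translation, rmsd=rmsd)


def apply_transform(s: Structure, t: RigidTransform) -> Structure:
    """Return a copy of ``s`` with every atom position rotated and translated."""
    out = s.copy()
    for _, res in out.residues():
        for atom in res.atoms:
            atom.position = t.rotation @ atom.position + t.translation
    return out


def superpose_structures(
    ref: Structure,
    pred: Structure,
    prune: bool = False,
    matching: ChainMatching | None = None,
) -> RigidTransform:
    """Full superposition: match chains, pair residues, fit all matched CA
    pairs with one global Kabsch fit.

    With ``prune`` enabled, pairs whose CA-CA distance after fitting exceeds
    2 A are dropped and the fit repeated, up to 5 rounds.  The returned
    transform carries the surviving pairs with their post-fit CA distances.
    """
    if matching is None:
        matching = match_chains(ref, pred)
    pairs: list[ResiduePair] = []
    for ref_id, pred_id in matching.items():
        pairs.extend(match_residues(ref.chain(ref_id), pred.chain(pred_id)))
    if len(pairs) < 3:
        raise SuperpositionError("fewer than 3 matched residue pairs with CA atoms")

    def coords(pair_list: list[ResiduePair]) -> tuple[np.ndarray, np.ndarray]:
        ref_xyz, pred_xyz = [], []
        for p in pair_list:
            rc, rn, ri = p.ref_residue
            pc, pn, pi = p.pred_residue
            rres = next(r for r in ref.chain(rc).residues if (r.number, r.insertion_code) == (rn, ri))
            pres = next(r for r in pred.chain(pc).residues if (r.number, r.insertion_code) == (pn, pi))
            ref_xyz.append(rres.atom("CA").position)
            pred_xyz.append(pres.atom("CA").position)
        return np.array(ref_xyz), np.array(pred_xyz)

    active = pairs
    ref_xyz, pred_xyz = coords(active)
    t = kabsch_fit(ref_xyz, pred_xyz)
    if prune:
        for _ in range(PRUNE_MAX_ITER):
            dists = np.linalg.norm(t.apply_points(pred_xyz) - ref_xyz, axis=1)
            keep = dists <= PRUNE_DISTANCE
            if keep.all() or keep.sum() < 3:
                break
            active = [p for p, k in zip(active, keep) if k]
            ref_xyz, pred_xyz = ref_xyz[keep], pred_xyz[keep]
            t = kabsch_fit(ref_xyz, pred_xyz)
    dists = np.linalg.norm(t.apply_points(pred_xyz) - ref_xyz, axis=1)
    t.pairs = tuple(
        ResiduePair(p.ref_residue, p.pred_residue, float(d))
        for p, d in zip(active, dists)
    )
    logger.info("superposed %d residue pairs, rmsd %.3f A", len(t.pairs), t.rmsd)
    return t
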