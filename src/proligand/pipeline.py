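"""End-to-end pipeline: superpose the predicted backbone onto the reference,
average backbones, graft ligands, and (optionally) score ligand fit against a
density map.

Outputs are written to an output directory: ``complex.pdb`` (merged model
with ligands), ``merge_report.tsv``, ``qscores.tsv`` when a map is supplied,
and ``run.log``.  Log lines carry no timestamps so that two runs with the
same configuration and seed produce byte-identical files.  Any stage failure
aborts the run, removes partial outputs, and reports the stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .backbone_merge import MergeParams, average_backbone, report_summary
from .ligand_transfer import LigandPolicy, is_ligand, transfer_ligands
from .map_qscore import QScoreParams, qscore_selection, read_mrc
from .structure_io import parse_pdb, write_pdb
from .superpose import apply_transform, superpose_structures

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

_LOGGERS = ("proligand.superpose", "proligand.backbone_merge",
            "proligand.ligand_transfer", "proligand.map_qscore", __name__)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    reference: Path
    predicted: Path
    outdir: Path
    density_map: Path | None = None
    merge: MergeParams = field(default_factory=MergeParams)
    ligands: LigandPolicy = field(default_factory=LigandPolicy)
    qscore: QScoreParams = field(default_factory=QScoreParams)
    prune: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference = Path(self.reference)
        self.predicted = Path(self.predicted)
        self.outdir = Path(self.outdir)
        self.density_map = Path(self.density_map) if self.density_map else None

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        merge = MergeParams(**data.pop("merge", {}))
        lig = data.pop("ligands", {})
        for key in ("explicit_include", "explicit_exclude"):
            if key in lig:
                lig[key] = frozenset(lig[key])
        ligands = LigandPolicy(**lig)
        qscore = QScoreParams(**data.pop("qscore", {}))
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(merge=merge, ligands=ligands, qscore=qscore, **data)


@dataclass
class PipelineResult:
    complex_path: Path
    report_path: Path
    qscore_path: Path | None
    log_path: Path
    overall_percent: float
    rmsd: float
    ligand_mean_q: float | None


def _cleanup(paths: list[Path]) -> None:
    for p in paths:
        if p.exists():
            p.unlink()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run superpose -> average -> graft-ligands (-> qscore) and write outputs."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    log_path = cfg.outdir / "run.log"
    complex_path = cfg.outdir / "complex.pdb"
    report_path = cfg.outdir / "merge_report.tsv"
    qscore_path = cfg.outdir / "qscores.tsv"
    outputs = [complex_path, report_path, qscore_path, log_path]
    _cleanup(outputs)

    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    attached = []
    for name in _LOGGERS:
        lg = logging.getLogger(name)
        lg.setLevel(logging.INFO)
        lg.addHandler(handler)
        attached.append(lg)

    stage = "load"
    try:
        logger.info("reference=%s predicted=%s seed=%d",
                    cfg.reference.name, cfg.predicted.name, cfg.seed)
        ref = parse_pdb(cfg.reference.read_text())
        pred = parse_pdb(cfg.predicted.read_text())

        stage = "superpose"
        transform = superpose_structures(ref, pred, prune=cfg.prune)
        pred_fit = apply_transform(pred, transform)

        stage = "merge"
        logger.info("thresholds: default=%g per-chain=%s",
                    cfg.merge.default_threshold, dict(cfg.merge.per_chain_threshold))
        merged, report = average_backbone(ref, pred_fit, cfg.merge)

        stage = "graft-ligands"
        complex_structure = transfer_ligands(ref, merged, cfg.ligands)

        ligand_mean_q = None
        wrote_qscores = False
        if cfg.density_map is not None:
            stage = "qscore"
            density = read_mrc(cfg.density_map)
            rows = []
            all_scores = []
            for chain in complex_structure.chains:
                for res in chain.residues:
                    if not is_ligand(res, cfg.ligands):
                        continue
                    result = qscore_selection(density, res.atoms, cfg.qscore, seed=cfg.seed)
                    rows.append((chain.id, res.number, res.name, len(result.per_atom), result.mean))
                    all_scores.extend(result.per_atom)
            if all_scores:
                ligand_mean_q = float(sum(all_scores) / len(all_scores))
            lines = ["chain\tresidue\tname\tn_atoms\tq_mean"]
            lines += [f"{c}\t{n}\t{r}\t{na}\t{q:.4f}" for c, n, r, na, q in rows]
            if ligand_mean_q is not None:
                lines.append(f"#overall\t\t\t\t{ligand_mean_q:.4f}")
            qscore_path.write_text("\n".join(lines) + "\n")
            wrote_qscores = True
            logger.info("ligand mean q = %s", f"{ligand_mean_q:.4f}" if ligand_mean_q is not None else "n/a")

        stage = "write"
        complex_path.write_text(write_pdb(complex_structure))
        report_path.write_text(report_summary(report))
        logger.info("overall %% averaged = %.2f", report.overall_percent)
    except Exception as exc:
        _cleanup(outputs)
        raise PipelineError(stage, exc) from exc
    finally:
        for lg in attached:
            lg.removeHandler(handler)
        handler.close()
        # the log itself survives only on success; on failure it was removed
    return PipelineResult(
        complex_path=complex_path,
        report_path=report_path,
        qscore_path=qscore_path if wrote_qscores else None,
        log_path=log_path,
        overall_percent=report.overall_percent,
        rmsd=transform.rmsd,
        ligand_mean_q=ligand_mean_q,
    )
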