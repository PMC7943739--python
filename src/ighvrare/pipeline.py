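"""Reproducible simulate -> annotate -> haplotype -> detect -> summarize runs.

One YAML config drives a full run; every source of randomness derives from
the single config seed (fanned out per subject by index offset), so the
same config produces byte-identical detection tables.  Each stage writes
its outputs to the run directory and the final JSON report embeds the
config hash, stage row counts and every detection call.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import cohorts
from .annotate import annotate_sequences, write_annotated_tsv
from .detect import (
    CohortResult,
    DetectionConfig,
    SubjectRepertoire,
    analyze_cohort,
)
from .germline import GermlineDatabase, load_germline_fasta
from .haplotype import haplotype_table
from .locus import example_locus
from .simulate import simulate_repertoire, write_repertoire

__all__ = ["load_config", "run_pipeline", "PipelineError"]

logger = logging.getLogger("ighvrare")

_COHORT_KINDS = ("detection", "haplotyping")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "germline": "bundled",
    "cohort": {
        "kind": "detection",
        "n_subjects": cohorts.DETECTION_N_SUBJECTS,
        "n_carriers": cohorts.DETECTION_N_CARRIERS,
        "n_reads": 20_000,
        "shm_rate": 0.02,
        "seq_error_rate": 0.001,
    },
    "target_alleles": None,  # None = all V alleles
    "thresholds": {},        # overrides of DetectionConfig fields
}


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def validate_config(user: dict) -> dict:
    """Schema-check and merge a user config over the defaults."""
    cfg = {**DEFAULT_CONFIG, **user}
    cfg["cohort"] = {**DEFAULT_CONFIG["cohort"], **(user.get("cohort") or {})}
    cfg["thresholds"] = dict(user.get("thresholds") or {})
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise PipelineError(f"config: unknown top-level key(s) {sorted(unknown)}")
    if cfg["cohort"]["kind"] not in _COHORT_KINDS:
        raise PipelineError(
            f"config: cohort.kind must be one of {_COHORT_KINDS}")
    if not isinstance(cfg["seed"], int):
        raise PipelineError("config: seed must be an integer")
    bad = set(cfg["thresholds"]) - set(DetectionConfig.__dataclass_fields__)
    if bad:
        raise PipelineError(f"config: unknown threshold(s) {sorted(bad)}")
    if cfg["germline"] != "bundled" and not Path(cfg["germline"]).exists():
        raise PipelineError(f"config: germline path {cfg['germline']} not found")
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_germline(cfg: dict) -> GermlineDatabase:
    if cfg["germline"] == "bundled":
        return example_locus()
    return load_germline_fasta(cfg["germline"])


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> CohortResult:
    """Execute the full pipeline into ``out_dir``; returns the cohort result.

    Stages: simulate (per-subject AIRR/FASTA/truth), annotate (extended
    AIRR TSV), haplotype (per-subject table), detect + summarize
    (detection/summary/deletion-candidate TSVs and report.json).
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) \
        else validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out_dir)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run(cfg: dict, out_dir: Path) -> CohortResult:
    db = _load_germline(cfg)
    det_cfg = DetectionConfig(**cfg["thresholds"])
    c = cfg["cohort"]

    # --- simulate
    try:
        if c["kind"] == "detection":
            specs, carrier_truth = cohorts.detection_cohort(
                seed=cfg["seed"], n_subjects=c["n_subjects"],
                n_carriers=c["n_carriers"], n_reads=c["n_reads"],
                shm_rate=c["shm_rate"], seq_error_rate=c["seq_error_rate"])
        else:
            specs, _ = cohorts.haplotyping_cohort(
                seed=cfg["seed"], n_subjects=c["n_subjects"],
                n_reads=c["n_reads"])
            carrier_truth = {}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"simulate: {exc}") from exc

    subjects = []
    stage_counts: dict[str, int] = {}
    for spec in specs:
        try:
            reads, log = simulate_repertoire(spec, db)
            write_repertoire(reads, out_dir / "reads", prefix=spec.subject_id)
            if log.frame_redraw_exhausted:
                logger.warning("%s: %d reads accepted with unmatched frame "
                               "target", spec.subject_id,
                               log.frame_redraw_exhausted)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"simulate[{spec.subject_id}]: {exc}") from exc
        try:
            ann = annotate_sequences(
                [r.read_id for r in reads], [r.sequence for r in reads],
                db, det_cfg.max_mismatch_frac)
            write_annotated_tsv(
                ann, out_dir / f"{spec.subject_id}.annotated.tsv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"annotate[{spec.subject_id}]: {exc}") from exc
        subj = SubjectRepertoire.from_annotated(spec.subject_id, ann, det_cfg)
        try:
            ht = haplotype_table(ann, subj.context, det_cfg.dominance_frac,
                                 det_cfg.min_anchored_reads)
            ht.to_csv(out_dir / f"{spec.subject_id}.haplotypes.tsv",
                      sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"haplotype[{spec.subject_id}]: {exc}") from exc
        subjects.append(subj)
        stage_counts[spec.subject_id] = len(ann)
        logger.info("%s: %d reads annotated, heterozygous=%s",
                    spec.subject_id, len(ann), subj.context.heterozygous)

    # --- detect + summarize
    try:
        result = analyze_cohort(subjects, db, cfg["target_alleles"], det_cfg)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"detect: {exc}") from exc
    result.detection.to_csv(out_dir / "detection.tsv", sep="\t", index=False)
    result.summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    result.deletion_candidates.to_csv(
        out_dir / "deletion_candidates.tsv", sep="\t", index=False)

    report = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "stage_read_counts": stage_counts,
        "carrier_truth": carrier_truth,
        "detection_calls": result.detection.to_dict(orient="records"),
    }
    with open(out_dir / "report.json", "w") as fhj:
        json.dump(report, fhj, indent=2, default=str)
    logger.info("pipeline complete: %d subjects, report at %s",
                len(subjects), out_dir / "report.json")
    return result
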