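"""End-to-end orchestration over a cohort directory.

Per patient: score tumor variant candidates, select the assay-backed panel,
re-verify each panel mutation in the deep-sequenced tumor library, and —
for eligible patients — run barcode consensus, background estimation and
per-mutation calling on every plasma draw, assembling the monitoring
timeline.  Writes panels, calls, timelines, a cohort summary and a manifest
carrying version, parameters and seed.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .calling import (
    VAF_DETECTION_THRESHOLD,
    classify_sample,
    call_mutation,
    estimate_background,
)
from .consensus import (
    DEFAULT_LAYOUT,
    DEFAULT_RULES,
    ConsensusPileup,
    ConsensusRules,
    ReadLayout,
    run_consensus,
)
from .io import (
    calls_to_frame,
    config_hash,
    read_assays,
    read_candidates,
    read_events,
    read_fastq,
    read_tsv,
    standard_meta,
    write_tsv,
)
from .panel import (
    AmpliconAssay,
    PanelMutation,
    patient_eligible,
    score_candidates,
    select_panel,
    verify_in_tumor,
)
from .timeline import PatientTimeline, build_timeline, cohort_summary, timelines_frame

PathLike = Union[str, Path]
logger = logging.getLogger("umi_mrd")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    cohort_dir: Path
    out_dir: Path
    rules: ConsensusRules = DEFAULT_RULES
    layout: ReadLayout = DEFAULT_LAYOUT
    vaf_threshold: float = VAF_DETECTION_THRESHOLD
    verification_threshold: float = 0.01
    background_min_positions: int = 5
    panel_k: int = 8
    make_plots: bool = False
    log_level: str = "INFO"
    seed: Optional[int] = None  # recorded in outputs; no pipeline randomness

    def __post_init__(self) -> None:
        self.cohort_dir = Path(self.cohort_dir)
        self.out_dir = Path(self.out_dir)
        for name in ("vaf_threshold", "verification_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_cohort(cls, cohort_dir: PathLike, out_dir: PathLike, **overrides) -> "PipelineConfig":
        cohort_dir = Path(cohort_dir)
        config_path = cohort_dir / "config.yaml"
        if not config_path.exists():
            raise PipelineError(f"missing cohort config: {config_path}")
        with open(config_path) as handle:
            doc = yaml.safe_load(handle) or {}
        kwargs = dict(
            cohort_dir=cohort_dir,
            out_dir=Path(out_dir),
            vaf_threshold=doc.get("vaf_threshold", VAF_DETECTION_THRESHOLD),
            verification_threshold=doc.get("verification_threshold", 0.01),
            panel_k=doc.get("panel_k", 8),
            seed=doc.get("seed"),
            layout=ReadLayout(
                barcode_length=doc.get("barcode_length", 12),
                spacer=doc.get("spacer", DEFAULT_LAYOUT.spacer),
            ),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def params(self) -> dict:
        return {
            "rules": self.rules.__dict__,
            "layout": {"barcode_length": self.layout.barcode_length, "spacer": self.layout.spacer},
            "vaf_threshold": self.vaf_threshold,
            "verification_threshold": self.verification_threshold,
            "background_min_positions": self.background_min_positions,
            "panel_k": self.panel_k,
        }


@dataclass
class PatientResult:
    patient_id: str
    panel: list[PanelMutation]
    eligible: bool
    timeline: Optional[PatientTimeline] = None
    n_plasma_samples: int = 0


@dataclass
class RunResult:
    patients: list[PatientResult]
    summary: dict
    manifest: dict

    @property
    def timelines(self) -> list[PatientTimeline]:
        return [p.timeline for p in self.patients if p.timeline is not None]


def _assay_pileup(
    fastq_path: Path, assay: AmpliconAssay, config: PipelineConfig
) -> ConsensusPileup:
    if not fastq_path.exists():
        raise PipelineError(f"missing FASTQ: {fastq_path}")
    pileup, stats = run_consensus(
        read_fastq(fastq_path),
        reference=assay.insert,
        assay_id=assay.assay_id,
        layout=config.layout,
        rules=config.rules,
    )
    logger.debug(
        "%s: %d reads, %d families, %d used",
        fastq_path.name,
        stats.n_reads,
        stats.n_families,
        stats.n_families_used,
    )
    return pileup


def _match_assay(mut: PanelMutation, assays: list[AmpliconAssay]) -> Optional[AmpliconAssay]:
    for assay in assays:
        if assay.chrom == mut.candidate.chrom and assay.start <= mut.candidate.position <= assay.end:
            return assay
    return None


def process_patient(patient_id: str, config: PipelineConfig) -> PatientResult:
    pdir = config.cohort_dir / "patients" / patient_id
    if not pdir.exists():
        raise PipelineError(f"missing patient directory: {pdir}")
    candidates = read_candidates(pdir / "candidates.tsv")
    assays = read_assays(pdir / "assays.tsv")
    events = read_events(pdir / "events.tsv")
    samples, _ = read_tsv(pdir / "samples.tsv")

    ranked = score_candidates(candidates)
    backed = []
    for mut in ranked:
        assay = _match_assay(mut, assays)
        if assay is not None:
            mut.assay = assay
            backed.append(mut)
    panel = select_panel(backed, k=config.panel_k)
    logger.info("%s: %d candidates, %d assay-backed, panel of %d",
                patient_id, len(candidates), len(backed), len(panel))

    tumor_rows = samples[samples["sample_type"] == "tumor"]
    tumor_pileups: dict[str, ConsensusPileup] = {}
    for row in tumor_rows.itertuples(index=False):
        for mut in panel:
            assay = mut.assay
            path = pdir / "fastq" / f"{row.sample_id}.{assay.assay_id}.fastq.gz"
            if assay.assay_id not in tumor_pileups and path.exists():
                tumor_pileups[assay.assay_id] = _assay_pileup(path, assay, config)
    panel = verify_in_tumor(panel, tumor_pileups, threshold=config.verification_threshold)
    eligible = patient_eligible(panel)
    if not eligible:
        logger.info("%s: no tumor-verified mutation; ineligible for monitoring",
                    patient_id)
        return PatientResult(patient_id, panel, eligible=False)

    plasma_rows = samples[samples["sample_type"] == "plasma"]
    sample_calls = []
    for row in plasma_rows.itertuples(index=False):
        pileups: dict[str, ConsensusPileup] = {}
        for mut in panel:
            assay = mut.assay
            if assay.assay_id in pileups:
                continue
            path = pdir / "fastq" / f"{row.sample_id}.{assay.assay_id}.fastq.gz"
            pileups[assay.assay_id] = _assay_pileup(path, assay, config)
        backgrounds = {
            assay_id: estimate_background(
                pileup,
                panel_offsets=next(
                    m.assay.target_offsets for m in panel if m.assay.assay_id == assay_id
                ),
                min_positions=config.background_min_positions,
            )
            for assay_id, pileup in pileups.items()
        }
        calls = [
            call_mutation(
                pileups[mut.assay.assay_id],
                mut,
                backgrounds[mut.assay.assay_id],
                vaf_threshold=config.vaf_threshold,
            )
            for mut in panel
        ]
        sample_calls.append(
            classify_sample(str(row.sample_id), patient_id, int(row.day), calls)
        )

    timeline = None
    if sample_calls:
        timeline = build_timeline(sample_calls, events)
    return PatientResult(
        patient_id,
        panel,
        eligible=True,
        timeline=timeline,
        n_plasma_samples=len(sample_calls),
    )


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Run every stage for every cohort patient and write the report bundle.

    On a stage failure, partial outputs and a manifest recording the error
    are retained and :class:`PipelineError` is raised.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    started = time.time()

    with open(config.cohort_dir / "config.yaml") as handle:
        cohort_doc = yaml.safe_load(handle) or {}
    patient_ids = cohort_doc.get("patients", [])
    meta = standard_meta(seed=config.seed, params=config.params())
    manifest = {
        "tool": "umi-mrd",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config.params()),
        "params": config.params(),
        "patients": patient_ids,
        "outputs": [],
        "status": "running",
    }

    results: list[PatientResult] = []
    try:
        from .io import panel_to_frame

        for patient_id in patient_ids:
            results.append(process_patient(patient_id, config))

        panels = pd.concat(
            [panel_to_frame(r.panel).assign(eligible=r.eligible) for r in results],
            ignore_index=True,
        )
        write_tsv(panels, config.out_dir / "panels.tsv", meta)
        manifest["outputs"].append("panels.tsv")

        all_samples = [
            s for r in results if r.timeline for s in r.timeline.samples
        ]
        write_tsv(calls_to_frame(all_samples), config.out_dir / "calls.tsv", meta)
        manifest["outputs"].append("calls.tsv")

        timelines = [r.timeline for r in results if r.timeline is not None]
        write_tsv(timelines_frame(timelines), config.out_dir / "timelines.tsv", meta)
        manifest["outputs"].append("timelines.tsv")

        summary = cohort_summary(timelines) if timelines else {}
        summary["ineligible_patients"] = [
            r.patient_id for r in results if not r.eligible
        ]
        with open(config.out_dir / "summary.json", "w") as handle:
            json.dump({"meta": meta, "summary": summary}, handle, indent=2)
        manifest["outputs"].append("summary.json")

        if config.make_plots:
            from .plotting import timeline_plot

            for tl in timelines:
                out = config.out_dir / f"timeline_{tl.patient_id}.png"
                timeline_plot(tl, out)
                manifest["outputs"].append(out.name)

        manifest["status"] = "ok"
        return RunResult(patients=results, summary=summary, manifest=manifest)
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed:\n%s", traceback.format_exc())
        raise
    finally:
        manifest["runtime_s"] = round(time.time() - started, 2)
        with open(config.out_dir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2)
        logger.removeHandler(handler)
        handler.close()
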