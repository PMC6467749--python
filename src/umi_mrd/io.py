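"""Readers and writers for the pipeline's tabular and sequence formats.

TSV dialect: tab-separated, UTF-8, with ``#key=value`` header lines carrying
tool version, config hash and seed so every output is traceable to the run
that produced it.  FASTQ is Phred+33, optionally gzipped (parsed with
pysam); candidate variants are accepted as VCF (SNVs, with INFO keys for the
COSMIC flag, location and impact) or as a TSV with the same columns.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterator, Optional, Union

import pandas as pd
import pysam

from . import __version__
from .calling import MutationCall, PlasmaSampleCall
from .panel import AmpliconAssay, CandidateMutation, PanelMutation
from .timeline import ClinicalEvent

PathLike = Union[str, Path]


def config_hash(params: dict) -> str:
    """Short stable digest of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def standard_meta(seed: Optional[int] = None, params: Optional[dict] = None) -> dict:
    meta = {"tool": "umi-mrd", "version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if params is not None:
        meta["config_hash"] = config_hash(params)
    return meta


def write_tsv(frame: pd.DataFrame, path: PathLike, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for key, value in (meta or {}).items():
            handle.write(f"#{key}={value}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_tsv(path: PathLike) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(path) as handle:
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
            pos = handle.tell()
            line = handle.readline()
        handle.seek(pos)
        frame = pd.read_csv(handle, sep="\t")
    return frame, meta


def read_fastq(path: PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a (possibly gzipped) FASTQ."""
    with pysam.FastxFile(str(path)) as fastq:
        for entry in fastq:
            yield entry.name, entry.sequence


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = [
    "patient_id",
    "gene",
    "chrom",
    "position",
    "ref",
    "alt",
    "tumor_vaf",
    "in_cosmic",
    "location_class",
    "impact_class",
]


def candidates_to_frame(candidates: list[CandidateMutation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {col: getattr(c, col) for col in _CANDIDATE_COLUMNS}
            for c in candidates
        ],
        columns=_CANDIDATE_COLUMNS,
    )


def read_candidates(path: PathLike, patient_id: Optional[str] = None) -> list[CandidateMutation]:
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return read_candidates_vcf(path, patient_id=patient_id or "unknown")
    frame, _ = read_tsv(path)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            CandidateMutation(
                patient_id=str(row.patient_id),
                gene=str(row.gene),
                chrom=str(row.chrom),
                position=int(row.position),
                ref=str(row.ref),
                alt=str(row.alt),
                tumor_vaf=float(row.tumor_vaf),
                in_cosmic=_as_bool(row.in_cosmic),
                location_class=str(row.location_class),
                impact_class=str(row.impact_class),
            )
        )
    return out


def read_candidates_vcf(path: PathLike, patient_id: str) -> list[CandidateMutation]:
    """SNV candidates from a VCF with INFO keys VAF, COSMIC, LOC, IMPACT."""
    from cyvcf2 import VCF

    out = []
    for variant in VCF(str(path)):
        if len(variant.REF) != 1 or not variant.ALT or len(variant.ALT[0]) != 1:
            continue  # SNVs only
        info = variant.INFO
        out.append(
            CandidateMutation(
                patient_id=patient_id,
                gene=str(info.get("GENE", "")) or ".",
                chrom=str(variant.CHROM),
                position=int(variant.POS),
                ref=variant.REF,
                alt=variant.ALT[0],
                tumor_vaf=float(info.get("VAF", 0.0)),
                in_cosmic=info.get("COSMIC") is not None,
                location_class=str(info.get("LOC", "exonic")),
                impact_class=str(info.get("IMPACT", "none")),
            )
        )
    return out


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes"}
    return bool(value)


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------


def assays_to_frame(assays: list[AmpliconAssay]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "assay_id": a.assay_id,
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "insert": a.insert,
                "target_offsets": ",".join(map(str, a.target_offsets)),
            }
            for a in assays
        ],
        columns=["assay_id", "chrom", "start", "end", "insert", "target_offsets"],
    )


def read_assays(path: PathLike) -> list[AmpliconAssay]:
    frame, _ = read_tsv(path)
    out = []
    for row in frame.itertuples(index=False):
        offsets = (
            tuple(int(x) for x in str(row.target_offsets).split(",") if x)
            if not pd.isna(row.target_offsets)
            else ()
        )
        out.append(
            AmpliconAssay(
                assay_id=str(row.assay_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                insert=str(row.insert),
                target_offsets=offsets,
            )
        )
    return out


# ---------------------------------------------------------------------------
# panels, events, calls
# ---------------------------------------------------------------------------


def panel_to_frame(panel: list[PanelMutation]) -> pd.DataFrame:
    rows = []
    for m in panel:
        row = {col: getattr(m.candidate, col) for col in _CANDIDATE_COLUMNS}
        row["selection_score"] = m.selection_score
        row["verified_in_tumor"] = m.verified_in_tumor
        row["assay_id"] = m.assay.assay_id if m.assay else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS + ["selection_score", "verified_in_tumor", "assay_id"])


def read_panel(path: PathLike, assays: Optional[dict[str, AmpliconAssay]] = None) -> list[PanelMutation]:
    frame, _ = read_tsv(path)
    out = []
    for row in frame.itertuples(index=False):
        candidate = CandidateMutation(
            patient_id=str(row.patient_id),
            gene=str(row.gene),
            chrom=str(row.chrom),
            position=int(row.position),
            ref=str(row.ref),
            alt=str(row.alt),
            tumor_vaf=float(row.tumor_vaf),
            in_cosmic=_as_bool(row.in_cosmic),
            location_class=str(row.location_class),
            impact_class=str(row.impact_class),
        )
        assay = None
        if assays and str(row.assay_id) in assays:
            assay = assays[str(row.assay_id)]
        verified = row.verified_in_tumor
        out.append(
            PanelMutation(
                candidate=candidate,
                selection_score=float(row.selection_score),
                verified_in_tumor=None if pd.isna(verified) else _as_bool(verified),
                assay=assay,
            )
        )
    return out


def events_to_frame(events: list[ClinicalEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"patient_id": e.patient_id, "event_type": e.event_type, "day": e.day} for e in events],
        columns=["patient_id", "event_type", "day"],
    )


def read_events(path: PathLike) -> list[ClinicalEvent]:
    frame, _ = read_tsv(path)
    return [
        ClinicalEvent(str(r.patient_id), str(r.event_type), int(r.day))
        for r in frame.itertuples(index=False)
    ]


def calls_to_frame(samples: list[PlasmaSampleCall]) -> pd.DataFrame:
    rows = []
    for sample in samples:
        for call in sample.mutation_calls:
            c = call.mutation.candidate
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "patient_id": sample.patient_id,
                    "collection_day": sample.collection_day,
                    "assay_id": call.mutation.assay.assay_id if call.mutation.assay else "",
                    "gene": c.gene,
                    "chrom": c.chrom,
                    "position": c.position,
                    "ref": c.ref,
                    "alt": c.alt,
                    "vaf": call.vaf,
                    "informative_families": call.informative_families,
                    "background_threshold": call.background_threshold,
                    "detected": call.detected,
                    "sample_positive": sample.sample_positive,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "patient_id",
            "collection_day",
            "assay_id",
            "gene",
            "chrom",
            "position",
            "ref",
            "alt",
            "vaf",
            "informative_families",
            "background_threshold",
            "detected",
            "sample_positive",
        ],
    )


def read_calls(path: PathLike) -> list[PlasmaSampleCall]:
    """Rebuild sample calls from a calls TSV (for the monitor stage)."""
    frame, _ = read_tsv(path)
    samples: list[PlasmaSampleCall] = []
    for (sample_id, patient_id, day), group in frame.groupby(
        ["sample_id", "patient_id", "collection_day"], sort=False
    ):
        calls = []
        any_positive = False
        any_evaluable = False
        for row in group.itertuples(index=False):
            candidate = CandidateMutation(
                patient_id=str(patient_id),
                gene=str(row.gene),
                chrom=str(row.chrom),
                position=int(row.position),
                ref=str(row.ref),
                alt=str(row.alt),
                tumor_vaf=1.0,
                in_cosmic=False,
            )
            detected = None if pd.isna(row.detected) else _as_bool(row.detected)
            vaf = None if pd.isna(row.vaf) else float(row.vaf)
            if detected is not None:
                any_evaluable = True
                any_positive = any_positive or detected
            calls.append(
                MutationCall(
                    mutation=PanelMutation(candidate, selection_score=0.0),
                    vaf=vaf,
                    informative_families=int(row.informative_families),
                    background_threshold=float(row.background_threshold),
                    detected=detected,
                )
            )
        samples.append(
            PlasmaSampleCall(
                sample_id=str(sample_id),
                patient_id=str(patient_id),
                collection_day=int(day),
                mutation_calls=tuple(calls),
                sample_positive=any_positive if any_evaluable else None,
            )
        )
    return samples
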