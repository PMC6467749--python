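"""Synthetic monitoring cohort mirroring the study's structure.

Eight patients, 2-8 amplicon assays each, a deep-sequenced tumor library
per assay, and baseline plus longitudinal plasma draws at scripted true
VAFs.  The script encodes the clinically interesting shapes: a
baseline-negative early-stage patient whose ctDNA appears a year later and
precedes clinical recurrence by 156 days (HN04), a non-clearing patient
whose 3-week draw anticipates recurrence by 22 days (HN02), a patient whose
first positive draw follows diagnosed recurrence by 13 days (HN01), two
distant-metastasis patients negative in follow-up plasma, and a patient
with no tumor-verified mutations who is ineligible for monitoring (HN07).
All values are synthetic reconstructions of the narrative, not data.

Every simulation seed derives from the single cohort seed, so regeneration
is byte-identical (gzip members are written with a fixed mtime).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .consensus import DEFAULT_LAYOUT, ReadLayout, decode_seq
from .io import (
    assays_to_frame,
    candidates_to_frame,
    events_to_frame,
    standard_meta,
    write_tsv,
)
from .panel import AmpliconAssay, CandidateMutation
from .simulate import SimulationConfig, VariantSpec, simulate_run
from .timeline import ClinicalEvent

PathLike = Union[str, Path]

# study-condition scale for one plasma library: ~10 ng cell-free DNA input
# and ~20 raw reads per barcode family
PLASMA_MOLECULES = 3000
PLASMA_READS = 60000
TUMOR_MOLECULES = 1500
TUMOR_READS = 30000

GENE_LOCI = {
    "TP53": ("chr17", 7578406),
    "NSD1": ("chr5", 176637320),
    "ATM": ("chr11", 108121426),
    "CDK8": ("chr13", 26970133),
    "ARID1B": ("chr6", 157150547),
    "FANCA": ("chr16", 89849480),
    "RASA1a": ("chr5", 86640212),
    "RASA1b": ("chr5", 86669954),
    "SMARCA4": ("chr19", 11105260),
    "XRCC2": ("chr7", 152352148),
    "BCL10": ("chr1", 85741790),
    "PIK3CA": ("chr3", 178936091),
    "NOTCH1": ("chr9", 139399347),
    "CASP8": ("chr2", 202149589),
    "FAT1": ("chr4", 187539478),
    "KMT2D": ("chr12", 49433924),
    "CDKN2A": ("chr9", 21971120),
    "HRAS": ("chr11", 534288),
}


@dataclass(frozen=True)
class GeneScript:
    """One panel mutation: candidate annotation + assay + tumor truth."""

    label: str  # unique within patient; keys the plasma VAF script
    assay_len: int = 72
    tumor_vaf: float = 0.15  # claimed in the variant-call table
    tumor_sim_vaf: Optional[float] = None  # truth in the tumor library
    in_cosmic: bool = True
    location: str = "exonic"
    impact: str = "high"

    @property
    def gene(self) -> str:
        return self.label.rstrip("ab") if self.label.startswith("RASA1") else self.label

    @property
    def sim_vaf(self) -> float:
        return self.tumor_vaf if self.tumor_sim_vaf is None else self.tumor_sim_vaf


@dataclass(frozen=True)
class PatientScript:
    patient_id: str
    panel: tuple[GeneScript, ...]
    plasma: tuple[tuple[str, int, dict[str, float]], ...]  # (sample, day, vafs)
    events: tuple[tuple[str, int], ...]
    n_decoys: int = 3


COHORT: tuple[PatientScript, ...] = (
    PatientScript(
        "HN01",
        panel=(
            GeneScript("TP53", tumor_vaf=0.28),
            GeneScript("PIK3CA", tumor_vaf=0.14, impact="moderate"),
            GeneScript("NOTCH1", tumor_vaf=0.09, impact="moderate"),
        ),
        plasma=(
            ("B", -1, {"TP53": 0.010, "PIK3CA": 0.006, "NOTCH1": 0.0}),
            ("P21", 21, {}),
            ("P180", 180, {}),
            ("P300", 300, {}),
            ("P397", 397, {"TP53": 0.004}),
        ),
        events=(
            ("treatment", 0),
            ("adjuvant_therapy", 40),
            ("clinical_recurrence_local", 384),
            ("last_followup", 430),
        ),
    ),
    PatientScript(
        "HN02",
        panel=(
            GeneScript("ARID1B", tumor_vaf=0.22),
            GeneScript("ATM", tumor_vaf=0.26),
            GeneScript("CDK8", tumor_vaf=0.18),
            GeneScript("FANCA", assay_len=95, tumor_vaf=0.12, impact="moderate"),
            GeneScript("RASA1a", tumor_vaf=0.16, impact="moderate"),
            GeneScript("RASA1b", tumor_vaf=0.11, location="splice", impact="moderate"),
        ),
        plasma=(
            (
                "B",
                -1,
                {
                    "ARID1B": 0.009,
                    "ATM": 0.020,
                    "CDK8": 0.012,
                    "FANCA": 0.005,
                    "RASA1a": 0.008,
                    "RASA1b": 0.006,
                },
            ),
            ("P21", 21, {"ATM": 0.0015, "CDK8": 0.0012}),
        ),
        events=(
            ("treatment", 0),
            ("clinical_recurrence_local", 43),
            ("last_followup", 120),
        ),
    ),
    PatientScript(
        "HN03",
        panel=(
            GeneScript("CASP8", tumor_vaf=0.24),
            GeneScript("FAT1", tumor_vaf=0.17, impact="moderate"),
        ),
        plasma=(
            ("B", 0, {"CASP8": 0.008, "FAT1": 0.005}),
            ("P21", 21, {}),
            ("P90", 90, {}),
            ("P365", 365, {}),
        ),
        events=(("treatment", 0), ("last_followup", 540)),
    ),
    PatientScript(
        "HN04",
        panel=(
            GeneScript("NSD1", tumor_vaf=0.30),
            GeneScript("TP53", tumor_vaf=0.25),
        ),
        plasma=(
            ("B", -1, {}),
            ("P21", 21, {}),
            ("P90", 90, {}),
            ("P180", 180, {}),
            ("P365", 365, {"NSD1": 0.0021, "TP53": 0.0033}),
            ("P548", 548, {"NSD1": 0.0030, "TP53": 0.0040}),
        ),
        events=(
            ("treatment", 0),
            ("clinical_recurrence_local", 521),
            ("last_followup", 560),
        ),
    ),
    PatientScript(
        "HN05",
        panel=(
            GeneScript("SMARCA4", tumor_vaf=0.21),
            GeneScript("TP53", tumor_vaf=0.27),
            GeneScript("XRCC2", tumor_vaf=0.08, impact="moderate"),
        ),
        plasma=(
            ("B", -1, {"SMARCA4": 0.006, "TP53": 0.012, "XRCC2": 0.004}),
            ("P42", 42, {}),
            ("P180", 180, {}),
        ),
        events=(
            ("treatment", 0),
            ("adjuvant_therapy", 35),
            ("clinical_recurrence_distant", 287),
            ("last_followup", 400),
        ),
    ),
    PatientScript(
        "HN06",
        panel=(
            GeneScript("BCL10", tumor_vaf=0.13),
            GeneScript("TP53", tumor_vaf=0.29),
        ),
        plasma=(
            ("B", -1, {"BCL10": 0.009, "TP53": 0.015}),
            ("P21", 21, {}),
            ("P120", 120, {}),
        ),
        events=(
            ("treatment", 0),
            ("adjuvant_therapy", 30),
            ("clinical_recurrence_distant", 208),
            ("last_followup", 300),
        ),
    ),
    PatientScript(
        "HN07",
        # claimed in the tumor variant calls but absent from the deep-sequenced
        # tumor library (FFPE artifacts): verification fails, patient ineligible
        panel=(
            GeneScript("KMT2D", tumor_vaf=0.07, tumor_sim_vaf=0.0, impact="moderate"),
            GeneScript("CDKN2A", tumor_vaf=0.06, tumor_sim_vaf=0.0),
        ),
        plasma=(),
        events=(("treatment", 0), ("last_followup", 365)),
    ),
    PatientScript(
        "HN08",
        panel=(
            GeneScript("TP53", tumor_vaf=0.26),
            GeneScript("HRAS", tumor_vaf=0.19),
            GeneScript("NOTCH1", tumor_vaf=0.12, impact="moderate"),
            GeneScript("FAT1", tumor_vaf=0.05, in_cosmic=False, impact="low"),
        ),
        plasma=(
            # one panel mutation undetectable at baseline (true VAF 0)
            ("B", -1, {"TP53": 0.011, "HRAS": 0.007, "NOTCH1": 0.005, "FAT1": 0.0}),
            ("P21", 21, {}),
            ("P180", 180, {}),
            ("P365", 365, {}),
        ),
        events=(("treatment", 0), ("last_followup", 540)),
    ),
)


def _derive_seed(master_seed: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))


def _build_assay(
    master_seed: int, script: GeneScript
) -> tuple[AmpliconAssay, CandidateMutation, str]:
    """Deterministic assay insert + candidate record for one panel gene.

    Seeded by locus, not patient, so a shared gene locus has one insert
    sequence across the cohort."""
    locus_index = list(GENE_LOCI).index(script.label)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed), 900, locus_index, script.assay_len])
    )
    length = script.assay_len
    insert_codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    insert = decode_seq(insert_codes)
    offset = length // 2  # 1-based target offset
    ref = insert[offset - 1]
    alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
    chrom, center = GENE_LOCI[script.label]
    start = center - offset + 1
    assay = AmpliconAssay(
        assay_id=f"{script.label}",
        chrom=chrom,
        start=start,
        end=start + length - 1,
        insert=insert,
        target_offsets=(offset,),
    )
    candidate = CandidateMutation(
        patient_id="",  # filled by caller
        gene=script.gene,
        chrom=chrom,
        position=center,
        ref=ref,
        alt=alt,
        tumor_vaf=script.tumor_vaf,
        in_cosmic=script.in_cosmic,
        location_class=script.location,
        impact_class=script.impact,
    )
    return assay, candidate, alt


def _decoy_candidates(
    master_seed: int, patient_id: str, patient_index: int, n: int
) -> list[CandidateMutation]:
    """Low-priority candidates that never make the panel (no assay designed)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed), 901, patient_index])
    )
    out = []
    for j in range(n):
        ref, alt = "AC" if j % 2 else "GT"
        out.append(
            CandidateMutation(
                patient_id=patient_id,
                gene=f"DECOY{j + 1}",
                chrom=f"chr{int(rng.integers(1, 23))}",
                position=int(rng.integers(1_000_000, 50_000_000)),
                ref=ref,
                alt=alt,
                tumor_vaf=float(rng.uniform(0.02, 0.045)),
                in_cosmic=False,
                location_class="intronic",
                impact_class="none",
            )
        )
    return out


def _write_fastq_gz(path: Path, records: list[str]) -> None:
    """Deterministic gzip (fixed mtime, no filename field)."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0, compresslevel=1) as gz:
            gz.write("".join(records).encode("ascii"))


def _simulate_to_fastq(
    config: SimulationConfig, path: Path, layout: ReadLayout
) -> dict:
    truth, batch = simulate_run(config, layout)
    length = batch.read_matrix.shape[1]
    qual = chr(30 + 33) * length
    records = [
        f"@{batch.read_id(i)}\n{decode_seq(batch.read_matrix[i])}\n+\n{qual}\n"
        for i in range(batch.n_reads)
    ]
    _write_fastq_gz(path, records)
    return {
        "true_vaf": config.variants[0].vaf if config.variants else 0.0,
        "realized_vaf": float(truth.realized_vafs[0]) if config.variants else 0.0,
        "n_molecules": config.n_molecules,
        "reads": config.reads_to_sample,
        "seed": config.seed,
    }


def generate_fixtures(
    seed: int,
    outdir: PathLike,
    scale: float = 1.0,
    patients: Optional[Sequence[str]] = None,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> dict:
    """Write the synthetic cohort to ``outdir``; returns a manifest dict.

    ``scale`` multiplies molecule and read counts (for quick smoke runs);
    ``patients`` restricts generation to a subset of patient ids.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = [
        p for p in COHORT if patients is None or p.patient_id in set(patients)
    ]
    if patients is not None and len(selected) != len(set(patients)):
        known = {p.patient_id for p in COHORT}
        raise ValueError(f"unknown patient ids: {sorted(set(patients) - known)}")

    def scaled(value: int, floor: int) -> int:
        return max(int(round(value * scale)), floor)

    truth_rows = []
    meta = standard_meta(seed=seed)
    for pi, script in ((i, p) for i, p in enumerate(COHORT) if p in selected):
        pdir = outdir / "patients" / script.patient_id
        (pdir / "fastq").mkdir(parents=True, exist_ok=True)

        assays: list[AmpliconAssay] = []
        candidates: list[CandidateMutation] = []
        alts: dict[str, str] = {}
        for gi, gene_script in enumerate(script.panel):
            assay, cand, alt = _build_assay(seed, gene_script)
            assays.append(assay)
            candidates.append(
                CandidateMutation(
                    **{**cand.__dict__, "patient_id": script.patient_id}
                )
            )
            alts[gene_script.label] = alt
        candidates += _decoy_candidates(seed, script.patient_id, pi, script.n_decoys)

        write_tsv(candidates_to_frame(candidates), pdir / "candidates.tsv", meta)
        write_tsv(assays_to_frame(assays), pdir / "assays.tsv", meta)
        events = [
            ClinicalEvent(script.patient_id, etype, day)
            for etype, day in script.events
        ]
        write_tsv(events_to_frame(events), pdir / "events.tsv", meta)

        sample_rows = [{"sample_id": "T", "sample_type": "tumor", "day": ""}]
        for sample_id, day, _vafs in script.plasma:
            sample_rows.append(
                {"sample_id": sample_id, "sample_type": "plasma", "day": day}
            )
        write_tsv(pd.DataFrame(sample_rows), pdir / "samples.tsv", meta)

        # tumor library per assay
        for gi, (gene_script, assay) in enumerate(zip(script.panel, assays)):
            offset = assay.target_offsets[0]
            config = SimulationConfig(
                assay_id=assay.assay_id,
                reference_insert=assay.insert,
                variants=[
                    VariantSpec(
                        offset,
                        assay.insert[offset - 1],
                        alts[gene_script.label],
                        gene_script.sim_vaf,
                    )
                ],
                n_molecules=scaled(TUMOR_MOLECULES, 50),
                reads_to_sample=scaled(TUMOR_READS, 1000),
                seed=_derive_seed(seed, 1, pi, gi),
            )
            path = pdir / "fastq" / f"T.{assay.assay_id}.fastq.gz"
            info = _simulate_to_fastq(config, path, layout)
            truth_rows.append(
                {
                    "patient_id": script.patient_id,
                    "sample_id": "T",
                    "assay_id": assay.assay_id,
                    **info,
                }
            )

        # plasma libraries
        for si, (sample_id, _day, vafs) in enumerate(script.plasma):
            for gi, (gene_script, assay) in enumerate(zip(script.panel, assays)):
                offset = assay.target_offsets[0]
                vaf = vafs.get(gene_script.label, 0.0)
                config = SimulationConfig(
                    assay_id=assay.assay_id,
                    reference_insert=assay.insert,
                    variants=[
                        VariantSpec(
                            offset,
                            assay.insert[offset - 1],
                            alts[gene_script.label],
                            vaf,
                        )
                    ],
                    n_molecules=scaled(PLASMA_MOLECULES, 50),
                    reads_to_sample=scaled(PLASMA_READS, 1000),
                    seed=_derive_seed(seed, 2, pi, si, gi),
                )
                path = pdir / "fastq" / f"{sample_id}.{assay.assay_id}.fastq.gz"
                info = _simulate_to_fastq(config, path, layout)
                truth_rows.append(
                    {
                        "patient_id": script.patient_id,
                        "sample_id": sample_id,
                        "assay_id": assay.assay_id,
                        **info,
                    }
                )

    (outdir / "truth").mkdir(exist_ok=True)
    write_tsv(pd.DataFrame(truth_rows), outdir / "truth" / "simulations.tsv", meta)

    config_doc = {
        "seed": int(seed),
        "scale": float(scale),
        "patients": [p.patient_id for p in selected],
        "barcode_length": layout.barcode_length,
        "spacer": layout.spacer,
        "vaf_threshold": 0.0005,
        "verification_threshold": 0.01,
        "panel_k": 8,
    }
    with open(outdir / "config.yaml", "w") as handle:
        yaml.safe_dump(config_doc, handle, sort_keys=True)
    return {"outdir": str(outdir), **config_doc, "n_simulations": len(truth_rows)}
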