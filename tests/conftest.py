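import numpy as np
import pytest

from umi_mrd import (
    BarcodeFamily,
    ConsensusPileup,
    SimulationConfig,
    TaggedRead,
)

BARCODE_A = "AAAACCCCGGGG"
BARCODE_B = "TTTTGGGGCCCC"
BARCODE_C = "ACACACACACAC"


def make_family(
    size: int,
    alt_count: int,
    *,
    barcode: str = BARCODE_A,
    assay_id: str = "assay1",
    insert: str = "ACGTACG",
    alt_offset: int = 5,  # reference A at this offset
    alt_base: str = "T",
) -> BarcodeFamily:
    """Family of `size` reads, `alt_count` of which carry alt at alt_offset."""
    reads = []
    for i in range(size):
        seq = list(insert)
        if i < alt_count:
            seq[alt_offset - 1] = alt_base
        reads.append(
            TaggedRead(
                read_id=f"r{i}", barcode=barcode, insert="".join(seq), assay_id=assay_id
            )
        )
    return BarcodeFamily(barcode=barcode, assay_id=assay_id, member_reads=reads)


def make_pileup(
    informative: int,
    alt_families: int,
    *,
    reference: str = "ACGTACG",
    position: int = 5,  # reference A here
    alt_base: str = "T",
    assay_id: str = "assay1",
) -> ConsensusPileup:
    """Pileup whose every position is unanimous except `position`, where
    `alt_families` of `informative` families call the alternate base."""
    length = len(reference)
    counts = np.zeros((length, 5), dtype=np.int64)
    ref_codes = ["ACGTN".index(b) for b in reference]
    for i, code in enumerate(ref_codes):
        counts[i, code] = informative
    assert alt_base != reference[position - 1]
    alt_code = "ACGTN".index(alt_base)
    counts[position - 1, ref_codes[position - 1]] = informative - alt_families
    counts[position - 1, alt_code] = alt_families
    return ConsensusPileup(assay_id=assay_id, reference=reference, counts=counts)


def small_sim_config(**overrides) -> SimulationConfig:
    base = dict(
        assay_id="assay1",
        reference_insert="ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT",
        variants=[(10, "C", "T", 0.1)],
        n_molecules=300,
        reads_to_sample=6000,
        pcr_cycles=10,
        polymerase_error_rate=1e-5,
        sequencing_error_rate=0.001,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def mini_cohort(tmp_path_factory):
    """Reduced-scale synthetic cohort (structure checks and CLI smoke)."""
    from umi_mrd.fixtures import generate_fixtures

    outdir = tmp_path_factory.mktemp("cohort_mini")
    manifest = generate_fixtures(7, outdir, scale=0.1)
    return outdir, manifest


@pytest.fixture(scope="session")
def full_cohort_run(tmp_path_factory):
    """Study-condition cohort plus a full pipeline run over it."""
    from umi_mrd.fixtures import generate_fixtures
    from umi_mrd.pipeline import PipelineConfig, run_pipeline

    cohort = tmp_path_factory.mktemp("cohort_full")
    generate_fixtures(7, cohort, scale=1.0)
    out = tmp_path_factory.mktemp("run_full")
    result = run_pipeline(PipelineConfig.from_cohort(cohort, out))
    return cohort, out, result
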