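"""Barcode extraction, family grouping, consensus rules, pileups.

The consensus/pileup implementation is checked against an independent
brute-force oracle that applies the two agreement thresholds literally,
position by position.
"""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umi_mrd import (
    ConsensusRules,
    ReadRejected,
    TaggedRead,
    build_pileup,
    consensus_family,
    extract_barcode,
    extract_tagged_reads,
    group_families,
    run_consensus,
    simulate_run,
    variant_vaf,
)
from umi_mrd.consensus import DEFAULT_LAYOUT, decode_seq

from conftest import BARCODE_A, BARCODE_B, BARCODE_C, make_family, small_sim_config


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


class TestExtractBarcode:
    def test_simulator_round_trip_recovers_true_barcodes(self):
        config = small_sim_config(sequencing_error_rate=0.0)
        truth, batch = simulate_run(config)
        truth_barcodes = set(truth.barcodes())
        for read_id, seq in list(batch.iter_records())[:200]:
            tagged = extract_barcode(read_id, seq)
            assert tagged.barcode in truth_barcodes
            assert len(tagged.barcode) == 12

    def test_default_barcode_length_is_twelve(self):
        assert DEFAULT_LAYOUT.barcode_length == 12

    def test_short_read_rejected(self):
        with pytest.raises(ReadRejected) as err:
            extract_barcode("r", "ACGTA")
        assert err.value.reason == "too_short"

    def test_spacer_tolerates_one_mismatch_not_two(self):
        insert = "ACGTACG"
        good = BARCODE_A + DEFAULT_LAYOUT.spacer + insert
        one = list(good)
        one[12] = "T" if one[12] != "T" else "A"
        two = list(one)
        two[13] = "T" if two[13] != "T" else "A"
        assert extract_barcode("r", "".join(one)).insert == insert
        accepted, rejected = extract_tagged_reads([("r", "".join(two))])
        assert not accepted and rejected == Counter({"spacer_mismatch": 1})


class TestGroupFamilies:
    def test_counting_example(self):
        reads = [
            TaggedRead(f"r{i}", bc, "ACGT", "a1")
            for bc in (BARCODE_A, BARCODE_B, BARCODE_C)
            for i in range(10)
        ]
        families = group_families(reads)
        assert len(families) == 3
        assert all(f.size == 10 for f in families.values())

    def test_empty_stream(self):
        assert group_families([]) == {}

    def test_family_sizes_conserve_accepted_reads(self):
        config = small_sim_config()
        _, batch = simulate_run(config)
        accepted, rejected = extract_tagged_reads(
            batch.iter_records(), assay_id="assay1"
        )
        families = group_families(accepted)
        assert sum(f.size for f in families.values()) == len(accepted)
        assert len(accepted) + sum(rejected.values()) == batch.n_reads


# ---------------------------------------------------------------------------
# family consensus: the agreement rules
# ---------------------------------------------------------------------------


class TestConsensusRules:
    @pytest.mark.parametrize(
        "size, alt_count, expected_base",
        [
            (15, 15, "T"),  # unanimous small family reports the variant
            (15, 14, "N"),  # 14/15 < 100%: suppressed
            (20, 20, "T"),  # top of the unanimity band
            (20, 19, "N"),
            (25, 23, "T"),  # 92% >= 90%
            (25, 22, "N"),  # 88% < 90%
            (30, 27, "T"),  # exactly 90%: "at least 90%" is inclusive
            (30, 26, "N"),
            (21, 19, "T"),  # 19/21 = 90.5%
            (10, 10, "T"),  # smallest usable family
        ],
    )
    def test_agreement_thresholds(self, size, alt_count, expected_base):
        cons = consensus_family(make_family(size, alt_count))
        assert cons is not None
        assert cons.consensus_sequence[4] == expected_base
        # positions without the variant stay reference
        assert cons.consensus_sequence[0] == "A"

    def test_family_below_minimum_size_excluded(self):
        assert consensus_family(make_family(9, 9)) is None

    def test_rules_validation(self):
        with pytest.raises(ValueError):
            ConsensusRules(min_family_size=30, small_family_max=20)
        with pytest.raises(ValueError):
            ConsensusRules(large_family_fraction=0.4)


# ---------------------------------------------------------------------------
# pileups and VAF
# ---------------------------------------------------------------------------


class TestPileup:
    def test_maf_example_two_alt_in_thousand(self):
        cons = [consensus_family(make_family(15, 15))] * 2 + [
            consensus_family(make_family(15, 0))
        ] * 998
        pileup = build_pileup(cons, reference="ACGTACG")
        assert pileup.informative_families[4] == 1000
        assert pileup.minor_allele_frequency()[4] == pytest.approx(0.002)

    def test_all_n_position_has_undefined_maf(self):
        cons = [consensus_family(make_family(15, 14))] * 5
        pileup = build_pileup(cons, reference="ACGTACG")
        assert pileup.informative_families[4] == 0
        assert np.isnan(pileup.minor_allele_frequency()[4])
        assert variant_vaf(pileup, 5, "T") is None

    def test_mixed_assays_rejected(self):
        a = consensus_family(make_family(15, 0, assay_id="a1"))
        b = consensus_family(make_family(15, 0, assay_id="a2", barcode=BARCODE_B))
        with pytest.raises(ValueError, match="mixed assays"):
            build_pileup([a, b], reference="ACGTACG")

    @pytest.mark.parametrize(
        "alt, informative, expected",
        [(3, 1500, 0.002), (0, 1500, 0.0)],
    )
    def test_variant_vaf_arithmetic(self, alt, informative, expected):
        from conftest import make_pileup

        pileup = make_pileup(informative, alt, alt_base="T", position=5)
        assert variant_vaf(pileup, 5, "T") == pytest.approx(expected)

    def test_adding_alt_family_never_decreases_vaf(self):
        from conftest import make_pileup

        vafs = [
            variant_vaf(make_pileup(1000 + k, k, alt_base="T", position=5), 5, "T")
            for k in range(0, 30)
        ]
        assert all(b >= a for a, b in zip(vafs, vafs[1:]))


# ---------------------------------------------------------------------------
# brute-force oracle equivalence (object path and vectorised path)
# ---------------------------------------------------------------------------

REFERENCE = "ACGTA"


def brute_force_pileup(reads: list[tuple[str, str]]) -> dict[int, Counter]:
    """Literal re-implementation: group by barcode, apply the two
    agreement thresholds per position, tally consensus calls."""
    families: dict[str, list[str]] = {}
    for barcode, insert in reads:
        families.setdefault(barcode, []).append(insert)
    tally: dict[int, Counter] = {pos: Counter() for pos in range(len(REFERENCE))}
    for members in families.values():
        n = len(members)
        if n < 10:
            continue
        for pos in range(len(REFERENCE)):
            counts = Counter(m[pos] for m in members)
            base, count = max(
                ((b, counts.get(b, 0)) for b in "ACGT"), key=lambda x: x[1]
            )
            if n <= 20:
                ok = count == n
            else:
                ok = count / n >= 0.9
            tally[pos][base if ok else "N"] += 1
    return tally


@st.composite
def read_sets(draw):
    barcodes = [BARCODE_A, BARCODE_B, BARCODE_C]
    n = draw(st.integers(0, 50))
    reads = []
    for _ in range(n):
        barcode = draw(st.sampled_from(barcodes))
        insert = draw(
            st.text(alphabet="ACGTN", min_size=len(REFERENCE), max_size=len(REFERENCE))
        )
        reads.append((barcode, insert))
    return reads


@settings(max_examples=150, deadline=None, derandomize=True)
@given(read_sets())
def test_consensus_pileup_matches_bruteforce_oracle(reads):
    oracle = brute_force_pileup(reads)

    # object path
    tagged = [
        TaggedRead(f"r{i}", bc, ins, "a1") for i, (bc, ins) in enumerate(reads)
    ]
    consensuses = [
        c
        for fam in group_families(tagged).values()
        if (c := consensus_family(fam)) is not None
    ]
    if consensuses:
        pileup = build_pileup(consensuses, REFERENCE)
        for pos in range(len(REFERENCE)):
            for base_idx, base in enumerate("ACGTN"):
                assert pileup.counts[pos, base_idx] == oracle[pos][base]

    # vectorised path over raw sequences (N-free inserts only: an N in a
    # barcode would regroup under the packed code, matching exact grouping)
    raw = [
        (f"r{i}", bc + DEFAULT_LAYOUT.spacer + ins)
        for i, (bc, ins) in enumerate(reads)
    ]
    fast_pileup, stats = run_consensus(raw, REFERENCE, "a1")
    for pos in range(len(REFERENCE)):
        for base_idx, base in enumerate("ACGTN"):
            assert fast_pileup.counts[pos, base_idx] == oracle[pos][base]
    assert stats.n_reads == len(reads)


def test_fast_path_equals_object_path_on_simulated_run():
    config = small_sim_config(sequencing_error_rate=0.002)
    _, batch = simulate_run(config)
    fast, _ = run_consensus(batch, config.reference_insert, "assay1")

    tagged, _rej = extract_tagged_reads(batch.iter_records(), assay_id="assay1")
    consensuses = [
        c
        for fam in group_families(tagged).values()
        if (c := consensus_family(fam)) is not None
    ]
    slow = build_pileup(consensuses, config.reference_insert)
    assert np.array_equal(fast.counts, slow.counts)


def test_vaf_recovery_against_ground_truth():
    # estimated consensus VAF within 3 binomial SE of the
    # realized molecular VAF at 1% with >=5000 molecules
    config = small_sim_config(
        variants=[(10, "C", "T", 0.01)],
        n_molecules=5000,
        reads_to_sample=100_000,
        sequencing_error_rate=0.003,
    )
    truth, batch = simulate_run(config)
    pileup, _ = run_consensus(batch, config.reference_insert, "assay1")
    est = variant_vaf(pileup, 10, "T")
    informative = int(pileup.informative_families[9])
    p = truth.realized_vafs[0]
    se = np.sqrt(p * (1 - p) / informative)
    assert abs(est - p) <= 3 * se
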