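"""Simulator: ground-truth bookkeeping, error processes, determinism."""

import io
import math

import numpy as np
import pytest

from umi_mrd import (
    ConfigError,
    EmptyPoolError,
    amplify_and_sequence,
    simulate_molecules,
    simulate_run,
)
from umi_mrd.consensus import DEFAULT_LAYOUT, decode_seq
from umi_mrd.simulate import write_fastq

from conftest import small_sim_config


class TestSimulateMolecules:
    def test_zero_vaf_gives_all_reference_molecules(self):
        truth = simulate_molecules(
            small_sim_config(variants=[(10, "C", "T", 0.0)], n_molecules=100)
        )
        assert truth.mutant_counts[0] == 0
        assert all(a == "C" for a in decode_seq(truth.allele_codes[:, 0]))

    def test_realized_count_tracks_binomial_mean(self):
        # VAF 0.5, n=10000: realized count within 3*sqrt(n*p*q) of 5000
        truth = simulate_molecules(
            small_sim_config(variants=[(10, "C", "T", 0.5)], n_molecules=10000)
        )
        assert abs(truth.mutant_counts[0] - 5000) <= 3 * math.sqrt(10000 * 0.25)
        assert truth.realized_vafs[0] == truth.mutant_counts[0] / 10000

    def test_same_seed_reproduces_ground_truth(self):
        t1 = simulate_molecules(small_sim_config())
        t2 = simulate_molecules(small_sim_config())
        assert np.array_equal(t1.barcode_codes, t2.barcode_codes)
        assert np.array_equal(t1.allele_codes, t2.allele_codes)

    @pytest.mark.parametrize(
        "overrides, field",
        [
            (dict(seed=None), "seed"),
            (dict(variants=[(99, "C", "T", 0.1)]), "variants"),
            (dict(variants=[(10, "A", "T", 0.1)]), "variants"),  # ref mismatch
            (dict(variants=[(10, "C", "T", 1.5)]), "variants"),
            (dict(sequencing_error_rate=-0.1), "sequencing_error_rate"),
            (dict(reads_to_sample=0), "reads_to_sample"),
        ],
    )
    def test_invalid_config_names_the_field(self, overrides, field):
        with pytest.raises(ConfigError) as err:
            simulate_molecules(small_sim_config(**overrides))
        assert err.value.field == field


class TestAmplifyAndSequence:
    def test_error_free_reads_match_founder_molecules(self):
        config = small_sim_config(
            polymerase_error_rate=0.0, sequencing_error_rate=0.0
        )
        truth, batch = simulate_run(config)
        founders = truth.molecule_matrix()
        assert np.array_equal(batch.read_matrix, founders[batch.founder_ids])

    def test_mean_family_size_matches_uniform_sampling(self):
        config = small_sim_config(n_molecules=500, reads_to_sample=25000)
        truth, batch = simulate_run(config)
        sizes = np.bincount(batch.founder_ids, minlength=500)
        assert abs(sizes.mean() - 50) / 50 < 0.10

    def test_raw_mismatch_rate_matches_sequencing_error_rate(self):
        rate = 0.01
        config = small_sim_config(
            polymerase_error_rate=0.0,
            sequencing_error_rate=rate,
            n_molecules=200,
            reads_to_sample=5000,
        )
        truth, batch = simulate_run(config)
        founders = truth.molecule_matrix()
        n_bases = batch.read_matrix.size
        mismatches = int((batch.read_matrix != founders[batch.founder_ids]).sum())
        # substitutions always change the base, so observed rate ~ Binomial(n, rate)
        se = math.sqrt(rate * (1 - rate) / n_bases)
        assert abs(mismatches / n_bases - rate) <= 3 * se

    def test_every_barcode_traces_to_ground_truth(self):
        # exact conservation holds in the error-free limit; with errors on,
        # PCR can mutate a barcode, so only (almost all) reads need to trace
        config = small_sim_config(
            sequencing_error_rate=0.0, polymerase_error_rate=0.0
        )
        truth, batch = simulate_run(config)
        bl = config.barcode_length
        truth_barcodes = {decode_seq(row) for row in truth.barcode_codes}
        read_barcodes = {decode_seq(row[:bl]) for row in batch.read_matrix}
        assert read_barcodes <= truth_barcodes

        config = small_sim_config(sequencing_error_rate=0.0)
        truth, batch = simulate_run(config)
        truth_barcodes = {decode_seq(row) for row in truth.barcode_codes}
        traced = sum(
            decode_seq(row[:bl]) in truth_barcodes for row in batch.read_matrix
        )
        assert traced / batch.n_reads > 0.995

    def test_empty_pool_raises(self):
        config = small_sim_config(n_molecules=0)
        truth = simulate_molecules(config)
        with pytest.raises(EmptyPoolError):
            amplify_and_sequence(truth, config)

    def test_fastq_bytes_reproducible_for_same_seed(self):
        buffers = []
        for _ in range(2):
            _, batch = simulate_run(small_sim_config())
            handle = io.StringIO()
            write_fastq(batch, handle)
            buffers.append(handle.getvalue())
        assert buffers[0] == buffers[1]
        first = buffers[0].splitlines()
        assert first[0].startswith("@assay1:")
        assert set(first[3]) == {chr(30 + 33)}  # constant Q30

    def test_pcr_errors_are_shared_within_families(self):
        # with only polymerase errors, a mismatch seen by >=2 reads of a
        # family must be identical in all of them at that position more often
        # than independent errors would allow; check the weaker, structural
        # property that errors exist and sequencing-error-free reads from the
        # same founder differ only at shared or private lineage positions
        config = small_sim_config(
            n_molecules=50,
            reads_to_sample=5000,
            pcr_cycles=20,
            polymerase_error_rate=2e-4,
            sequencing_error_rate=0.0,
        )
        truth, batch = simulate_run(config)
        founders = truth.molecule_matrix()
        diffs = batch.read_matrix != founders[batch.founder_ids]
        assert diffs.any(), "polymerase errors should appear at this rate"
        # at least one error is shared by two reads of one family (inherited)
        shared = 0
        for founder in np.unique(batch.founder_ids):
            rows = diffs[batch.founder_ids == founder]
            if (rows.sum(axis=0) >= 2).any():
                shared += 1
        assert shared > 0


def test_zero_error_raw_vaf_equals_molecular_vaf_weighted_by_sampling():
    config = small_sim_config(
        polymerase_error_rate=0.0, sequencing_error_rate=0.0, n_molecules=400
    )
    truth, batch = simulate_run(config)
    offset = DEFAULT_LAYOUT.prefix_length + 10 - 1
    alt_code = 3  # T
    raw_vaf = float((batch.read_matrix[:, offset] == alt_code).mean())
    per_read_truth = truth.allele_codes[batch.founder_ids, 0]
    assert raw_vaf == float((per_read_truth == alt_code).mean())
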