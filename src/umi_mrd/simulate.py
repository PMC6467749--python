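"""Ground-truth simulator for barcoded amplicon sequencing.

Emulates a SiMSen-Seq-style library: each of ``n_molecules`` template
molecules (haploid genome-equivalents) receives a random 12-nt molecular
barcode before amplification; the barcoded pool is PCR-amplified with
deterministic doubling per cycle and per-base polymerase errors injected at
each copy event (inherited by all descendants of the copy); finally
``reads_to_sample`` single-end reads are drawn uniformly from the amplified
pool and hit with independent per-base sequencing errors.  True variants are
assigned per molecule by independent draws at the configured VAF, and the
realised molecular counts are recorded as ground truth so downstream
consensus calling can be scored against what actually entered the library.

The amplified pool is never materialised.  Because doubling gives every
founder molecule the same number of descendants, a uniform draw from the
final pool is a uniform founder choice plus a uniform random lineage through
that founder's binary genealogy; polymerase error draws are attached to
lineage *prefixes*, so reads of one family that descend through the same
early copy share its errors — exactly the correlated early-cycle error mode
that barcode consensus is designed to suppress.
"""

from __future__ import annotations

import copy
import gzip
from dataclasses import dataclass, field
from typing import IO, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .consensus import DEFAULT_LAYOUT, ReadLayout, decode_seq, encode_seq

_QUAL_CHAR = chr(30 + 33)  # constant Q30; the calling rules never use quality


class ConfigError(ValueError):
    """Invalid simulation configuration; names the offending field."""

    def __init__(self, sim_field: str, message: str):
        super().__init__(f"{sim_field}: {message}")
        self.field = sim_field


class EmptyPoolError(RuntimeError):
    """No amplified molecules to sample reads from."""


@dataclass(frozen=True)
class VariantSpec:
    """A true variant within the insert: 1-based offset, ref/alt base, VAF."""

    offset: int
    ref: str
    alt: str
    vaf: float


@dataclass
class SimulationConfig:
    assay_id: str
    reference_insert: str
    variants: list[VariantSpec] = field(default_factory=list)
    n_molecules: int = 1000
    barcode_length: int = 12
    pcr_cycles: int = 20
    polymerase_error_rate: float = 1e-5
    sequencing_error_rate: float = 1e-3
    reads_to_sample: int = 20000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.variants = [
            v if isinstance(v, VariantSpec) else VariantSpec(*v) for v in self.variants
        ]

    def validate(self) -> None:
        if not self.reference_insert or any(
            b not in "ACGT" for b in self.reference_insert
        ):
            raise ConfigError("reference_insert", "must be a non-empty ACGT string")
        if self.n_molecules < 0:
            raise ConfigError("n_molecules", "must be >= 0")
        if self.barcode_length < 1:
            raise ConfigError("barcode_length", "must be >= 1")
        if self.pcr_cycles < 0 or self.pcr_cycles > 40:
            raise ConfigError("pcr_cycles", "must be in 0..40")
        for name in ("polymerase_error_rate", "sequencing_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(name, "must be a probability in [0, 1]")
        if self.reads_to_sample < 1:
            raise ConfigError("reads_to_sample", "must be >= 1")
        if self.seed is None:
            raise ConfigError("seed", "an explicit seed is required")
        length = len(self.reference_insert)
        for v in self.variants:
            if not 1 <= v.offset <= length:
                raise ConfigError(
                    "variants", f"offset {v.offset} outside insert 1..{length}"
                )
            if self.reference_insert[v.offset - 1] != v.ref:
                raise ConfigError(
                    "variants",
                    f"ref base {v.ref} at offset {v.offset} does not match insert",
                )
            if v.ref == v.alt or v.alt not in "ACGT":
                raise ConfigError("variants", f"invalid alt allele {v.alt!r}")
            if not 0.0 <= v.vaf <= 1.0:
                raise ConfigError("variants", f"VAF {v.vaf} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "assay_id": self.assay_id,
            "reference_insert": self.reference_insert,
            "variants": [
                [v.offset, v.ref, v.alt, v.vaf] for v in self.variants
            ],
            "n_molecules": self.n_molecules,
            "barcode_length": self.barcode_length,
            "pcr_cycles": self.pcr_cycles,
            "polymerase_error_rate": self.polymerase_error_rate,
            "sequencing_error_rate": self.sequencing_error_rate,
            "reads_to_sample": self.reads_to_sample,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        data["variants"] = [VariantSpec(*v) for v in data.get("variants", [])]
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-molecule truth: barcode and allele at each variant position.

    ``realized_vafs`` are the molecular VAFs actually drawn (mutant molecules
    over n_molecules) — the quantity consensus calling estimates.
    """

    config: SimulationConfig
    barcode_codes: np.ndarray  # (n_molecules, barcode_length) uint8
    allele_codes: np.ndarray  # (n_molecules, n_variants) uint8
    mutant_counts: np.ndarray  # (n_variants,) int
    realized_vafs: np.ndarray  # (n_variants,) float
    _rng: np.random.Generator = field(repr=False, default=None)

    @property
    def n_molecules(self) -> int:
        return self.barcode_codes.shape[0]

    def barcodes(self) -> list[str]:
        return [decode_seq(row) for row in self.barcode_codes]

    def molecule_matrix(self, layout: ReadLayout = DEFAULT_LAYOUT) -> np.ndarray:
        """Full founder molecules as (n_molecules, L) codes:
        barcode + spacer + insert with each molecule's variant alleles."""
        insert = encode_seq(self.config.reference_insert)
        spacer = encode_seq(layout.spacer)
        n = self.n_molecules
        mat = np.empty((n, len(insert) + len(spacer) + self.config.barcode_length),
                       dtype=np.uint8)
        mat[:, : self.config.barcode_length] = self.barcode_codes
        mat[:, self.config.barcode_length : self.config.barcode_length + len(spacer)] = spacer
        mat[:, self.config.barcode_length + len(spacer) :] = insert
        offset = self.config.barcode_length + len(spacer)
        for j, v in enumerate(self.config.variants):
            mat[:, offset + v.offset - 1] = self.allele_codes[:, j]
        return mat

    def to_frame(self) -> pd.DataFrame:
        data = {
            "molecule_id": np.arange(self.n_molecules),
            "barcode": self.barcodes(),
        }
        for j, v in enumerate(self.config.variants):
            col = f"allele_pos{v.offset}"
            data[col] = [decode_seq(self.allele_codes[i : i + 1, j])
                         for i in range(self.n_molecules)]
        return pd.DataFrame(data)


def simulate_molecules(config: SimulationConfig) -> GroundTruth:
    """Tag each template molecule with a random barcode and draw its alleles.

    Each variant allele is an independent Bernoulli(vaf) draw per molecule;
    realised mutant counts and VAFs are recorded for oracle use.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    barcode_codes = rng.integers(0, 4, size=(n, config.barcode_length), dtype=np.uint8)
    insert_codes = encode_seq(config.reference_insert)
    n_var = len(config.variants)
    allele_codes = np.empty((n, n_var), dtype=np.uint8)
    mutant_counts = np.zeros(n_var, dtype=np.int64)
    for j, v in enumerate(config.variants):
        is_mut = rng.random(n) < v.vaf
        ref_code = insert_codes[v.offset - 1]
        alt_code = encode_seq(v.alt)[0]
        allele_codes[:, j] = np.where(is_mut, alt_code, ref_code)
        mutant_counts[j] = int(is_mut.sum())
    realized = mutant_counts / n if n else np.zeros(n_var)
    return GroundTruth(
        config=config,
        barcode_codes=barcode_codes,
        allele_codes=allele_codes,
        mutant_counts=mutant_counts,
        realized_vafs=realized,
        _rng=rng,
    )


@dataclass
class ReadBatch:
    """Sampled raw reads as a code matrix, with founder bookkeeping."""

    assay_id: str
    read_matrix: np.ndarray  # (n_reads, L) uint8
    founder_ids: np.ndarray  # (n_reads,) int

    @property
    def n_reads(self) -> int:
        return self.read_matrix.shape[0]

    def read_id(self, i: int) -> str:
        return f"{self.assay_id}:{i:07d}"

    def sequences(self) -> list[str]:
        return [decode_seq(row) for row in self.read_matrix]

    def iter_records(self) -> Iterator[tuple[str, str]]:
        for i in range(self.n_reads):
            yield self.read_id(i), decode_seq(self.read_matrix[i])

    def to_fastq(self, path_or_handle: Union[str, IO[str]]) -> None:
        write_fastq(self, path_or_handle)


def _pcr_errors(
    rng: np.random.Generator,
    reads: np.ndarray,
    founder_ids: np.ndarray,
    cycles: int,
    rate: float,
) -> None:
    """Inject polymerase errors in place, sharing draws on lineage prefixes.

    Each read's lineage through its founder's genealogy is a string of
    original/copy choices, one per cycle; a copy event at cycle t shared by
    all reads with the same founder and choice prefix gets one error draw,
    applied to every such read.  Later-cycle errors overwrite earlier ones
    at the same base.
    """
    if cycles == 0 or rate == 0.0 or reads.shape[0] == 0:
        return
    n_reads, length = reads.shape
    # key packing must stay within int64
    assert founder_ids.max(initial=0) * (cycles + 1) < (1 << (62 - cycles))
    prefix = np.zeros(n_reads, dtype=np.int64)
    founders64 = founder_ids.astype(np.int64)
    all_keys: list[np.ndarray] = []
    all_reads: list[np.ndarray] = []
    for t in range(cycles):
        bits = rng.integers(0, 2, size=n_reads, dtype=np.int64)
        prefix = prefix * 2 + bits
        sel = np.nonzero(bits)[0]
        keys = ((founders64[sel] * (cycles + 1) + t) << cycles) | prefix[sel]
        all_keys.append(keys)
        all_reads.append(sel)
    keys = np.concatenate(all_keys)
    read_of_key = np.concatenate(all_reads)
    uniq, inverse = np.unique(keys, return_inverse=True)
    n_errors = rng.binomial(length, rate, size=len(uniq))
    hot = np.nonzero(n_errors)[0]
    if len(hot) == 0:
        return
    order = np.argsort(inverse, kind="stable")
    sorted_inv = inverse[order]
    cycle_of = (uniq >> cycles) % (cycles + 1)
    for e in hot[np.argsort(cycle_of[hot], kind="stable")]:
        lo = np.searchsorted(sorted_inv, e, side="left")
        hi = np.searchsorted(sorted_inv, e, side="right")
        members = read_of_key[order[lo:hi]]
        for _ in range(int(n_errors[e])):
            pos = int(rng.integers(0, length))
            shift = int(rng.integers(1, 4))
            reads[members, pos] = (reads[members, pos] + shift) % 4


def _sequencing_errors(
    rng: np.random.Generator, reads: np.ndarray, rate: float
) -> None:
    if rate == 0.0 or reads.shape[0] == 0:
        return
    n_reads, length = reads.shape
    counts = rng.binomial(length, rate, size=n_reads)
    total = int(counts.sum())
    if total == 0:
        return
    rows = np.repeat(np.arange(n_reads), counts)
    cols = rng.integers(0, length, size=total)
    shifts = rng.integers(1, 4, size=total).astype(np.uint8)
    reads[rows, cols] = (reads[rows, cols] + shifts) % 4


def amplify_and_sequence(
    truth: GroundTruth,
    config: Optional[SimulationConfig] = None,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> ReadBatch:
    """PCR-amplify the tagged molecules and sample sequencing reads.

    Deterministic given the truth (the RNG state carried by the truth is
    copied, not consumed, so repeated amplification reproduces the batch).
    """
    if config is None:
        config = truth.config
    if config is not truth.config and config.to_dict() != truth.config.to_dict():
        raise ValueError("config does not match the one that produced the truth")
    if truth.n_molecules == 0:
        raise EmptyPoolError("no template molecules: the amplified pool is empty")
    rng = copy.deepcopy(truth._rng)
    founders = truth.molecule_matrix(layout)
    founder_ids = rng.integers(0, truth.n_molecules, size=config.reads_to_sample)
    reads = founders[founder_ids].copy()
    _pcr_errors(rng, reads, founder_ids, config.pcr_cycles,
                config.polymerase_error_rate)
    _sequencing_errors(rng, reads, config.sequencing_error_rate)
    return ReadBatch(
        assay_id=config.assay_id, read_matrix=reads, founder_ids=founder_ids
    )


def write_fastq(batch: ReadBatch, path_or_handle: Union[str, IO[str]]) -> None:
    """Write Phred+33 FASTQ (gzip if the path ends in .gz)."""
    if hasattr(path_or_handle, "write"):
        _write_fastq_handle(batch, path_or_handle)
        return
    path = str(path_or_handle)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as handle:
            _write_fastq_handle(batch, handle)
    else:
        with open(path, "w") as handle:
            _write_fastq_handle(batch, handle)


def _write_fastq_handle(batch: ReadBatch, handle: IO[str]) -> None:
    length = batch.read_matrix.shape[1]
    qual = _QUAL_CHAR * length
    chunk: list[str] = []
    for i in range(batch.n_reads):
        chunk.append(
            f"@{batch.read_id(i)}\n{decode_seq(batch.read_matrix[i])}\n+\n{qual}\n"
        )
        if len(chunk) == 10000:
            handle.write("".join(chunk))
            chunk.clear()
    if chunk:
        handle.write("".join(chunk))


def simulate_run(
    config: SimulationConfig, layout: ReadLayout = DEFAULT_LAYOUT
) -> tuple[GroundTruth, ReadBatch]:
    """Convenience: molecules then reads, one seed, one call."""
    truth = simulate_molecules(config)
    return truth, amplify_and_sequence(truth, config, layout)
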