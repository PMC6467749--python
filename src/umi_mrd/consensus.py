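"""Barcode-family consensus calling for UMI-tagged amplicon reads.

Raw amplicon reads carry a random molecular barcode (UMI) ligated during the
first PCR cycles, so every read descending from one template molecule shares
one barcode.  Grouping reads into *barcode families* and requiring
near-unanimous within-family agreement suppresses polymerase and sequencer
errors, which hit only a subset of a family, while true variants survive in
(nearly) every member.  The agreement rule: a base is
reported in the family consensus if it is carried by 100% of reads in
families of 10-20 reads, or by at least 90% of reads in families of more
than 20 reads; families below 10 reads are discarded, and positions where no
base reaches the threshold are called ``N`` and drop out of every frequency
denominator.

Two call paths are provided and kept in exact agreement (property-tested
against a brute-force oracle): an object path over :class:`TaggedRead` /
:class:`BarcodeFamily` for small inputs and inspection, and a vectorised
path (:func:`run_consensus`) used by the pipeline on full sequencing runs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

BASES = "ACGTN"
_A, _C, _G, _T, _N = range(5)

_CODE = np.full(256, _N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASE_BYTES = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A,C,G,T,N = 0..4; unknown chars -> N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


class ReadRejected(Exception):
    """A raw read failed barcode/spacer extraction; .reason says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class ReadLayout:
    """Physical structure of a single-end amplicon read.

    The library places the random molecular barcode at the 5' end, followed
    by a constant spacer used to validate register, followed by the target
    insert.  The barcode is 12 nt by default.
    """

    barcode_length: int = 12
    spacer: str = "ACTGGC"

    @property
    def prefix_length(self) -> int:
        return self.barcode_length + len(self.spacer)


DEFAULT_LAYOUT = ReadLayout()


@dataclass(frozen=True)
class TaggedRead:
    read_id: str
    barcode: str
    insert: str
    assay_id: str


@dataclass
class BarcodeFamily:
    barcode: str
    assay_id: str
    member_reads: list[TaggedRead]

    @property
    def size(self) -> int:
        return len(self.member_reads)


@dataclass(frozen=True)
class ConsensusRead:
    barcode: str
    assay_id: str
    consensus_sequence: str
    family_size: int


@dataclass(frozen=True)
class ConsensusRules:
    """Family-size and within-family agreement thresholds.

    Families of ``min_family_size`` .. ``small_family_max`` reads must agree
    unanimously (``small_family_fraction`` = 1.0); larger families need at
    least ``large_family_fraction`` (0.90) agreement.  Fractions are compared
    with IEEE division so an exact 27/30 boundary counts as >= 0.90.
    """

    min_family_size: int = 10
    small_family_max: int = 20
    small_family_fraction: float = 1.0
    large_family_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.min_family_size > self.small_family_max:
            raise ValueError("min_family_size must be <= small_family_max")
        for f in (self.small_family_fraction, self.large_family_fraction):
            if not 0.0 < f <= 1.0:
                raise ValueError("agreement fractions must be in (0, 1]")
        # a >0.5 fraction guarantees at most one base can win per position
        if self.large_family_fraction <= 0.5:
            raise ValueError("large_family_fraction must exceed 0.5")


DEFAULT_RULES = ConsensusRules()


def extract_barcode(
    read_id: str,
    sequence: str,
    layout: ReadLayout = DEFAULT_LAYOUT,
    assay_id: str = "",
) -> TaggedRead:
    """Split a raw read into barcode and insert, validating the spacer.

    Raises :class:`ReadRejected` with reason ``too_short`` when the read
    cannot contain barcode + spacer, or ``spacer_mismatch`` when the constant
    spacer differs from its expected sequence by more than one base.
    """
    if len(sequence) < layout.prefix_length + 1:
        raise ReadRejected("too_short")
    barcode = sequence[: layout.barcode_length]
    spacer = sequence[layout.barcode_length : layout.prefix_length]
    mismatches = sum(a != b for a, b in zip(spacer, layout.spacer))
    if mismatches > 1:
        raise ReadRejected("spacer_mismatch")
    return TaggedRead(
        read_id=read_id,
        barcode=barcode,
        insert=sequence[layout.prefix_length :],
        assay_id=assay_id,
    )


def extract_tagged_reads(
    records: Iterable[tuple[str, str]],
    layout: ReadLayout = DEFAULT_LAYOUT,
    assay_id: str = "",
) -> tuple[list[TaggedRead], Counter]:
    """Extract every read, tallying (not raising on) rejections."""
    accepted: list[TaggedRead] = []
    rejected: Counter = Counter()
    for read_id, seq in records:
        try:
            accepted.append(extract_barcode(read_id, seq, layout, assay_id))
        except ReadRejected as exc:
            rejected[exc.reason] += 1
    return accepted, rejected


def group_families(reads: Iterable[TaggedRead]) -> dict[tuple[str, str], BarcodeFamily]:
    """Exact-match grouping on (assay_id, barcode)."""
    families: dict[tuple[str, str], BarcodeFamily] = {}
    for read in reads:
        key = (read.assay_id, read.barcode)
        fam = families.get(key)
        if fam is None:
            families[key] = BarcodeFamily(read.barcode, read.assay_id, [read])
        else:
            fam.member_reads.append(read)
    return families


def _family_threshold_met(count: int, size: int, rules: ConsensusRules) -> bool:
    if size <= rules.small_family_max:
        return count / size >= rules.small_family_fraction
    return count / size >= rules.large_family_fraction


def consensus_family(
    family: BarcodeFamily, rules: ConsensusRules = DEFAULT_RULES
) -> Optional[ConsensusRead]:
    """Collapse one family to a consensus read, or None if it is too small.

    Per position, the base carried by a sufficient fraction of members
    becomes the consensus; otherwise the position is called N.
    """
    size = family.size
    if size < rules.min_family_size:
        return None
    lengths = {len(r.insert) for r in family.member_reads}
    if len(lengths) != 1:
        raise ValueError("family members must share insert length")
    mat = np.vstack([encode_seq(r.insert) for r in family.member_reads])
    consensus = np.full(mat.shape[1], _N, dtype=np.uint8)
    for pos in range(mat.shape[1]):
        counts = np.bincount(mat[:, pos], minlength=5)[:4]
        best = int(counts.argmax())
        if _family_threshold_met(int(counts[best]), size, rules):
            consensus[pos] = best
    return ConsensusRead(
        barcode=family.barcode,
        assay_id=family.assay_id,
        consensus_sequence=decode_seq(consensus),
        family_size=size,
    )


@dataclass
class ConsensusPileup:
    """Per-position counts of consensus families by allele.

    ``counts`` is (insert_length, 5): number of consensus families calling
    A, C, G, T, N at each 1-based position.  N calls are non-informative and
    excluded from every frequency denominator.
    """

    assay_id: str
    reference: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.reference), 5):
            raise ValueError("counts must be (reference length, 5)")

    @property
    def length(self) -> int:
        return len(self.reference)

    @property
    def informative_families(self) -> np.ndarray:
        """Non-N consensus family count per position."""
        return self.counts[:, :4].sum(axis=1)

    @property
    def reference_codes(self) -> np.ndarray:
        return encode_seq(self.reference)

    def minor_allele_frequency(self) -> np.ndarray:
        """Largest non-reference family fraction per position (NaN where no
        informative family exists)."""
        informative = self.informative_families
        nonref = self.counts[:, :4].copy()
        ref_codes = self.reference_codes
        rows = np.arange(self.length)
        valid_ref = ref_codes < 4
        nonref[rows[valid_ref], ref_codes[valid_ref]] = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            maf = nonref.max(axis=1) / informative
        return np.where(informative > 0, maf, np.nan)

    def allele_count(self, position: int, allele: str) -> int:
        """Consensus-family count for ``allele`` at 1-based ``position``."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return int(self.counts[position - 1, BASES.index(allele.upper())])

    def to_frame(self) -> pd.DataFrame:
        informative = self.informative_families
        maf = self.minor_allele_frequency()
        return pd.DataFrame(
            {
                "assay_id": self.assay_id,
                "position": np.arange(1, self.length + 1),
                "ref": list(self.reference),
                "A": self.counts[:, _A],
                "C": self.counts[:, _C],
                "G": self.counts[:, _G],
                "T": self.counts[:, _T],
                "N": self.counts[:, _N],
                "informative_families": informative,
                "maf": maf,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConsensusPileup":
        assays = frame["assay_id"].unique()
        if len(assays) != 1:
            raise ValueError("pileup frame must contain exactly one assay")
        frame = frame.sort_values("position")
        counts = frame[["A", "C", "G", "T", "N"]].to_numpy(dtype=np.int64)
        return cls(
            assay_id=str(assays[0]),
            reference="".join(frame["ref"]),
            counts=counts,
        )


def build_pileup(
    consensus_reads: Sequence[ConsensusRead], reference: str
) -> ConsensusPileup:
    """Tally consensus reads of one assay into a per-position pileup."""
    if not consensus_reads:
        raise ValueError("no consensus reads to pile up")
    assays = {c.assay_id for c in consensus_reads}
    if len(assays) != 1:
        raise ValueError(f"mixed assays in pileup: {sorted(assays)}")
    length = len(reference)
    counts = np.zeros((length, 5), dtype=np.int64)
    for cons in consensus_reads:
        if len(cons.consensus_sequence) != length:
            raise ValueError("consensus length does not match reference")
        codes = encode_seq(cons.consensus_sequence)
        counts[np.arange(length), codes] += 1
    return ConsensusPileup(assay_id=assays.pop(), reference=reference, counts=counts)


def variant_vaf(
    pileup: ConsensusPileup, position: int, alt: str
) -> Optional[float]:
    """Consensus VAF of ``alt`` at 1-based ``position``.

    Returns None (undefined) when no informative family covers the position.
    """
    informative = int(pileup.informative_families[position - 1])
    if informative == 0:
        return None
    return pileup.allele_count(position, alt) / informative


# ---------------------------------------------------------------------------
# vectorised path for full sequencing runs
# ---------------------------------------------------------------------------


@dataclass
class ConsensusStats:
    n_reads: int = 0
    rejected: Counter = field(default_factory=Counter)
    n_families: int = 0
    n_families_used: int = 0

    @property
    def n_accepted(self) -> int:
        return self.n_reads - sum(self.rejected.values())


def _tally_by_family(
    codes: np.ndarray, family_index: np.ndarray, n_families: int
) -> np.ndarray:
    """(n_reads, L) codes + family index -> (n_families, L, 5) base counts."""
    n_reads, length = codes.shape
    flat = (
        family_index[:, None].astype(np.int64) * length + np.arange(length)
    ) * 5 + codes
    tally = np.bincount(flat.ravel(), minlength=n_families * length * 5)
    return tally.reshape(n_families, length, 5)


def consensus_codes(
    family_counts: np.ndarray, rules: ConsensusRules = DEFAULT_RULES
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised family consensus.

    family_counts: (n_families, L, 5) per-position base tallies.
    Returns (kept_mask over families, (n_kept, L) consensus codes).
    """
    sizes = family_counts[:, 0, :].sum(axis=1)
    kept = sizes >= rules.min_family_size
    counts = family_counts[kept][:, :, :4]
    sizes = sizes[kept].astype(np.float64)
    best = counts.max(axis=2)
    arg = counts.argmax(axis=2).astype(np.uint8)
    frac_needed = np.where(
        sizes <= rules.small_family_max,
        rules.small_family_fraction,
        rules.large_family_fraction,
    )
    ok = best / sizes[:, None] >= frac_needed[:, None]
    return kept, np.where(ok, arg, np.uint8(_N))


def run_consensus(
    records: Iterable[tuple[str, str]],
    reference: str,
    assay_id: str,
    layout: ReadLayout = DEFAULT_LAYOUT,
    rules: ConsensusRules = DEFAULT_RULES,
) -> tuple[ConsensusPileup, ConsensusStats]:
    """Extract, group, collapse and pile up a full run of raw reads.

    ``records`` yields (read_id, sequence), or may be an already-encoded
    read matrix ((n_reads, length) base codes, e.g. ``ReadBatch.read_matrix``)
    to skip string decoding.  Reads whose length differs from barcode +
    spacer + reference are rejected (``too_short`` when shorter than the
    prefix, ``length_mismatch`` otherwise); spacer mismatches >1 base are
    rejected.  Produces the same pileup as the object path.
    """
    stats = ConsensusStats()
    length = len(reference)
    expected = layout.prefix_length + length
    if hasattr(records, "read_matrix"):
        records = records.read_matrix
    if isinstance(records, np.ndarray):
        stats.n_reads = records.shape[0]
        if records.shape[1] != expected:
            raise ValueError("read matrix width does not match layout + reference")
        mat = records
    else:
        seqs: list[str] = []
        for _read_id, seq in records:
            stats.n_reads += 1
            if len(seq) < layout.prefix_length + 1:
                stats.rejected["too_short"] += 1
            elif len(seq) != expected:
                stats.rejected["length_mismatch"] += 1
            else:
                seqs.append(seq)
        if not seqs:
            return (
                ConsensusPileup(assay_id, reference, np.zeros((length, 5), np.int64)),
                stats,
            )
        mat = _CODE[
            np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        ].reshape(len(seqs), expected)
        del seqs

    spacer_codes = encode_seq(layout.spacer)
    spacer_mm = (
        mat[:, layout.barcode_length : layout.prefix_length] != spacer_codes
    ).sum(axis=1)
    keep = spacer_mm <= 1
    stats.rejected["spacer_mismatch"] += int((~keep).sum())
    mat = mat[keep]
    if mat.shape[0] == 0:
        return (
            ConsensusPileup(assay_id, reference, np.zeros((length, 5), np.int64)),
            stats,
        )

    # pack the barcode into one integer per read for exact-match grouping;
    # barcodes containing N are grouped by code 4 like any other base
    barcodes = mat[:, : layout.barcode_length].astype(np.int64)
    packed = np.zeros(mat.shape[0], dtype=np.int64)
    for j in range(layout.barcode_length):
        packed = packed * 5 + barcodes[:, j]
    _uniq, family_index = np.unique(packed, return_inverse=True)
    n_families = len(_uniq)
    stats.n_families = n_families

    inserts = mat[:, layout.prefix_length :]
    family_counts = _tally_by_family(inserts, family_index, n_families)
    kept, cons = consensus_codes(family_counts, rules)
    stats.n_families_used = int(kept.sum())

    counts = np.zeros((length, 5), dtype=np.int64)
    if cons.shape[0]:
        flat = np.arange(length) * 5 + cons
        counts = np.bincount(flat.ravel(), minlength=length * 5).reshape(length, 5)
    return ConsensusPileup(assay_id, reference, counts), stats
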