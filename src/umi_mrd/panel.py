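"""Patient-specific mutation-panel design from tumor variant calls.

Somatic SNVs called in the primary tumor are scored on variant allele
frequency, COSMIC membership, genomic location and predicted functional
impact, ranked, and the top candidates (2-8 per patient) become the plasma
monitoring panel.  Selected mutations must re-verify in a deep-sequenced
tumor library before plasma monitoring; a patient with no verified mutation
is ineligible for monitoring.  Amplicon assays targeting the panel are
classified short when the target region is under 80 bp, which favours
recovery of fragmented cell-free DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .consensus import ConsensusPileup, variant_vaf

LOCATION_CLASSES = ("exonic", "intronic", "UTR", "intergenic", "splice")
IMPACT_CLASSES = ("high", "moderate", "low", "none")

SHORT_ASSAY_MAX_BP = 80  # strict bound: length < 80 bp is "short"


@dataclass(frozen=True)
class CandidateMutation:
    patient_id: str
    gene: str
    chrom: str
    position: int  # 1-based
    ref: str
    alt: str
    tumor_vaf: float
    in_cosmic: bool = False
    location_class: str = "exonic"
    impact_class: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_vaf <= 1.0:
            raise ValueError(f"tumor VAF {self.tumor_vaf} outside [0, 1]")
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide substitutions are supported")
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {self.location_class!r}")
        if self.impact_class not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact_class!r}")


@dataclass(frozen=True)
class AmpliconAssay:
    """One amplicon targeting panel mutations; 1-based inclusive region."""

    assay_id: str
    chrom: str
    start: int
    end: int
    insert: str
    target_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("assay end before start")
        if len(self.insert) != self.length:
            raise ValueError("insert length must equal region length")
        for off in self.target_offsets:
            if not 1 <= off <= self.length:
                raise ValueError(f"target offset {off} outside assay")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_short(self) -> bool:
        return self.length < SHORT_ASSAY_MAX_BP

    def offset_of(self, position: int) -> int:
        """Genomic position -> 1-based offset within the insert."""
        if not self.start <= position <= self.end:
            raise ValueError(f"position {position} outside assay {self.assay_id}")
        return position - self.start + 1


@dataclass
class PanelMutation:
    candidate: CandidateMutation
    selection_score: float
    verified_in_tumor: Optional[bool] = None  # None = unverifiable
    assay: Optional[AmpliconAssay] = None

    def __getattr__(self, name):
        # delegate candidate fields (gene, position, ...) for convenience
        return getattr(self.candidate, name)


@dataclass(frozen=True)
class ScoringWeights:
    """Configurable weights for the four selection criteria.

    The score saturates VAF at 30% (the top of the tumor VAF range the
    design targets), rewards COSMIC membership, and down-weights non-exonic
    and low-impact calls.
    """

    w_vaf: float = 1.0
    w_cosmic: float = 1.0
    w_location: float = 1.0
    w_impact: float = 1.0
    vaf_saturation: float = 0.30
    location_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "exonic": 1.0,
            "splice": 0.25,
            "UTR": 0.25,
            "intronic": 0.25,
            "intergenic": 0.0,
        }
    )
    impact_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "high": 1.0,
            "moderate": 0.5,
            "low": 0.1,
            "none": 0.0,
        }
    )


DEFAULT_WEIGHTS = ScoringWeights()


def score_candidate(
    candidate: CandidateMutation, weights: ScoringWeights = DEFAULT_WEIGHTS
) -> float:
    return (
        weights.w_vaf * min(candidate.tumor_vaf / weights.vaf_saturation, 1.0)
        + weights.w_cosmic * float(candidate.in_cosmic)
        + weights.w_location * weights.location_weights[candidate.location_class]
        + weights.w_impact * weights.impact_weights[candidate.impact_class]
    )


def score_candidates(
    candidates: Sequence[CandidateMutation],
    weights: ScoringWeights = DEFAULT_WEIGHTS,
) -> list[PanelMutation]:
    """Score and rank candidates; a total order independent of input order.

    Ties in score break by (tumor VAF descending, genomic position
    ascending, chrom, alt) so that permuting the input never changes the
    ranking.
    """
    scored = [PanelMutation(c, score_candidate(c, weights)) for c in candidates]
    scored.sort(
        key=lambda m: (
            -m.selection_score,
            -m.candidate.tumor_vaf,
            m.candidate.chrom,
            m.candidate.position,
            m.candidate.alt,
        )
    )
    return scored


def select_panel(
    ranked: Sequence[PanelMutation], k: int = 4
) -> list[PanelMutation]:
    """Top-k panel, with k clamped to the 2..8 design range.

    Fewer than 2 available candidates yields a degenerate panel with a
    warning rather than a failure.
    """
    if k < 2:
        raise ValueError("panel size k must be >= 2")
    k = min(k, 8)
    if not ranked:
        warnings.warn("no candidate mutations: empty panel", stacklevel=2)
        return []
    if len(ranked) < 2:
        warnings.warn(
            "only one candidate mutation available: panel of size 1", stacklevel=2
        )
    return list(ranked[:k])


def verify_in_tumor(
    panel: Iterable[PanelMutation],
    tumor_pileups: Mapping[str, ConsensusPileup],
    threshold: float = 0.01,
) -> list[PanelMutation]:
    """Flag each panel mutation by its tumor consensus VAF.

    verified_in_tumor is True when the deep-sequenced tumor shows the
    mutation at >= ``threshold`` consensus VAF, False when covered but below
    it, and None (unverifiable) when the assay's tumor pileup is missing or
    the position has no informative family.
    """
    out: list[PanelMutation] = []
    for mut in panel:
        verified: Optional[bool] = None
        if mut.assay is not None and mut.assay.assay_id in tumor_pileups:
            pileup = tumor_pileups[mut.assay.assay_id]
            offset = mut.assay.offset_of(mut.candidate.position)
            vaf = variant_vaf(pileup, offset, mut.candidate.alt)
            if vaf is not None:
                verified = vaf >= threshold
        out.append(replace_verified(mut, verified))
    return out


def replace_verified(mut: PanelMutation, verified: Optional[bool]) -> PanelMutation:
    return PanelMutation(
        candidate=mut.candidate,
        selection_score=mut.selection_score,
        verified_in_tumor=verified,
        assay=mut.assay,
    )


def patient_eligible(panel: Sequence[PanelMutation]) -> bool:
    """A patient stays in monitoring only with >= 1 tumor-verified mutation."""
    return any(m.verified_in_tumor for m in panel)


def classify_assay(assay: AmpliconAssay) -> str:
    """'short' iff the target region is strictly under 80 bp, else 'long'."""
    return "short" if assay.is_short else "long"
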