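"""Plasma sample classification against a patient's mutation panel.

A panel mutation is *detected* in a plasma consensus pileup when its
consensus VAF is at least 0.05% and above the assay's background noise; a
plasma sample is *positive* when one or more panel mutations are detected.
Background noise is estimated per assay as mean + 3 SD of the minor-allele
frequencies at positions not targeted by any panel mutation (the assay's
own error floor after consensus suppression).  Positions with no
informative consensus family are *not evaluable* — absence of evidence,
kept distinct from a negative call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .consensus import ConsensusPileup, variant_vaf
from .panel import PanelMutation

VAF_DETECTION_THRESHOLD = 0.0005  # 0.05%, inclusive


@dataclass(frozen=True)
class BackgroundModel:
    """Noise floor of one assay over non-panel positions."""

    assay_id: str
    mean: float
    sd: float
    max: float
    n_positions: int
    method: str = "mean_plus_3sd"

    @property
    def threshold(self) -> float:
        if self.method == "fallback":
            return 0.0
        return max(self.mean + 3.0 * self.sd, 0.0)


@dataclass(frozen=True)
class MutationCall:
    mutation: PanelMutation
    vaf: Optional[float]  # None when not evaluable
    informative_families: int
    background_threshold: float
    detected: Optional[bool]  # None when not evaluable

    @property
    def evaluable(self) -> bool:
        return self.detected is not None


@dataclass(frozen=True)
class PlasmaSampleCall:
    sample_id: str
    patient_id: str
    collection_day: int  # days relative to treatment day 0; negative = pre
    mutation_calls: tuple[MutationCall, ...]
    sample_positive: Optional[bool]  # None when no call was evaluable


def estimate_background(
    pileup: ConsensusPileup,
    panel_offsets: Iterable[int],
    min_positions: int = 5,
) -> BackgroundModel:
    """Summarise non-panel MAFs into a per-assay noise threshold.

    ``panel_offsets`` are 1-based insert offsets carrying targeted
    mutations; they are excluded so a true variant never inflates its own
    background.  With fewer than ``min_positions`` informative non-panel
    positions the model falls back to a zero threshold, with a warning.
    """
    excluded = set(panel_offsets)
    maf = pileup.minor_allele_frequency()
    keep = [
        i
        for i in range(pileup.length)
        if (i + 1) not in excluded and not math.isnan(maf[i])
    ]
    values = maf[keep]
    if len(keep) < min_positions:
        warnings.warn(
            f"assay {pileup.assay_id}: only {len(keep)} informative non-panel "
            "positions; background threshold falls back to 0",
            stacklevel=2,
        )
        return BackgroundModel(
            assay_id=pileup.assay_id,
            mean=float("nan"),
            sd=float("nan"),
            max=float("nan"),
            n_positions=len(keep),
            method="fallback",
        )
    return BackgroundModel(
        assay_id=pileup.assay_id,
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        max=float(values.max()),
        n_positions=len(keep),
    )


def call_mutation(
    pileup: ConsensusPileup,
    mutation: PanelMutation,
    background: BackgroundModel,
    vaf_threshold: float = VAF_DETECTION_THRESHOLD,
    offset: Optional[int] = None,
) -> MutationCall:
    """Detect one panel mutation: VAF >= threshold AND above background.

    ``offset`` (1-based position within the assay insert) defaults to the
    mutation's offset within its linked assay.
    """
    if offset is None:
        if mutation.assay is None:
            raise ValueError("mutation has no assay; pass offset explicitly")
        offset = mutation.assay.offset_of(mutation.candidate.position)
    informative = int(pileup.informative_families[offset - 1])
    vaf = variant_vaf(pileup, offset, mutation.candidate.alt)
    detected: Optional[bool] = None
    if vaf is not None:
        detected = (vaf >= vaf_threshold) and (vaf > background.threshold)
    return MutationCall(
        mutation=mutation,
        vaf=vaf,
        informative_families=informative,
        background_threshold=background.threshold,
        detected=detected,
    )


def classify_sample(
    sample_id: str,
    patient_id: str,
    collection_day: int,
    calls: Sequence[MutationCall],
) -> PlasmaSampleCall:
    """One or more detected mutations make the sample positive.

    With no evaluable call at all the sample is not evaluable (positive is
    None) rather than negative.
    """
    if not calls:
        raise ValueError("a sample call needs at least one mutation call")
    evaluable = [c for c in calls if c.evaluable]
    if not evaluable:
        positive: Optional[bool] = None
    else:
        positive = any(c.detected for c in evaluable)
    return PlasmaSampleCall(
        sample_id=sample_id,
        patient_id=patient_id,
        collection_day=collection_day,
        mutation_calls=tuple(calls),
        sample_positive=positive,
    )
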