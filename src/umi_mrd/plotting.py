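"""Figure-style plots: per-base minor-allele-frequency profiles and
per-patient monitoring timelines."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .consensus import ConsensusPileup
from .timeline import RECURRENCE_EVENTS, PatientTimeline

PathLike = Union[str, Path]


def maf_profile_plot(
    pileup: ConsensusPileup,
    path: PathLike,
    highlight_offsets: Sequence[int] = (),
    title: Optional[str] = None,
) -> None:
    """Consensus minor-allele frequency at each base of the amplicon.

    A flat near-zero profile with isolated spikes at true variant positions
    is the expected signature of effective error suppression.
    """
    maf = pileup.minor_allele_frequency() * 100
    positions = np.arange(1, pileup.length + 1)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(positions, np.nan_to_num(maf), width=0.8, color="#3b6ea5")
    for off in highlight_offsets:
        ax.axvline(off, color="#c23b22", linestyle="--", linewidth=0.8)
    ax.set_xlabel("position in amplicon (bp)")
    ax.set_ylabel("minor allele frequency (%)")
    ax.set_title(title or f"assay {pileup.assay_id}")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


def timeline_plot(timeline: PatientTimeline, path: PathLike) -> None:
    """Sample days, positivity and clinical events for one patient."""
    fig, ax = plt.subplots(figsize=(8, 2.5))
    for sample in timeline.samples:
        if sample.sample_positive is None:
            color, marker = "#999999", "x"
        elif sample.sample_positive:
            color, marker = "#c23b22", "o"
        else:
            color, marker = "#3b6ea5", "o"
        ax.scatter(sample.collection_day, 0, color=color, marker=marker, zorder=3)
    for event in timeline.events:
        if event.event_type == "treatment":
            ax.axvline(event.day, color="black", linewidth=1)
        elif event.event_type in RECURRENCE_EVENTS:
            ax.axvline(event.day, color="#c23b22", linewidth=1, linestyle=":")
        elif event.event_type == "adjuvant_therapy":
            ax.axvline(event.day, color="#777777", linewidth=0.8, linestyle="--")
    ax.set_yticks([])
    ax.set_xlabel("days from treatment")
    ax.set_title(
        f"{timeline.patient_id}  (red = ctDNA positive, blue = negative, "
        "x = not evaluable)"
    )
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
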