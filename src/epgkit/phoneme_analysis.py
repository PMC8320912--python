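"""Per-phoneme palatogram analysis.

Aligns palatogram sequences with phoneme timelines, extracts a cumulative
contact map for every occurrence of a set of target phonemes (summing the
palatograms over the phoneme's duration), and summarises asymmetry across
occurrences.  The per-occurrence metric is activation-weighted: it is
computed from the cumulative left/right activation counts over the
phoneme's frames, not from a per-frame average of indices.  Occurrences
with no tongue-palate contact at all (e.g. bilabials) carry undefined
metrics and are excluded from means rather than treated as symmetric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .formats import PhonemeInterval, PhonemeTimeline
from .palatogram import (
    AsymmetryMetrics,
    PalatogramSequence,
    cumulative_activation,
    metrics_from_counts,
)

__all__ = [
    "PhonemeOccurrence",
    "PhonemeSummary",
    "frames_for_interval",
    "extract_phonemes",
    "summarise_phoneme",
    "occurrences_table",
    "plot_occurrence_variability",
]


@dataclass
class PhonemeOccurrence:
    """One realisation of a phoneme with its cumulative contact map."""

    label: str
    sentence_id: str
    interval: PhonemeInterval
    frame_range: tuple[int, int]
    cumulative_map: np.ndarray
    metrics: AsymmetryMetrics


@dataclass
class PhonemeSummary:
    """All occurrences of one phoneme pooled together.

    ``pooled_map`` is the elementwise sum of the occurrence maps and
    ``pooled_metrics`` is computed from the pooled left/right totals, so
    pooling commutes with the metric.  ``per_occurrence_index`` lists each
    occurrence's left fraction (NaN where undefined), in corpus order.
    """

    label: str
    n_occurrences: int
    pooled_map: np.ndarray
    pooled_metrics: AsymmetryMetrics
    per_occurrence_index: list[float]
    occurrences: list[PhonemeOccurrence] = field(default_factory=list)


def frames_for_interval(
    interval: PhonemeInterval, frame_rate: float, n_frames: int
) -> tuple[int, int]:
    """Half-open frame index range covering a time interval.

    Frame ``i`` (sampled at ``i / frame_rate`` seconds) is included when
    its time falls in ``[start, end)``; the result is clipped to
    ``[0, n_frames)``.  A zero-length or out-of-range interval yields an
    empty range.
    """
    eps = 1e-6
    lo = int(math.ceil(interval.start * frame_rate - eps))
    hi = int(math.ceil(interval.end * frame_rate - eps))
    lo = min(max(lo, 0), n_frames)
    hi = min(max(hi, 0), n_frames)
    if hi < lo:
        hi = lo
    return lo, hi


def extract_phonemes(
    corpus: Iterable[tuple[PhonemeTimeline, PalatogramSequence, str]],
    targets: Sequence[str],
) -> list[PhonemeOccurrence]:
    """Extract every occurrence of the target phonemes from a corpus.

    Parameters
    ----------
    corpus : iterable of (PhonemeTimeline, PalatogramSequence, sentence_id)
        Paired annotation and EPG data per sentence.
    targets : sequence of str
        Phoneme codes of interest, e.g. ``["d", "s", "ng"]``.

    Returns
    -------
    list of PhonemeOccurrence
        In corpus order; each carries the cumulative map summed over the
        phoneme's frames and the asymmetry metrics of that map.  A target
        absent from every sentence triggers a warning.
    """
    targets = list(targets)
    wanted = set(targets)
    seen: set[str] = set()
    out: list[PhonemeOccurrence] = []
    for timeline, seq, sentence_id in corpus:
        for iv in timeline.phonemes:
            if iv.label not in wanted:
                continue
            seen.add(iv.label)
            rng = frames_for_interval(iv, seq.frame_rate, seq.n_frames)
            cmap = cumulative_activation(seq, rng)
            out.append(
                PhonemeOccurrence(
                    label=iv.label,
                    sentence_id=sentence_id,
                    interval=iv,
                    frame_range=rng,
                    cumulative_map=cmap,
                    metrics=metrics_from_counts(cmap, seq.layout),
                )
            )
    for label in targets:
        if label not in seen:
            warnings.warn(f"phoneme {label!r} not found in any sentence", stacklevel=2)
    return out


def summarise_phoneme(occs: Sequence[PhonemeOccurrence]) -> PhonemeSummary:
    """Pool the occurrences of one phoneme.

    All occurrences must share a label (and layout shape).  Raises on an
    empty list.
    """
    if not occs:
        raise ValueError("cannot summarise an empty occurrence list")
    labels = {o.label for o in occs}
    if len(labels) > 1:
        raise ValueError(f"occurrences mix labels {sorted(labels)}")
    shapes = {o.cumulative_map.shape for o in occs}
    if len(shapes) > 1:
        raise ValueError("occurrences mix palate layouts")
    pooled = np.sum([o.cumulative_map for o in occs], axis=0)
    pooled_metrics = AsymmetryMetrics(
        n_left=sum(o.metrics.n_left for o in occs),
        n_right=sum(o.metrics.n_right for o in occs),
    )
    return PhonemeSummary(
        label=occs[0].label,
        n_occurrences=len(occs),
        pooled_map=pooled,
        pooled_metrics=pooled_metrics,
        per_occurrence_index=[o.metrics.left_fraction for o in occs],
        occurrences=list(occs),
    )


def occurrences_table(occs: Sequence[PhonemeOccurrence]) -> pd.DataFrame:
    """Tabulate per-occurrence metrics (one row per occurrence)."""
    return pd.DataFrame(
        {
            "sentence_id": [o.sentence_id for o in occs],
            "label": [o.label for o in occs],
            "start": [o.interval.start for o in occs],
            "end": [o.interval.end for o in occs],
            "n_left": [o.metrics.n_left for o in occs],
            "n_right": [o.metrics.n_right for o in occs],
            "left_fraction": [o.metrics.left_fraction for o in occs],
            "signed_index": [o.metrics.signed_index for o in occs],
        }
    )


def plot_occurrence_variability(
    summaries: Sequence[PhonemeSummary],
    by_speaker: Callable[[str], str] | None = None,
    metric: str = "left_fraction",
    ax=None,
    seed: int = 0,
):
    """Scatter the per-occurrence asymmetry metric by phoneme (and speaker).

    One point per occurrence, horizontally jittered within its
    phoneme-by-speaker group; the y-axis is ``left_fraction`` (default) or
    ``signed_index``.  Occurrences with undefined metrics are skipped.

    Parameters
    ----------
    by_speaker : callable, optional
        Maps a sentence_id to a speaker label; omit for a single group
        per phoneme.
    """
    import matplotlib.pyplot as plt

    if metric not in ("left_fraction", "signed_index"):
        raise ValueError(f"unknown metric {metric!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * max(len(summaries), 2) + 2, 4))
    rng = np.random.default_rng(seed)
    groups: list[tuple[str, list[float]]] = []
    for s in summaries:
        buckets: dict[str, list[float]] = {}
        for o in s.occurrences:
            if not o.metrics.defined:
                continue
            key = by_speaker(o.sentence_id) if by_speaker else ""
            buckets.setdefault(key, []).append(getattr(o.metrics, metric))
        if not buckets:
            warnings.warn(f"phoneme {s.label!r}: no defined occurrences to plot",
                          stacklevel=2)
            continue
        for spk in sorted(buckets):
            name = f"[{s.label}] {spk}".strip()
            groups.append((name, buckets[spk]))
    for x, (name, vals) in enumerate(groups):
        jitter = rng.uniform(-0.15, 0.15, size=len(vals))
        ax.scatter(x + jitter, vals, s=18, alpha=0.7)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([g[0] for g in groups], rotation=30, ha="right")
    ax.set_ylabel(metric.replace("_", " "))
    lo, hi = (0.0, 1.0) if metric == "left_fraction" else (-1.0, 1.0)
    ax.set_ylim(min(lo, *(min(v) for _, v in groups)) - 0.05 if groups else lo - 0.05,
                max(hi, *(max(v) for _, v in groups)) + 0.05 if groups else hi + 0.05)
    ax.axhline(0.5 if metric == "left_fraction" else 0.0, color="k", lw=0.6, ls=":")
    return ax
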