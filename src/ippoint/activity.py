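"""Functional-activity (+/-) labeling of projections against peak files.

A projection is "plus" when its projected point (widened by ``window`` bp on
each side) overlaps at least one activity peak (ATAC/ChIP) in the target
genome; the overlapping peak with the largest overlap is recorded.  Class-
wise fractions of plus projections summarize how often positional orthologs
retain activity.  A same-TAD background sampler pairs each query with a
random nonortholog peak for control comparisons.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chain_io import GenomicInterval


@dataclass(frozen=True)
class ActivityLabel:
    result_ref: str  # projection row name
    label: str  # "plus" | "minus"
    peak: Optional[GenomicInterval] = None
    unprojectable: bool = False

    def __post_init__(self) -> None:
        if (self.label == "plus") != (self.peak is not None):
            raise ValueError("label is plus iff a peak is recorded")


@dataclass(frozen=True)
class BackgroundPair:
    query: GenomicInterval
    background_peak: GenomicInterval
    same_tad: bool


class _PeakIndex:
    """Per-chromosome sorted peak arrays with running-max ends."""

    def __init__(self, peaks: Sequence[GenomicInterval]):
        self.per_chrom: dict[str, tuple[list[int], list[int], list[GenomicInterval]]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for pk in peaks:
            by_chrom.setdefault(pk.chrom, []).append(pk)
        for chrom, pks in by_chrom.items():
            pks.sort(key=lambda p: (p.start, p.end))
            starts = [p.start for p in pks]
            maxend, m = [], 0
            for p in pks:
                m = max(m, p.end)
                maxend.append(m)
            self.per_chrom[chrom] = (starts, maxend, pks)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        entry = self.per_chrom.get(chrom)
        if entry is None:
            return []
        starts, maxend, pks = entry
        hi = bisect.bisect_left(starts, end)
        out = []
        i = hi - 1
        while i >= 0 and maxend[i] > start:
            if pks[i].end > start:
                out.append(pks[i])
            i -= 1
        out.reverse()
        return out


def _projected_point(row) -> Optional[tuple[str, int]]:
    """Point used for activity overlap: direct target for DC, else bridged."""
    has_direct = row["tpos_direct"] is not None and not pd.isna(row["tpos_direct"])
    has_bridged = row["tpos_bridged"] is not None and not pd.isna(row["tpos_bridged"])
    if row["class"] == "DC" and has_direct:
        return row["tchrom_direct"], int(row["tpos_direct"])
    if has_bridged:
        return row["tchrom_bridged"], int(row["tpos_bridged"])
    if has_direct:
        return row["tchrom_direct"], int(row["tpos_direct"])
    return None


def label_projection_activity(
    projections: pd.DataFrame,
    peaks: Sequence[GenomicInterval],
    window: int = 0,
) -> list[ActivityLabel]:
    """Label each projection plus/minus by peak overlap at the projected point.

    The point +/- ``window`` bp (a 2*window+1 bp interval) is intersected
    with the peak set; ties on overlap size go to the lower peak start.
    UNPROJECTABLE rows are labeled minus with a flag so they can be counted
    separately.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    index = _PeakIndex(peaks)
    labels: list[ActivityLabel] = []
    for _, row in projections.iterrows():
        name = str(row["qname"])
        point = _projected_point(row)
        if point is None:
            labels.append(ActivityLabel(name, "minus", None, unprojectable=True))
            continue
        chrom, pos = point
        lo, hi = pos - window, pos + window + 1
        hits = index.overlapping(chrom, lo, hi)
        if not hits:
            labels.append(ActivityLabel(name, "minus", None))
            continue
        best = max(
            hits,
            key=lambda p: (min(hi, p.end) - max(lo, p.start), -p.start),
        )
        labels.append(ActivityLabel(name, "plus", best))
    return labels


def summarize_class_fractions(
    labels: Sequence[ActivityLabel], classes: Sequence[str]
) -> pd.DataFrame:
    """Per-class counts and plus-fractions (one label per projection).

    Returns rows for DC, IC, NC and UNPROJECTABLE with columns
    ``class, n, n_plus, fraction_plus``; fractions are 0 for empty classes.
    """
    if len(labels) != len(classes):
        raise ValueError("need exactly one label per projection")
    order = ["DC", "IC", "NC", "UNPROJECTABLE"]
    counts = {c: [0, 0] for c in order}
    for lab, cls in zip(labels, classes):
        if cls not in counts:
            raise ValueError(f"unknown class {cls!r}")
        counts[cls][0] += 1
        if lab.label == "plus":
            counts[cls][1] += 1
    rows = [
        {
            "class": c,
            "n": n,
            "n_plus": n_plus,
            "fraction_plus": (n_plus / n) if n else 0.0,
        }
        for c, (n, n_plus) in counts.items()
    ]
    return pd.DataFrame(rows, columns=["class", "n", "n_plus", "fraction_plus"])


def sample_background_peak(
    query: GenomicInterval,
    ortholog_peak: GenomicInterval,
    peaks: Sequence[GenomicInterval],
    tads: Optional[Sequence[GenomicInterval]] = None,
    rng: "np.random.Generator | int | None" = None,
) -> BackgroundPair:
    """Draw a random nonortholog peak, preferring the query's TAD.

    The TAD containing the ortholog peak's midpoint restricts the candidate
    pool; when no TAD file is given or no other peak falls in that TAD the
    draw is genome-wide with ``same_tad=False``.  Deterministic for a given
    seed; raises when the ortholog peak is the only peak.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    others = [p for p in peaks if p != ortholog_peak]
    if not others:
        raise ValueError("no valid background: only one peak available")
    pool, same_tad = others, False
    if tads is not None:
        mid = ortholog_peak.midpoint
        tad = next(
            (t for t in tads if t.chrom == ortholog_peak.chrom and t.contains(mid)),
            None,
        )
        if tad is not None:
            in_tad = [
                p
                for p in others
                if p.chrom == tad.chrom and p.midpoint >= tad.start and p.midpoint < tad.end
            ]
            if in_tad:
                pool, same_tad = in_tad, True
    choice = pool[int(rng.integers(len(pool)))]
    return BackgroundPair(query=query, background_peak=choice, same_tad=same_tad)
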