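"""Shared-motif counting and TFBS-order shuffling between ortholog CRE pairs.

Each CRE carries a list of motif hits inside its 500-bp window.  Two
orthologs are compared by (1) how many motif hits they share (per-motif
minimum counts) and (2) how shuffled the 5'->3' order of their shared
motifs is, measured as the normalized Kendall tau rank distance K_d: the
number of discordant motif pairs divided by n(n-1)/2.

Before ranking, hits are cleaned: overlapping hits of the same motif keep
only the higher score; hits of different motifs overlapping by at least
``min_cross_overlap`` bp (default 8) keep only the higher score; contiguous
runs of one motif collapse to a single occurrence.  A motif recurring
noncontiguously (e.g. A,B,C,A,D) yields a matrix of unique ranking rows
({A,B,C,D} and {B,C,A,D}), and K_d is the minimum over all row pairs and
both orientations of the second list.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Optional, Sequence, Tuple

import pandas as pd

from .chain_io import GenomicInterval


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence inside a CRE window."""

    motif_id: str
    interval: GenomicInterval
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass(frozen=True)
class RankingSet:
    """Unique 5'->3' motif orderings of one CRE's shared motifs.

    ``rows`` are permutations of one motif set; multiple rows arise when a
    motif recurs noncontiguously.
    """

    rows: Tuple[Tuple[str, ...], ...]

    def __post_init__(self) -> None:
        motif_sets = {frozenset(r) for r in self.rows}
        if len(motif_sets) != 1:
            raise ValueError("all ranking rows must cover the same motif set")
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("ranking rows must be pairwise distinct")

    @property
    def motifs(self) -> frozenset:
        return frozenset(self.rows[0])


@dataclass(frozen=True)
class KendallResult:
    pair_id: str
    n_shared: int
    k_d: float
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_d <= 1.0):
            raise ValueError("k_d must lie in [0, 1]")


class RankingError(ValueError):
    """Raised when a CRE pair cannot produce a ranking (e.g. < 2 motifs)."""


def dedupe_same_motif_hits(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Drop overlapping hits of the same motif, keeping the higher score.

    Greedy by descending score (ties by lower start): a hit survives only if
    it does not overlap an already-kept hit of the same motif.  Output in
    5'->3' order.
    """
    kept: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.interval.start)):
        if any(
            k.motif_id == hit.motif_id and k.interval.overlap_len(hit.interval) > 0
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.interval.start, h.interval.end))
    return kept


def count_shared_motifs(
    hits_a: Sequence[MotifHit], hits_b: Sequence[MotifHit]
) -> Tuple[Counter, int]:
    """Shared motif multiset between two deduped hit lists.

    Per motif, the shared count is min(count_a, count_b); ``n_shared`` sums
    these over motifs.
    """
    ca = Counter(h.motif_id for h in hits_a)
    cb = Counter(h.motif_id for h in hits_b)
    shared = Counter(
        {m: min(ca[m], cb[m]) for m in ca if m in cb and min(ca[m], cb[m]) > 0}
    )
    return shared, sum(shared.values())


def filter_cross_motif_overlaps(
    hits: Sequence[MotifHit], min_cross_overlap: int = 8
) -> list[MotifHit]:
    """Resolve >= ``min_cross_overlap`` bp overlaps between different motifs.

    Greedy by descending score (ties by lower start); the survivor set is a
    fixed point of the filter (idempotent).  Same-motif overlaps are assumed
    already deduped.
    """
    kept: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.interval.start)):
        if any(
            k.motif_id != hit.motif_id
            and k.interval.overlap_len(hit.interval) >= min_cross_overlap
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.interval.start, h.interval.end))
    return kept


def _collapse_runs(order: Sequence[str]) -> list[str]:
    out: list[str] = []
    for m in order:
        if not out or out[-1] != m:
            out.append(m)
    return out


def _expand_rows(order: Sequence[str], max_rows: int = 4096) -> Tuple[Tuple[str, ...], ...]:
    """Unique ranking rows from a motif order with noncontiguous recurrences.

    Each row keeps exactly one occurrence per motif; rows are the distinct
    orderings induced by every combination of kept occurrences.
    """
    positions: dict[str, list[int]] = {}
    for i, m in enumerate(order):
        positions.setdefault(m, []).append(i)
    motifs = list(positions)
    n_comb = math.prod(len(v) for v in positions.values())
    if n_comb > max_rows:
        raise RankingError(
            f"{n_comb} occurrence combinations exceed the {max_rows} row cap"
        )
    rows = set()
    for combo in itertools.product(*(positions[m] for m in motifs)):
        chosen = dict(zip(motifs, combo))
        row = tuple(sorted(motifs, key=lambda m: chosen[m]))
        rows.add(row)
    return tuple(sorted(rows))


def prepare_ranking(
    hits: Sequence[MotifHit], min_cross_overlap: int = 8
) -> RankingSet:
    """Build the ranking matrix for one CRE's shared-motif hits.

    Applies the cross-motif overlap filter, collapses same-motif runs, and
    expands noncontiguous recurrences into unique ranking rows.  Raises
    :class:`RankingError` when fewer than 2 distinct motifs remain.
    """
    filtered = filter_cross_motif_overlaps(hits, min_cross_overlap)
    order = _collapse_runs([h.motif_id for h in filtered])
    if len(set(order)) < 2:
        raise RankingError(
            f"only {len(set(order))} distinct motif(s) after filtering"
        )
    return RankingSet(_expand_rows(order))


def _discordant_pairs(a: Sequence[str], b: Sequence[str]) -> int:
    rank_b = {m: i for i, m in enumerate(b)}
    n = len(a)
    disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            if rank_b[a[i]] > rank_b[a[j]]:
                disc += 1
    return disc


def normalized_kendall_min(
    ranking_a: RankingSet, ranking_b: RankingSet, pair_id: str = ""
) -> KendallResult:
    """Minimum normalized Kendall tau distance between two ranking sets.

    K_d(row_a, row_b) = #discordant pairs / (n(n-1)/2); the result is the
    minimum over all row pairs of the two matrices and both orientations
    (forward / reversed) of ``ranking_b``.  Forward wins ties.
    """
    if ranking_a.motifs != ranking_b.motifs:
        raise ValueError(
            "rankings cover different motif sets: "
            f"{sorted(ranking_a.motifs)} vs {sorted(ranking_b.motifs)}"
        )
    n = len(ranking_a.rows[0])
    if n < 2:
        raise ValueError("need at least 2 motifs")
    denom = n * (n - 1) / 2
    best: Optional[Tuple[float, str]] = None
    for row_a in ranking_a.rows:
        for row_b in ranking_b.rows:
            for orientation, rb in (
                ("forward", row_b),
                ("reverse", tuple(reversed(row_b))),
            ):
                k = _discordant_pairs(row_a, rb) / denom
                key = (k, 0 if orientation == "forward" else 1)
                if best is None or key < (best[0], 0 if best[1] == "forward" else 1):
                    best = (k, orientation)
    assert best is not None
    return KendallResult(pair_id, n, best[0], best[1])


def cohens_d(x: Sequence[float], y: Sequence[float]) -> Tuple[float, str]:
    """Cohen's d with pooled SD, plus a magnitude label.

    d = (mean(x) - mean(y)) / s_pooled with
    s_pooled = sqrt(((n_x-1) s_x^2 + (n_y-1) s_y^2) / (n_x + n_y - 2)).
    Labels on |d|: < 0.2 small, <= 0.5 medium, > 0.5 large.
    """
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need >= 2 observations")
    sx, sy = stdev(x), stdev(y)
    pooled = math.sqrt(((nx - 1) * sx**2 + (ny - 1) * sy**2) / (nx + ny - 2))
    if pooled == 0:
        if mean(x) == mean(y):
            return 0.0, "small"
        raise ValueError("pooled SD is 0 with unequal means: d undefined")
    d = (mean(x) - mean(y)) / pooled
    mag = abs(d)
    label = "small" if mag < 0.2 else ("medium" if mag <= 0.5 else "large")
    return d, label


def kendall_pipeline(
    pairs: Sequence[Tuple[str, str, Sequence[MotifHit], Sequence[MotifHit]]],
    min_shared: int = 6,
    min_cross_overlap: int = 8,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """K_d for every CRE pair with enough shared TFBS, grouped by class.

    ``pairs`` holds (pair_id, conservation class, hits_a, hits_b).  Each
    pair's hits are deduped, pairs with fewer than ``min_shared`` shared
    TFBS are dropped, the remaining hits are restricted to the shared motif
    set, ranked and compared.  Returns (per-pair results, per-class summary
    with n, median K_d); classes with no surviving pairs appear with n=0.
    """
    rows = []
    n_dropped = 0
    for pair_id, cls, hits_a, hits_b in pairs:
        da = dedupe_same_motif_hits(hits_a)
        db = dedupe_same_motif_hits(hits_b)
        shared, n_shared = count_shared_motifs(da, db)
        if n_shared < min_shared:
            n_dropped += 1
            continue
        ra = [h for h in da if h.motif_id in shared]
        rb = [h for h in db if h.motif_id in shared]
        try:
            rank_a = prepare_ranking(ra, min_cross_overlap)
            rank_b = prepare_ranking(rb, min_cross_overlap)
        except RankingError:
            n_dropped += 1
            continue
        if rank_a.motifs != rank_b.motifs:
            # the cross-motif filter removed different motifs on each side;
            # restrict both rankings to the common survivors
            common = rank_a.motifs & rank_b.motifs
            if len(common) < 2:
                n_dropped += 1
                continue
            rank_a = RankingSet(
                tuple(sorted({tuple(m for m in r if m in common) for r in rank_a.rows}))
            )
            rank_b = RankingSet(
                tuple(sorted({tuple(m for m in r if m in common) for r in rank_b.rows}))
            )
        res = normalized_kendall_min(rank_a, rank_b, pair_id)
        rows.append(
            {
                "pair_id": pair_id,
                "class": cls,
                "n_shared": n_shared,
                "k_d": res.k_d,
                "orientation": res.orientation,
            }
        )
    results = pd.DataFrame(
        rows, columns=["pair_id", "class", "n_shared", "k_d", "orientation"]
    )
    summary_rows = []
    for cls in ["DC", "IC", "NC"]:
        sub = results[results["class"] == cls]
        summary_rows.append(
            {
                "class": cls,
                "n": len(sub),
                "median_k_d": float(sub["k_d"].median()) if len(sub) else float("nan"),
            }
        )
    summary = pd.DataFrame(summary_rows, columns=["class", "n", "median_k_d"])
    results.attrs["n_dropped"] = n_dropped
    return results, summary


def class_effect_sizes(results: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Cohen's d of K_d between conservation classes.

    Class pairs where either side has < 2 results are skipped.
    """
    rows = []
    for ca, cb in itertools.combinations(["DC", "IC", "NC"], 2):
        xa = results.loc[results["class"] == ca, "k_d"].tolist()
        xb = results.loc[results["class"] == cb, "k_d"].tolist()
        if len(xa) < 2 or len(xb) < 2:
            continue
        try:
            d, label = cohens_d(xa, xb)
        except ValueError:
            continue
        rows.append({"class_a": ca, "class_b": cb, "cohens_d": d, "magnitude": label})
    return pd.DataFrame(rows, columns=["class_a", "class_b", "cohens_d", "magnitude"])
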