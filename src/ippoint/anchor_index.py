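"""Sorted-array index over anchor blocks for nearest-anchor queries.

The index serves one species pair and answers, for a point on either genome:
which anchor contains it, and which anchors flank it up- and downstream on
the same chromosome.  The distance ``d`` to the nearest anchor edge is the
quantity the projection classifier thresholds on.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

from .chain_io import AnchorBlock, GenomicInterval


@dataclass(frozen=True)
class AnchorNeighborhood:
    """Anchors around a query position on one genome of the pair.

    ``containing`` is set when the position lies inside an anchor (then
    ``d == 0``); otherwise ``upstream`` is the nearest anchor ending at or
    before the position and ``downstream`` the nearest starting after it,
    and ``d`` is the bp distance to the nearer of the two facing edges
    (ties broken toward upstream).  With half-open ends a position exactly at
    an anchor's exclusive end has upstream distance 0 without being contained.
    All fields are ``None``/``d is None`` when the chromosome has no anchors.
    """

    containing: Optional[AnchorBlock] = None
    upstream: Optional[AnchorBlock] = None
    downstream: Optional[AnchorBlock] = None
    d: Optional[int] = None

    @property
    def empty(self) -> bool:
        return (
            self.containing is None
            and self.upstream is None
            and self.downstream is None
        )


class _ChromIndex:
    """Per-chromosome sorted structures over one side of the anchors."""

    __slots__ = ("starts", "by_start", "maxend", "ends", "by_end")

    def __init__(self, blocks: list[tuple[GenomicInterval, AnchorBlock]]):
        by_start = sorted(blocks, key=lambda t: (t[0].start, t[0].end))
        self.starts = [iv.start for iv, _ in by_start]
        self.by_start = by_start
        # running max of ends, for bounded backward scans in containing queries
        self.maxend = []
        m = 0
        for iv, _ in by_start:
            m = max(m, iv.end)
            self.maxend.append(m)
        by_end = sorted(blocks, key=lambda t: (t[0].end, t[0].start))
        self.ends = [iv.end for iv, _ in by_end]
        self.by_end = by_end


class AnchorIndex:
    """Index of anchor blocks for one species pair, queryable from either side."""

    def __init__(self, anchors: Sequence[AnchorBlock]):
        anchors = list(anchors)
        pairs = {(blk.species_a, blk.species_b) for blk in anchors}
        if len(pairs) > 1:
            raise ValueError(f"anchors span multiple species pairs: {pairs}")
        if anchors:
            self.species_pair = anchors[0].species_a, anchors[0].species_b
        else:
            self.species_pair = (None, None)
        self._anchors = anchors
        self._side: dict[str, dict[str, _ChromIndex]] = {}
        for species in self.species_pair:
            if species is None:
                continue
            per_chrom: dict[str, list] = {}
            for blk in anchors:
                iv = blk.interval(species)
                per_chrom.setdefault(iv.chrom, []).append((iv, blk))
            self._side[species] = {
                chrom: _ChromIndex(blocks) for chrom, blocks in per_chrom.items()
            }

    def __len__(self) -> int:
        return len(self._anchors)

    @property
    def anchors(self) -> list[AnchorBlock]:
        return list(self._anchors)

    def _check_species(self, species: str) -> None:
        if species not in self._side:
            raise KeyError(
                f"species {species!r} not in indexed pair {self.species_pair}"
            )

    def locate(self, species: str, chrom: str, pos: int) -> AnchorNeighborhood:
        """Neighborhood of ``pos`` on ``chrom`` of ``species``.

        An unknown chromosome yields an empty neighborhood, not an error;
        so does an index built from zero anchors.  Containing-anchor ties
        are broken by larger block, then lower start.
        """
        if not self._anchors:
            return AnchorNeighborhood()
        self._check_species(species)
        cidx = self._side[species].get(chrom)
        if cidx is None:
            return AnchorNeighborhood()

        # containing: start <= pos < end; scan back while running max end > pos
        containing = None
        hi = bisect.bisect_right(cidx.starts, pos)
        best_key = None
        i = hi - 1
        while i >= 0 and cidx.maxend[i] > pos:
            iv, blk = cidx.by_start[i]
            if iv.end > pos:
                key = (-(len(iv)), iv.start)
                if best_key is None or key < best_key:
                    best_key, containing = key, blk
            i -= 1

        # upstream: max end among blocks with end <= pos
        upstream = None
        j = bisect.bisect_right(cidx.ends, pos)
        if j > 0:
            up_iv, upstream = cidx.by_end[j - 1]
        # downstream: min start among blocks with start > pos
        downstream = None
        if hi < len(cidx.starts):
            down_iv, downstream = cidx.by_start[hi]

        if containing is not None:
            return AnchorNeighborhood(containing, upstream, downstream, 0)
        d_up = pos - up_iv.end if upstream is not None else None
        d_down = down_iv.start - pos if downstream is not None else None
        if d_up is None and d_down is None:
            return AnchorNeighborhood()
        if d_down is None or (d_up is not None and d_up <= d_down):
            d = d_up
        else:
            d = d_down
        return AnchorNeighborhood(None, upstream, downstream, d)

    def nearest_anchor(
        self, species: str, chrom: str, pos: int
    ) -> Optional[AnchorBlock]:
        """Nearest anchor to ``pos`` (containing wins; ties toward upstream)."""
        nb = self.locate(species, chrom, pos)
        if nb.containing is not None:
            return nb.containing
        if nb.upstream is None:
            return nb.downstream
        if nb.downstream is None:
            return nb.upstream
        d_up = pos - nb.upstream.interval(species).end
        d_down = nb.downstream.interval(species).start - pos
        return nb.upstream if d_up <= d_down else nb.downstream


def build_index(anchors: Sequence[AnchorBlock]) -> AnchorIndex:
    """Build an :class:`AnchorIndex`; all anchors must share one species pair."""
    return AnchorIndex(anchors)


def write_index_tsv(index: AnchorIndex, path) -> None:
    """Serialize anchors to a TSV (one row per block, forward coordinates)."""
    with open(path, "w") as fh:
        fh.write(
            "species_a\tchrom_a\tstart_a\tend_a\t"
            "species_b\tchrom_b\tstart_b\tend_b\torientation\n"
        )
        for blk in index.anchors:
            fh.write(
                f"{blk.species_a}\t{blk.a.chrom}\t{blk.a.start}\t{blk.a.end}\t"
                f"{blk.species_b}\t{blk.b.chrom}\t{blk.b.start}\t{blk.b.end}\t"
                f"{blk.orientation}\n"
            )
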