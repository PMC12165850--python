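"""Interspecies point projection (IPP).

A query coordinate is projected to a target genome by interpolating its
position relative to flanking anchor points (ungapped alignment blocks).
When direct anchors are distant, the projection is routed through bridging
species: a uniform-cost search over (species, chrom, pos) states finds the
species path minimizing the summed per-hop distance to anchor points.

Projections are classified by confidence:

* ``DC`` (directly conserved): within ``dc_threshold`` bp (default 300,
  boundary inclusive) of a direct alignment between query and target.
* ``IC`` (indirectly conserved): not DC, but reachable through bridged
  alignments with summed anchor distance strictly below ``ic_threshold``
  (default 2500 bp).
* ``NC`` (nonconserved): a projection exists but meets neither bound.
* ``UNPROJECTABLE``: no direct anchors on the chromosome and no bridged
  path below the IC bound.

Per-hop distance is measured on the source side of the hop (the distance
from the current point to the nearest anchor used), which is what limits
interpolation accuracy.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Optional, Sequence, Tuple

import pandas as pd

from .anchor_index import AnchorIndex, AnchorNeighborhood
from .chain_io import AnchorBlock, GenomicInterval

logger = logging.getLogger(__name__)

PairKey = Tuple[str, str]


class ConservationClass(str, Enum):
    DC = "DC"
    IC = "IC"
    NC = "NC"
    UNPROJECTABLE = "UNPROJECTABLE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ProjectionParams:
    """Thresholds and search limits for projection and classification.

    dc_threshold : bp; DC iff the direct-anchor distance is <= this
        (boundary inclusive, "within").
    ic_threshold : bp; IC iff the best bridged summed distance is < this
        (boundary exclusive, "less than"); also the search pruning bound.
    max_hops : maximum number of pairwise projections in a bridged path.
    min_block_size : bp; anchor blocks below this are ignored at extraction.
    """

    dc_threshold: int = 300
    ic_threshold: int = 2500
    max_hops: int = 4
    min_block_size: int = 10

    def __post_init__(self) -> None:
        if self.dc_threshold <= 0:
            raise ValueError("dc_threshold must be > 0")
        if self.ic_threshold < self.dc_threshold:
            raise ValueError("ic_threshold must be >= dc_threshold")
        if self.max_hops < 1:
            raise ValueError("max_hops must be >= 1")


@dataclass(frozen=True)
class PairwiseProjection:
    """One projection of a point between the two species of an anchor index."""

    source: Tuple[str, str, int]  # (species, chrom, pos)
    target: Tuple[str, str, int]
    d: int  # bp to the nearest anchor on the source side
    mode: str  # "in_block" | "interpolated" | "one_sided"

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.mode == "in_block" and self.d != 0:
            raise ValueError("in_block projections have d == 0")


@dataclass(frozen=True)
class ProjectionPath:
    """A chain of pairwise projections from query species to target species."""

    species_sequence: Tuple[str, ...]
    per_hop: Tuple[PairwiseProjection, ...]
    total_distance: int
    final: Tuple[str, int]  # (chrom, pos) in target species

    def __post_init__(self) -> None:
        if self.total_distance != sum(h.d for h in self.per_hop):
            raise ValueError("total_distance must equal the sum of per-hop d")
        if len(set(self.species_sequence)) != len(self.species_sequence):
            raise ValueError("species_sequence must not repeat species")


@dataclass(frozen=True)
class ProjectionResult:
    query: GenomicInterval
    point: int
    direct: Optional[PairwiseProjection]
    bridged: Optional[ProjectionPath]
    cls: ConservationClass


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def project_pairwise(
    species: str, chrom: str, pos: int, index: AnchorIndex
) -> Optional[PairwiseProjection]:
    """Project one point through one anchor index.

    * inside an anchor: exact offset mapping (orientation-aware), ``d = 0``;
    * between two same-orientation anchors on one target chromosome: linear
      interpolation between the facing anchor edges, rounded to the nearest
      integer;
    * otherwise (single flanking anchor, orientation mismatch, or targets on
      different chromosomes): constant-offset extrapolation from the nearest
      anchor (ties toward upstream).

    Returns ``None`` when the chromosome has no anchors in this index.
    """
    nb = index.locate(species, chrom, pos)
    if nb.empty:
        return None
    source = (species, chrom, pos)

    if nb.containing is not None:
        blk = nb.containing
        tgt_iv = blk.other_interval(species)
        tpos = blk.map_position(species, pos)
        return PairwiseProjection(source, (_other(blk, species), tgt_iv.chrom, tpos), 0, "in_block")

    up, down = nb.upstream, nb.downstream
    if up is not None and down is not None:
        up_src, down_src = up.interval(species), down.interval(species)
        up_tgt, down_tgt = up.other_interval(species), down.other_interval(species)
        if (
            up.orientation == down.orientation
            and up_tgt.chrom == down_tgt.chrom
            and down_src.start > up_src.end
        ):
            frac = (pos - up_src.end) / (down_src.start - up_src.end)
            if up.orientation == "same":
                a_edge, b_edge = up_tgt.end, down_tgt.start
            else:
                # inverted pair: the target-side gap runs backwards
                a_edge, b_edge = up_tgt.start, down_tgt.end
            tpos = _round_half_up(a_edge + frac * (b_edge - a_edge))
            return PairwiseProjection(
                source,
                (_other(up, species), up_tgt.chrom, tpos),
                nb.d,
                "interpolated",
            )

    blk = index.nearest_anchor(species, chrom, pos)
    assert blk is not None
    src_iv = blk.interval(species)
    tgt_iv = blk.other_interval(species)
    offset = pos - src_iv.start
    if blk.orientation == "same":
        tpos = tgt_iv.start + offset
    else:
        tpos = tgt_iv.end - 1 - offset
    return PairwiseProjection(
        source, (_other(blk, species), tgt_iv.chrom, tpos), nb.d, "one_sided"
    )


def _other(blk: AnchorBlock, species: str) -> str:
    return blk.species_b if species == blk.species_a else blk.species_a


def _neighbors(
    indexes: Dict[PairKey, AnchorIndex], species: str
) -> Iterable[Tuple[str, AnchorIndex]]:
    for (a, b), idx in indexes.items():
        if a == species:
            yield b, idx
        elif b == species:
            yield a, idx


def best_bridged_path(
    species: str,
    chrom: str,
    pos: int,
    target_species: str,
    indexes: Dict[PairKey, AnchorIndex],
    params: ProjectionParams = ProjectionParams(),
) -> Optional[ProjectionPath]:
    """Minimum-summed-distance species path from the query point to the target.

    Uniform-cost search over (species, chrom, pos) states; a hop is one
    pairwise projection through the anchor index of a species pair.  Paths
    are pruned once their cumulative distance reaches ``ic_threshold`` or
    their hop count exceeds ``max_hops``; species never repeat within a
    path.  Ties are broken by fewer hops, then lexicographic species order.
    Returns ``None`` when the target is unreachable under pruning.
    """
    # heap entries: (cost, hops, species_seq, chrom, pos, per_hop)
    start = (0, 0, (species,), chrom, pos, ())
    heap = [start]
    while heap:
        cost, hops, seq, cur_chrom, cur_pos, per_hop = heapq.heappop(heap)
        cur_species = seq[-1]
        if cur_species == target_species:
            return ProjectionPath(seq, per_hop, cost, (cur_chrom, cur_pos))
        if hops >= params.max_hops:
            continue
        for nxt, idx in sorted(_neighbors(indexes, cur_species)):
            if nxt in seq:
                continue
            proj = project_pairwise(cur_species, cur_chrom, cur_pos, idx)
            if proj is None:
                continue
            new_cost = cost + proj.d
            if new_cost >= params.ic_threshold:
                continue
            heapq.heappush(
                heap,
                (
                    new_cost,
                    hops + 1,
                    seq + (nxt,),
                    proj.target[1],
                    proj.target[2],
                    per_hop + (proj,),
                ),
            )
    return None


def classify(
    direct: Optional[PairwiseProjection],
    bridged: Optional[ProjectionPath],
    params: ProjectionParams = ProjectionParams(),
) -> ConservationClass:
    """Apply the DC/IC/NC thresholds to a query's projections.

    DC iff a direct projection exists with ``d <= dc_threshold`` (inclusive);
    else IC iff a bridged path exists with ``total_distance < ic_threshold``
    (exclusive); else NC if any projection exists; else UNPROJECTABLE.
    """
    if direct is not None and direct.d <= params.dc_threshold:
        return ConservationClass.DC
    if bridged is not None and bridged.total_distance < params.ic_threshold:
        return ConservationClass.IC
    if direct is not None or bridged is not None:
        return ConservationClass.NC
    return ConservationClass.UNPROJECTABLE


def project_point(
    species: str,
    chrom: str,
    pos: int,
    target_species: str,
    indexes: Dict[PairKey, AnchorIndex],
    params: ProjectionParams = ProjectionParams(),
) -> Tuple[Optional[PairwiseProjection], Optional[ProjectionPath], ConservationClass]:
    """Direct projection, best bridged path and class for one point."""
    direct_idx = indexes.get((species, target_species)) or indexes.get(
        (target_species, species)
    )
    direct = None
    if direct_idx is not None:
        direct = project_pairwise(species, chrom, pos, direct_idx)
    bridged = best_bridged_path(
        species, chrom, pos, target_species, indexes, params
    )
    return direct, bridged, classify(direct, bridged, params)


PROJECTION_COLUMNS = [
    "qchrom",
    "qstart",
    "qend",
    "qname",
    "point",
    "tchrom_direct",
    "tpos_direct",
    "d_direct",
    "tchrom_bridged",
    "tpos_bridged",
    "d_bridged_sum",
    "path",
    "class",
]


def project_regions(
    regions: Sequence[GenomicInterval],
    query_species: str,
    target_species: str,
    indexes: Dict[PairKey, AnchorIndex],
    params: ProjectionParams = ProjectionParams(),
    summits: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Project each region's point (midpoint, or given summit) to the target.

    Returns one row per region with direct and bridged coordinates, the
    summed distances, the species path and the conservation class.  Regions
    on chromosomes absent from every index come back UNPROJECTABLE.
    """
    rows = []
    for i, region in enumerate(regions):
        point = summits[i] if summits is not None else region.midpoint
        direct, bridged, cls = project_point(
            query_species, region.chrom, point, target_species, indexes, params
        )
        rows.append(
            {
                "qchrom": region.chrom,
                "qstart": region.start,
                "qend": region.end,
                "qname": region.name if region.name else f"region_{i}",
                "point": point,
                "tchrom_direct": direct.target[1] if direct else None,
                "tpos_direct": direct.target[2] if direct else None,
                "d_direct": direct.d if direct else None,
                "tchrom_bridged": bridged.final[0] if bridged else None,
                "tpos_bridged": bridged.final[1] if bridged else None,
                "d_bridged_sum": bridged.total_distance if bridged else None,
                "path": "->".join(bridged.species_sequence) if bridged else None,
                "class": cls.value,
            }
        )
    table = pd.DataFrame(rows, columns=PROJECTION_COLUMNS)
    counts = table["class"].value_counts().to_dict() if len(table) else {}
    logger.info(
        "projected %d regions %s->%s: %s",
        len(table),
        query_species,
        target_species,
        {c.value: counts.get(c.value, 0) for c in ConservationClass},
    )
    return table
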