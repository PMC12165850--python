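"""Synthetic multispecies syntenic genomes with ground-truth orthology.

The simulator lays out an ancestral chromosome as ``n_anchors`` colinear
anchor slots separated by spacers, then evolves it along a species tree:

* each anchor accrues divergence independently on every branch (an
  exponential increment with mean equal to the branch length); an anchor is
  alignable between two species iff its summed divergence along the tree
  path between them stays below the threshold ``theta``.  A bridge at
  intermediate distance can therefore align to both endpoints of a pair
  that no longer aligns directly — the regime bridged projection exploits;
* spacer lengths are resampled per species from a lognormal (an indel
  model), so orthologous positions drift apart while staying interpolable;
* optionally a contiguous anchor run is inverted in one species to
  exercise minus-strand chain handling.

True ortholog positions are tracked by piecewise-linear coordinate maps;
chain files are emitted per species pair from the surviving anchors.  A
separate brute-force projector (linear scans + exhaustive path
enumeration) computes expected conservation classes; it shares only the
definitions with the production algorithm, not its code paths.

``simulate_motif_pairs`` builds paired motif-hit lists where list B is list
A after a known number of disjoint adjacent transpositions, for calibrating
the Kendall-tau shuffling statistics.

This is a fixture device, not a claim about molecular evolution: it is the
minimal generative model producing direct-alignment failure with bridged
survival.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chain_io import AnchorBlock, ChainAlignment, GenomicInterval, write_bed, write_chain
from .core import ConservationClass, ProjectionParams

CHROM = "chr1"


@dataclass(frozen=True)
class SpeciesTree:
    """Unrooted species tree as (node, node, branch length) edges."""

    edges: Tuple[Tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        for a, b, ln in self.edges:
            if ln < 0:
                raise ValueError(f"negative branch length on {a}-{b}")
        species = self.species
        if len(species) != len(self.edges) + 1:
            raise ValueError("edges must form a tree (n_nodes == n_edges + 1)")
        # connectivity check via BFS from an arbitrary node
        if species and len(self._reachable(species[0])) != len(species):
            raise ValueError("tree is not connected")

    @property
    def species(self) -> List[str]:
        seen: List[str] = []
        for a, b, _ in self.edges:
            for s in (a, b):
                if s not in seen:
                    seen.append(s)
        return seen

    def _adjacency(self) -> Dict[str, List[Tuple[str, int]]]:
        adj: Dict[str, List[Tuple[str, int]]] = {}
        for i, (a, b, _) in enumerate(self.edges):
            adj.setdefault(a, []).append((b, i))
            adj.setdefault(b, []).append((a, i))
        return adj

    def _reachable(self, start: str) -> set:
        adj = self._adjacency()
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt, _ in adj.get(node, []):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    def path_edges(self, a: str, b: str) -> List[int]:
        """Edge indices on the unique path between two species."""
        adj = self._adjacency()
        prev: Dict[str, Tuple[str, int]] = {}
        stack = [a]
        seen = {a}
        while stack:
            node = stack.pop()
            if node == b:
                break
            for nxt, ei in adj.get(node, []):
                if nxt not in seen:
                    seen.add(nxt)
                    prev[nxt] = (node, ei)
                    stack.append(nxt)
        if b not in seen:
            raise KeyError(f"no path {a} -> {b}")
        path = []
        node = b
        while node != a:
            node, ei = prev[node]
            path.append(ei)
        return path[::-1]

    @staticmethod
    def path(species: Sequence[str], branch_length: float) -> "SpeciesTree":
        """A path (caterpillar) tree with uniform branch lengths."""
        edges = tuple(
            (species[i], species[i + 1], branch_length)
            for i in range(len(species) - 1)
        )
        return SpeciesTree(edges)


@dataclass
class MultispeciesSim:
    """Simulated genomes, divergence and coordinate maps for one run."""

    tree: SpeciesTree
    theta: float
    seed: int
    anchor_len: int
    n_anchors: int
    # per species: layout order of anchor slots along the chromosome,
    # anchor start positions indexed by slot, strand (+1/-1) per slot
    anchor_start: Dict[str, np.ndarray]
    anchor_strand: Dict[str, np.ndarray]
    chrom_sizes: Dict[str, int]
    # per tree edge: divergence increment per anchor
    edge_divergence: np.ndarray  # (n_edges, n_anchors)

    @property
    def species(self) -> List[str]:
        return self.tree.species

    def path_divergence(self, a: str, b: str) -> np.ndarray:
        """Summed per-anchor divergence along the tree path a..b."""
        idx = self.tree.path_edges(a, b)
        return self.edge_divergence[idx].sum(axis=0)

    def alignable(self, a: str, b: str) -> np.ndarray:
        """Boolean per anchor: alignable between species a and b."""
        return self.path_divergence(a, b) < self.theta

    # ---- ground-truth coordinate map -------------------------------------

    def _segment(self, species: str, pos: int) -> Tuple[str, int, int]:
        """Locate ``pos``: ('anchor', slot, ancestral offset) or
        ('spacer', left_slot, bp into spacer) or ('flank', -1/n, offset)."""
        starts = self.anchor_start[species]
        L = self.anchor_len
        order = np.argsort(starts)
        sorted_starts = starts[order]
        i = int(np.searchsorted(sorted_starts, pos, side="right")) - 1
        if i < 0:
            return "flank", -1, int(sorted_starts[0]) - pos
        slot = int(order[i])
        s = int(sorted_starts[i])
        if pos < s + L:
            off = pos - s
            if self.anchor_strand[species][slot] < 0:
                off = L - 1 - off
            return "anchor", slot, off
        if i + 1 < len(sorted_starts):
            return "spacer", i, pos - (s + L)  # i = rank along chromosome
        return "flank", self.n_anchors, pos - (s + L)

    def true_position(self, species_from: str, pos: int, species_to: str) -> Optional[int]:
        """True ortholog position via the piecewise-linear coordinate map.

        Returns ``None`` where orthology is undefined (spacer flanked by
        anchors that are not equivalently adjacent in the target layout,
        which only arises with inversions)."""
        if species_from == species_to:
            return pos
        L = self.anchor_len
        kind, a, b = self._segment(species_from, pos)
        starts_to = self.anchor_start[species_to]
        if kind == "anchor":
            slot, off = a, b
            s_to = int(starts_to[slot])
            if self.anchor_strand[species_to][slot] < 0:
                return s_to + L - 1 - off
            return s_to + off
        order_from = np.argsort(self.anchor_start[species_from])
        order_to = np.argsort(starts_to)
        if kind == "flank":
            if a == -1:
                first = int(order_from[0])
                if int(order_to[0]) != first:
                    return None
                return int(starts_to[first]) - b
            last = int(order_from[-1])
            if int(order_to[-1]) != last:
                return None
            return int(starts_to[last]) + L + b
        # spacer between chromosome-rank a and a+1 in species_from
        left, right = int(order_from[a]), int(order_from[a + 1])
        # find the same ordered adjacency in the target layout
        pos_in_to = {int(s): r for r, s in enumerate(order_to)}
        ra, rb = pos_in_to[left], pos_in_to[right]
        if abs(ra - rb) != 1:
            return None
        gap_from = int(self.anchor_start[species_from][right]) - (
            int(self.anchor_start[species_from][left]) + L
        )
        frac = b / gap_from if gap_from > 0 else 0.0
        if rb == ra + 1:
            left_end_to = int(starts_to[left]) + L
            gap_to = int(starts_to[right]) - left_end_to
            return left_end_to + int(math.floor(frac * gap_to + 0.5))
        # adjacency reversed in target (inversion): walk backwards
        right_end_to = int(starts_to[left]) - 1
        gap_to = int(starts_to[left]) - (int(starts_to[right]) + L)
        return right_end_to - int(math.floor(frac * gap_to + 0.5))

    # ---- chain emission ---------------------------------------------------

    def chains(self, species_a: str, species_b: str) -> List[ChainAlignment]:
        """UCSC chains for one pair, built from its alignable anchors.

        Maximal runs of consecutive, plus-strand alignable anchors become
        multi-block chains; anchors involved in an inversion are emitted as
        single-block chains (minus-strand when the relative orientation is
        inverted)."""
        ok = self.alignable(species_a, species_b)
        L = self.anchor_len
        sa_start, sb_start = self.anchor_start[species_a], self.anchor_start[species_b]
        sa_str, sb_str = self.anchor_strand[species_a], self.anchor_strand[species_b]
        t_size, q_size = self.chrom_sizes[species_a], self.chrom_sizes[species_b]
        chains: List[ChainAlignment] = []
        chain_id = 1

        def flush_run(run: List[int]) -> None:
            nonlocal chain_id
            if not run:
                return
            blocks = []
            for j, k in enumerate(run):
                if j + 1 < len(run):
                    nk = run[j + 1]
                    dt = int(sa_start[nk]) - (int(sa_start[k]) + L)
                    dq = int(sb_start[nk]) - (int(sb_start[k]) + L)
                    blocks.append((L, dt, dq))
                else:
                    blocks.append((L, None, None))
            chains.append(
                ChainAlignment(
                    score=float(L * len(run)),
                    t_name=CHROM,
                    t_size=t_size,
                    t_strand="+",
                    t_start=int(sa_start[run[0]]),
                    t_end=int(sa_start[run[-1]]) + L,
                    q_name=CHROM,
                    q_size=q_size,
                    q_strand="+",
                    q_start=int(sb_start[run[0]]),
                    q_end=int(sb_start[run[-1]]) + L,
                    chain_id=chain_id,
                    blocks=tuple(blocks),
                    species_t=species_a,
                    species_q=species_b,
                )
            )
            chain_id += 1

        run: List[int] = []
        singles: List[int] = []
        for k in range(self.n_anchors):
            plain = sa_str[k] > 0 and sb_str[k] > 0
            if ok[k] and plain:
                if run and k != run[-1] + 1:
                    flush_run(run)
                    run = []
                run.append(k)
            else:
                flush_run(run)
                run = []
                if ok[k]:
                    singles.append(k)
        flush_run(run)

        for k in singles:
            inverted = (sa_str[k] > 0) != (sb_str[k] > 0)
            qs, qe = int(sb_start[k]), int(sb_start[k]) + L
            if inverted:
                q_start, q_end = q_size - qe, q_size - qs
                q_strand = "-"
            else:
                q_start, q_end, q_strand = qs, qe, "+"
            chains.append(
                ChainAlignment(
                    score=float(L),
                    t_name=CHROM,
                    t_size=t_size,
                    t_strand="+",
                    t_start=int(sa_start[k]),
                    t_end=int(sa_start[k]) + L,
                    q_name=CHROM,
                    q_size=q_size,
                    q_strand=q_strand,
                    q_start=q_start,
                    q_end=q_end,
                    chain_id=chain_id,
                    blocks=((L, None, None),),
                    species_t=species_a,
                    species_q=species_b,
                )
            )
            chain_id += 1
        return chains

    def all_chains(self) -> Dict[Tuple[str, str], List[ChainAlignment]]:
        out = {}
        sp = self.species
        for a, b in itertools.combinations(sp, 2):
            out[(a, b)] = self.chains(a, b)
        return out


def simulate_multispecies_anchors(
    tree: SpeciesTree,
    n_anchors: int = 200,
    anchor_len: int = 100,
    spacer_mean: float = 900.0,
    spacer_sigma: float = 0.6,
    theta: float = 1.0,
    seed: int = 42,
    deterministic_divergence: bool = False,
    inverted_run: Optional[Tuple[str, int, int]] = None,
) -> MultispeciesSim:
    """Simulate anchors, per-species genomes and divergence along a tree.

    Spacer lengths are lognormal with mean ``spacer_mean`` (``spacer_sigma``
    = 0 degenerates to fixed spacers).  ``deterministic_divergence`` makes
    every anchor's per-branch increment exactly the branch length (useful
    for constructing exact alignability patterns).  ``inverted_run``
    = (species, lo, hi) reverses anchor slots ``lo..hi-1`` in that species.
    Fully deterministic given ``seed``.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if n_anchors < 1 or anchor_len < 1:
        raise ValueError("need n_anchors >= 1 and anchor_len >= 1")
    rng = np.random.default_rng(seed)
    species = tree.species
    n_edges = len(tree.edges)

    if deterministic_divergence:
        edge_div = np.array(
            [[ln] * n_anchors for _, _, ln in tree.edges], dtype=float
        ).reshape(max(n_edges, 0), n_anchors)
    else:
        lens = np.array([ln for _, _, ln in tree.edges], dtype=float)
        edge_div = lens[:, None] * rng.exponential(1.0, size=(n_edges, n_anchors))

    mu = math.log(spacer_mean) - spacer_sigma**2 / 2 if spacer_mean > 0 else 0.0

    def draw_spacers(n: int) -> np.ndarray:
        if spacer_sigma == 0:
            return np.full(n, max(1, round(spacer_mean)), dtype=int)
        raw = rng.lognormal(mean=mu, sigma=spacer_sigma, size=n)
        return np.maximum(1, np.round(raw)).astype(int)

    anchor_start: Dict[str, np.ndarray] = {}
    anchor_strand: Dict[str, np.ndarray] = {}
    chrom_sizes: Dict[str, int] = {}
    for sp in species:
        layout = list(range(n_anchors))
        strand = np.ones(n_anchors, dtype=int)
        if inverted_run is not None and inverted_run[0] == sp:
            lo, hi = inverted_run[1], inverted_run[2]
            layout = layout[:lo] + layout[lo:hi][::-1] + layout[hi:]
            strand[lo:hi] = -1
        spacers = draw_spacers(n_anchors + 1)  # leading flank + gaps + trailing
        starts = np.zeros(n_anchors, dtype=int)
        pos = int(spacers[0])
        for rank, slot in enumerate(layout):
            starts[slot] = pos
            pos += anchor_len + int(spacers[rank + 1])
        anchor_start[sp] = starts
        anchor_strand[sp] = strand
        chrom_sizes[sp] = pos

    sim = MultispeciesSim(
        tree=tree,
        theta=theta,
        seed=seed,
        anchor_len=anchor_len,
        n_anchors=n_anchors,
        anchor_start=anchor_start,
        anchor_strand=anchor_strand,
        chrom_sizes=chrom_sizes,
        edge_divergence=edge_div,
    )
    if not any(
        sim.alignable(a, b).any() for a, b in itertools.combinations(species, 2)
    ):
        warnings.warn(
            "theta so small that no anchor is alignable in any species pair",
            stacklevel=2,
        )
    return sim


# ---- independent brute-force projector (the oracle) -----------------------


def _oracle_pairwise(
    sim: MultispeciesSim, sp_from: str, pos: int, sp_to: str
) -> Optional[Tuple[int, int]]:
    """(target position, d) for one hop, by linear scan over all anchors."""
    ok = sim.alignable(sp_from, sp_to)
    L = sim.anchor_len
    sa, sb = sim.anchor_start[sp_from], sim.anchor_start[sp_to]
    stra, strb = sim.anchor_strand[sp_from], sim.anchor_strand[sp_to]
    best_up = best_down = None  # (edge distance, slot)
    for k in range(sim.n_anchors):
        if not ok[k]:
            continue
        s = int(sa[k])
        if s <= pos < s + L:
            off = pos - s if stra[k] > 0 else s + L - 1 - pos
            t = int(sb[k]) + off if strb[k] > 0 else int(sb[k]) + L - 1 - off
            return t, 0
        if s + L <= pos:
            cand = (pos - (s + L), k)
            if best_up is None or cand < best_up:
                best_up = cand
        elif s > pos:
            cand = (s - pos, k)
            if best_down is None or cand < best_down:
                best_down = cand

    def one_sided(k: int) -> int:
        off = pos - int(sa[k]) if stra[k] > 0 else int(sa[k]) + L - 1 - pos
        return int(sb[k]) + off if strb[k] > 0 else int(sb[k]) + L - 1 - off

    if best_up is None and best_down is None:
        return None
    if best_up is not None and best_down is not None:
        du, ku = best_up
        dd, kd = best_down
        # relative orientation per anchor: same iff strands agree
        same_u = stra[ku] == strb[ku]
        same_d = stra[kd] == strb[kd]
        if same_u == same_d:
            up_end = int(sa[ku]) + L
            frac = (pos - up_end) / (int(sa[kd]) - up_end)
            if same_u:
                # source end edge maps to target end edge when relative-same
                a_edge, b_edge = int(sb[ku]) + L, int(sb[kd])
            else:
                a_edge, b_edge = int(sb[ku]), int(sb[kd]) + L
            return int(math.floor(a_edge + frac * (b_edge - a_edge) + 0.5)), min(du, dd)
        k = ku if du <= dd else kd
        return one_sided(k), min(du, dd)
    if best_up is not None:
        return one_sided(best_up[1]), best_up[0]
    return one_sided(best_down[1]), best_down[0]


def oracle_project(
    sim: MultispeciesSim,
    sp_from: str,
    pos: int,
    sp_to: str,
    params: ProjectionParams = ProjectionParams(),
    bridging: Optional[Sequence[str]] = None,
) -> Tuple[Optional[int], Optional[int], Optional[int], ConservationClass]:
    """Brute-force projection: (d_direct, best bridged sum, bridged pos, class).

    Enumerates every repeat-free species path of at most ``max_hops`` hops
    through the allowed bridging species and takes the minimum summed
    source-side distance.  Classification uses the same DC/IC/NC definitions
    as the production classifier.
    """
    direct = _oracle_pairwise(sim, sp_from, pos, sp_to)
    d_direct = direct[1] if direct is not None else None

    pool = [s for s in (bridging if bridging is not None else sim.species)
            if s not in (sp_from, sp_to)]
    best: Optional[Tuple[int, int]] = None  # (total, final_pos)
    max_bridges = params.max_hops - 1
    for r in range(0, min(len(pool), max_bridges) + 1):
        for mids in itertools.permutations(pool, r):
            seq = (sp_from,) + mids + (sp_to,)
            total = 0
            cur = pos
            feasible = True
            for a, b in zip(seq, seq[1:]):
                hop = _oracle_pairwise(sim, a, cur, b)
                if hop is None:
                    feasible = False
                    break
                cur, d = hop
                total += d
            if feasible and (best is None or total < best[0]):
                best = (total, cur)
    bridged_sum = bridged_pos = None
    if best is not None and best[0] < params.ic_threshold:
        bridged_sum, bridged_pos = best[0], best[1]

    if d_direct is not None and d_direct <= params.dc_threshold:
        cls = ConservationClass.DC
    elif bridged_sum is not None:
        cls = ConservationClass.IC
    elif d_direct is not None:
        cls = ConservationClass.NC
    else:
        cls = ConservationClass.UNPROJECTABLE
    return d_direct, bridged_sum, bridged_pos, cls


@dataclass
class TruthTable:
    """Per-query ground truth: true positions, oracle distances and class."""

    table: pd.DataFrame
    target_species: str
    params: ProjectionParams

    def lookup(self, qpos: int) -> Tuple[Optional[int], ConservationClass]:
        row = self.table.loc[self.table["qpos"] == qpos]
        if row.empty:
            raise KeyError(f"no truth row for query position {qpos}")
        rec = row.iloc[0]
        true_pos = rec[f"true_pos_{self.target_species}"]
        true_pos = None if pd.isna(true_pos) else int(true_pos)
        return true_pos, ConservationClass(rec["expected_class"])


def build_truth_table(
    sim: MultispeciesSim,
    queries: Sequence[int],
    query_species: str,
    target_species: str,
    params: ProjectionParams = ProjectionParams(),
) -> TruthTable:
    """Run the brute-force oracle for every query position."""
    rows = []
    for qpos in queries:
        rec: dict = {"qchrom": CHROM, "qpos": int(qpos)}
        for sp in sim.species:
            rec[f"true_pos_{sp}"] = sim.true_position(query_species, int(qpos), sp)
        d_direct, bridged_sum, bridged_pos, cls = oracle_project(
            sim, query_species, int(qpos), target_species, params
        )
        rec["d_direct_oracle"] = d_direct
        rec["d_bridged_oracle"] = bridged_sum
        rec["bridged_pos_oracle"] = bridged_pos
        rec["expected_class"] = cls.value
        rows.append(rec)
    return TruthTable(pd.DataFrame(rows), target_species, params)


def sample_queries(
    sim: MultispeciesSim, species: str, n_queries: int, seed: int
) -> np.ndarray:
    """Uniform query positions over the species' chromosome (50 bp margins)."""
    rng = np.random.default_rng(seed)
    size = sim.chrom_sizes[species]
    return np.sort(rng.integers(50, size - 50, size=n_queries))


# ---- motif-pair simulation -------------------------------------------------


@dataclass(frozen=True)
class MotifPairSim:
    pair_id: str
    hits_a: tuple
    hits_b: tuple
    n_motifs: int
    t_transpositions: int
    flipped: bool


def _disjoint_adjacent_swaps(n: int, t: int, rng: np.random.Generator) -> List[int]:
    """t pairwise-disjoint adjacent swap indices in [0, n-2].

    Drawn uniformly over all valid index sets (indices pairwise >= 2 apart)
    by enumeration; n stays small (a CRE window holds few motifs)."""
    if t == 0:
        return []
    if t > n // 2:
        raise ValueError(f"cannot place {t} disjoint adjacent swaps in n={n}")
    valid = [
        combo
        for combo in itertools.combinations(range(n - 1), t)
        if all(b - a >= 2 for a, b in zip(combo, combo[1:]))
    ]
    return list(valid[int(rng.integers(len(valid)))])


def simulate_motif_pairs(
    n_pairs: int,
    n_motifs: "int | Callable[[np.random.Generator], int]" = 6,
    t_transpositions: "int | Callable[[np.random.Generator], int]" = 0,
    orientation_flip_prob: float = 0.0,
    seed: int = 0,
    motif_len: int = 10,
    window: int = 500,
) -> List[MotifPairSim]:
    """Paired motif-hit lists with a known number of adjacent transpositions.

    List B carries the same motifs as list A at the same (sorted) slot
    positions but with ``t`` disjoint adjacent transpositions applied to the
    motif order, and is optionally orientation-flipped (order and coordinates
    reversed within the window).  Each disjoint adjacent transposition
    contributes exactly one discordant pair, so the forward normalized
    Kendall distance of a pair is t / (n(n-1)/2).
    """
    from .tfbs import MotifHit  # deferred to avoid an import cycle

    rng = np.random.default_rng(seed)
    out: List[MotifPairSim] = []
    for p in range(n_pairs):
        n = n_motifs(rng) if callable(n_motifs) else int(n_motifs)
        if n * motif_len > window:
            raise ValueError(
                f"{n} motifs of {motif_len} bp exceed the {window} bp window"
            )
        t = t_transpositions(rng) if callable(t_transpositions) else int(t_transpositions)
        slot = window // n
        starts = [
            i * slot + int(rng.integers(0, slot - motif_len + 1)) for i in range(n)
        ]
        motifs = [f"M{i:02d}" for i in range(n)]
        scores_a = np.round(rng.uniform(5.0, 15.0, size=n), 2)
        order_b = list(motifs)
        for i in _disjoint_adjacent_swaps(n, t, rng):
            order_b[i], order_b[i + 1] = order_b[i + 1], order_b[i]
        scores_b = np.round(rng.uniform(5.0, 15.0, size=n), 2)
        flipped = bool(rng.random() < orientation_flip_prob)
        starts_b = list(starts)
        if flipped:
            starts_b = sorted(window - (s + motif_len) for s in starts_b)
            order_b = order_b[::-1]
        hits_a = tuple(
            MotifHit(motifs[i], GenomicInterval("cre", starts[i], starts[i] + motif_len),
                     float(scores_a[i]))
            for i in range(n)
        )
        hits_b = tuple(
            MotifHit(order_b[i], GenomicInterval("cre", starts_b[i], starts_b[i] + motif_len),
                     float(scores_b[i]))
            for i in range(n)
        )
        out.append(MotifPairSim(f"pair_{p:04d}", hits_a, hits_b, n, t, flipped))
    return out


# ---- the standard fixture and on-disk emission -----------------------------

STANDARD_SPECIES = ("spA", "spB", "spC", "spD")


def standard_fixture(
    seed: int = 42,
    n_anchors: int = 200,
    n_queries: int = 500,
    branch_length: float = 0.45,
    theta: float = 1.0,
    params: ProjectionParams = ProjectionParams(),
) -> Tuple[MultispeciesSim, np.ndarray, TruthTable]:
    """The standard test condition: a 4-species path tree.

    Query species is the first leaf, target the last; the two interior
    species bridge.  Branch lengths put adjacent pairs mostly within the
    alignability threshold while the end-to-end pair frequently exceeds it,
    producing a DC/IC/NC mixture.
    """
    tree = SpeciesTree.path(list(STANDARD_SPECIES), branch_length)
    sim = simulate_multispecies_anchors(
        tree, n_anchors=n_anchors, anchor_len=100, spacer_mean=900.0,
        spacer_sigma=0.6, theta=theta, seed=seed,
    )
    queries = sample_queries(sim, STANDARD_SPECIES[0], n_queries, seed=seed + 1)
    truth = build_truth_table(
        sim, queries, STANDARD_SPECIES[0], STANDARD_SPECIES[-1], params
    )
    return sim, queries, truth


def simulate_activity_peaks(
    sim: MultispeciesSim,
    truth: TruthTable,
    target_species: str,
    seed: int,
    peak_width: int = 200,
    frac_with_peak: float = 0.6,
    n_decoys: int = 100,
) -> List[GenomicInterval]:
    """Target-genome peaks: some at true ortholog positions, plus decoys.

    Peaks sit exactly at the true positions of a random subset of queries,
    so projection error — which grows from DC through NC — translates into
    decreasing overlap fractions.
    """
    rng = np.random.default_rng(seed)
    size = sim.chrom_sizes[target_species]
    peaks = []
    col = f"true_pos_{target_species}"
    for _, row in truth.table.iterrows():
        if pd.isna(row[col]) or rng.random() >= frac_with_peak:
            continue
        center = int(row[col])
        start = max(0, center - peak_width // 2)
        peaks.append(GenomicInterval(CHROM, start, start + peak_width, name="truepeak"))
    for i in range(n_decoys):
        start = int(rng.integers(0, max(1, size - peak_width)))
        peaks.append(GenomicInterval(CHROM, start, start + peak_width, name="decoy"))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def write_fixture(
    sim: MultispeciesSim,
    queries: np.ndarray,
    truth: TruthTable,
    out_dir,
    query_species: str,
    target_species: str,
    seed: int,
) -> dict:
    """Write chains, genomes.tsv, queries.bed, truth.tsv, peaks.bed and a
    ready-to-run config.yaml under ``out_dir``; returns the path map."""
    out = Path(out_dir)
    (out / "chains").mkdir(parents=True, exist_ok=True)
    chain_paths = {}
    for (a, b), chains in sim.all_chains().items():
        path = out / "chains" / f"{a}.{b}.chain"
        write_chain(chains, path)
        chain_paths[(a, b)] = path
    with open(out / "genomes.tsv", "w") as fh:
        fh.write("species\tchrom\tsize\n")
        for sp in sim.species:
            fh.write(f"{sp}\t{CHROM}\t{sim.chrom_sizes[sp]}\n")
    write_bed(
        [
            GenomicInterval(CHROM, int(q) - 1 if int(q) > 0 else 0, int(q) + 1,
                            name=f"q{i:04d}")
            for i, q in enumerate(queries)
        ],
        out / "queries.bed",
    )
    truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
    peaks = simulate_activity_peaks(sim, truth, target_species, seed=seed + 2)
    write_bed(peaks, out / "peaks.bed")

    config = {
        "species": list(sim.species),
        "chains": [
            {"a": a, "b": b, "path": str(Path("chains") / f"{a}.{b}.chain")}
            for (a, b) in sim.all_chains()
        ],
        "thresholds": {
            "dc": truth.params.dc_threshold,
            "ic": truth.params.ic_threshold,
            "max_hops": truth.params.max_hops,
            "min_block_size": truth.params.min_block_size,
        },
        "seed": seed,
    }
    import yaml

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return {
        "chains": chain_paths,
        "genomes": out / "genomes.tsv",
        "queries": out / "queries.bed",
        "truth": out / "truth.tsv",
        "peaks": out / "peaks.bed",
        "config": out / "config.yaml",
    }
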