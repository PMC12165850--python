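"""Reading and writing UCSC chain alignments and BED intervals.

A chain file describes a colinear pairwise genome alignment as a header line

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by alignment block lines ``size dt dq`` (the last line carries only
``size``).  ``dt``/``dq`` are the gaps to the next block on the target and
query genomes.  When ``qStrand`` is ``-`` the query coordinates are given on
the reverse complement; this module keeps them as written at parse time and
converts to forward-strand coordinates only when decomposing a chain into
ungapped anchor blocks.

All coordinates are 0-based half-open internally (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence


class ChainParseError(ValueError):
    """Raised when a chain file cannot be parsed; names the offending line."""


class ChainIntegrityError(ValueError):
    """Raised when block sums contradict the header spans of a chain."""


class BedParseError(ValueError):
    """Raised for malformed BED rows; names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval: ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ChainAlignment:
    """One chain: header fields plus the ordered block list.

    ``blocks`` holds ``(size, dt, dq)`` triples; the final block has
    ``dt = dq = None``.  Query coordinates are kept exactly as written in the
    file (reverse-complement coordinates when ``q_strand == '-'``).
    """

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: tuple = ()
    species_t: Optional[str] = None
    species_q: Optional[str] = None

    def validate(self) -> None:
        if self.t_strand != "+":
            raise ChainIntegrityError(
                f"chain {self.chain_id}: tStrand must be '+'"
            )
        if not self.blocks:
            raise ChainIntegrityError(f"chain {self.chain_id}: no blocks")
        t_span = q_span = 0
        for i, (size, dt, dq) in enumerate(self.blocks):
            last = i == len(self.blocks) - 1
            if size <= 0:
                raise ChainIntegrityError(
                    f"chain {self.chain_id}: block {i} has size {size} <= 0"
                )
            if last != (dt is None and dq is None):
                raise ChainIntegrityError(
                    f"chain {self.chain_id}: gap fields present on last block "
                    "or missing on an interior block"
                )
            t_span += size + (dt or 0)
            q_span += size + (dq or 0)
        if t_span != self.t_end - self.t_start:
            raise ChainIntegrityError(
                f"chain {self.chain_id}: blocks span {t_span} bp on target "
                f"but header declares {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ChainIntegrityError(
                f"chain {self.chain_id}: blocks span {q_span} bp on query "
                f"but header declares {self.q_end - self.q_start}"
            )


@dataclass(frozen=True)
class AnchorBlock:
    """An ungapped aligned block between two species — one anchor point.

    Both intervals are in forward genome coordinates; ``orientation`` is
    ``"inverted"`` when the block came from a minus-strand query chain.
    """

    species_a: str
    species_b: str
    a: GenomicInterval
    b: GenomicInterval
    orientation: str = "same"  # "same" | "inverted"
    source_chain_id: int = 0

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError(
                f"anchor sides differ in length: {len(self.a)} vs {len(self.b)}"
            )
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def interval(self, species: str) -> GenomicInterval:
        if species == self.species_a:
            return self.a
        if species == self.species_b:
            return self.b
        raise KeyError(species)

    def other_interval(self, species: str) -> GenomicInterval:
        if species == self.species_a:
            return self.b
        if species == self.species_b:
            return self.a
        raise KeyError(species)

    def map_position(self, species: str, pos: int) -> int:
        """Map ``pos`` (inside this block on ``species``) to the other side."""
        src = self.interval(species)
        dst = self.other_interval(species)
        if not src.contains(pos):
            raise ValueError(f"position {pos} outside block {src}")
        offset = pos - src.start
        if self.orientation == "same":
            return dst.start + offset
        return dst.end - 1 - offset


def read_chain(
    path, species_a: Optional[str] = None, species_b: Optional[str] = None
) -> list[ChainAlignment]:
    """Parse a UCSC chain file.

    ``species_a``/``species_b`` tag the target/query sides of every parsed
    chain so downstream anchor extraction knows which genomes it relates.
    Minus-strand query coordinates are kept as written.
    """
    chains: list[ChainAlignment] = []
    header = None
    blocks: list[tuple] = []
    header_line_no = 0

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks:
            raise ChainParseError(
                f"line {header_line_no}: chain header with no block lines"
            )
        chain = replace(header, blocks=tuple(blocks))
        try:
            chain.validate()
        except ChainIntegrityError as exc:
            raise ChainIntegrityError(
                f"line {header_line_no}: {exc}"
            ) from exc
        chains.append(chain)
        header, blocks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                fields = line.split()
                if len(fields) != 13:
                    raise ChainParseError(
                        f"line {line_no}: chain header has {len(fields)} "
                        "fields, expected 13"
                    )
                try:
                    header = ChainAlignment(
                        score=float(fields[1]),
                        t_name=fields[2],
                        t_size=int(fields[3]),
                        t_strand=fields[4],
                        t_start=int(fields[5]),
                        t_end=int(fields[6]),
                        q_name=fields[7],
                        q_size=int(fields[8]),
                        q_strand=fields[9],
                        q_start=int(fields[10]),
                        q_end=int(fields[11]),
                        chain_id=int(fields[12]),
                        species_t=species_a,
                        species_q=species_b,
                    )
                except ValueError as exc:
                    raise ChainParseError(f"line {line_no}: {exc}") from exc
                header_line_no = line_no
            else:
                if header is None:
                    raise ChainParseError(
                        f"line {line_no}: block line before any chain header"
                    )
                parts = line.split()
                try:
                    if len(parts) == 1:
                        blocks.append((int(parts[0]), None, None))
                    elif len(parts) == 3:
                        blocks.append(
                            (int(parts[0]), int(parts[1]), int(parts[2]))
                        )
                    else:
                        raise ValueError(f"{len(parts)} fields")
                except ValueError as exc:
                    raise ChainParseError(
                        f"line {line_no}: bad block line {line!r} ({exc})"
                    ) from exc
    finish()
    return chains


def write_chain(alignments: Sequence[ChainAlignment], path) -> Path:
    """Write chains in UCSC chain format; refuses invariant-violating input."""
    for aln in alignments:
        aln.validate()
    path = Path(path)
    with open(path, "w") as fh:
        for aln in alignments:
            score = int(aln.score) if aln.score == int(aln.score) else aln.score
            fh.write(
                f"chain {score} {aln.t_name} {aln.t_size} {aln.t_strand} "
                f"{aln.t_start} {aln.t_end} {aln.q_name} {aln.q_size} "
                f"{aln.q_strand} {aln.q_start} {aln.q_end} {aln.chain_id}\n"
            )
            for size, dt, dq in aln.blocks:
                if dt is None:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")
    return path


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 (tab- or space-separated, 0-based half-open).

    Comment (``#``), ``track`` and ``browser`` lines are skipped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if (
                not line.strip()
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise BedParseError(
                    f"line {line_no}: expected >= 3 columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(
                    f"line {line_no}: non-integer coordinates"
                ) from exc
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = None
            if len(cols) > 4 and cols[4] != ".":
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"line {line_no}: non-numeric score"
                    ) from exc
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "+"
            try:
                intervals.append(
                    GenomicInterval(cols[0], start, end, strand, name, score)
                )
            except ValueError as exc:
                raise BedParseError(f"line {line_no}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != "+":
                cols += [
                    iv.name if iv.name is not None else ".",
                    f"{iv.score:g}" if iv.score is not None else "0",
                    iv.strand,
                ]
            fh.write("\t".join(cols) + "\n")
    return path


def extract_anchor_blocks(
    chain: ChainAlignment, min_block_size: int = 10
) -> list[AnchorBlock]:
    """Decompose a chain into ungapped anchor blocks of >= ``min_block_size`` bp.

    Minus-strand query blocks are converted to forward coordinates
    (``pos_fwd = qSize - pos_rev`` applied to both ends) and flagged
    ``orientation="inverted"``.  Output sorted by the target-side start.
    """
    chain.validate()
    species_a = chain.species_t if chain.species_t is not None else "a"
    species_b = chain.species_q if chain.species_q is not None else "b"
    anchors: list[AnchorBlock] = []
    t = chain.t_start
    q = chain.q_start  # strand-local coordinate when q_strand == "-"
    for size, dt, dq in chain.blocks:
        if size >= min_block_size:
            a_iv = GenomicInterval(chain.t_name, t, t + size)
            if chain.q_strand == "+":
                b_iv = GenomicInterval(chain.q_name, q, q + size)
                orientation = "same"
            else:
                b_iv = GenomicInterval(
                    chain.q_name, chain.q_size - (q + size), chain.q_size - q
                )
                orientation = "inverted"
            anchors.append(
                AnchorBlock(
                    species_a=species_a,
                    species_b=species_b,
                    a=a_iv,
                    b=b_iv,
                    orientation=orientation,
                    source_chain_id=chain.chain_id,
                )
            )
        t += size + (dt or 0)
        q += size + (dq or 0)
    anchors.sort(key=lambda blk: (blk.a.chrom, blk.a.start))
    return anchors
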