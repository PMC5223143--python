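"""Genomic intervals, BED I/O, tag counting and peak calling.

Coordinates are 0-based half-open throughout (BED convention).  Sequencing
tags are single-bp 5' positions; a tag at position ``p`` overlaps a region
``[start, end)`` iff ``start <= p < end``.  Strand is carried on intervals
but ignored by all counting operations, since the tag-based assays handled
here (DNase-seq, ChIP-seq, unstranded RNA-seq) are effectively unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import stats


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A named 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def auto_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class RegionSet:
    """An ordered collection of uniquely named :class:`GenomicInterval`.

    Region order is preserved as given; operations that need positional
    lookups sort internally and report results in the original order.
    """

    def __init__(self, regions: Iterable[GenomicInterval], name: str = ""):
        self.name = name
        self.regions: list[GenomicInterval] = []
        seen: set[str] = set()
        for r in regions:
            if not r.id:
                r = GenomicInterval(r.chrom, r.start, r.end, r.strand, r.auto_id())
            if r.id in seen:
                raise ValueError(f"duplicate region id {r.id!r}")
            seen.add(r.id)
            self.regions.append(r)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.regions[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def by_id(self, rid: str) -> GenomicInterval:
        for r in self.regions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def sorted(self) -> "RegionSet":
        return RegionSet(
            sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)),
            name=self.name,
        )

    def total_span(self) -> int:
        """Total bp covered, counting overlapping regions once."""
        span = 0
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            rs.sort(key=lambda r: r.start)
            cur_s, cur_e = rs[0].start, rs[0].end
            for r in rs[1:]:
                if r.start <= cur_e:
                    cur_e = max(cur_e, r.end)
                else:
                    span += cur_e - cur_s
                    cur_s, cur_e = r.start, r.end
            span += cur_e - cur_s
        return span


@dataclass
class TagTrack:
    """Single-bp tag positions for one sample, sorted per chromosome."""

    sample_id: str
    tags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.tags.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and arr.min() < 0:
                raise ValueError("tag positions must be >= 0")
            clean[chrom] = np.sort(arr)
        self.tags = clean

    @property
    def total(self) -> int:
        return int(sum(a.size for a in self.tags.values()))

    @classmethod
    def from_positions(
        cls, sample_id: str, positions: Iterable[tuple[str, int]]
    ) -> "TagTrack":
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in positions:
            by_chrom.setdefault(chrom, []).append(pos)
        return cls(sample_id, {c: np.array(p) for c, p in by_chrom.items()})


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str, name: str = "") -> RegionSet:
    """Read a BED3/BED6 file (tab-separated, no header) into a RegionSet.

    A missing name column yields auto-generated ids ``chrom:start-end``;
    a missing strand column yields strand ``.``.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            rid = parts[3] if len(parts) >= 4 and parts[3] else ""
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                regions.append(GenomicInterval(chrom, start, end, strand, rid))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return RegionSet(regions, name=name)


def write_bed(regions: RegionSet, path: str, scores: Mapping[str, float] | None = None) -> None:
    """Write a RegionSet as BED6 (score column 0 unless ``scores`` given)."""
    with open(path, "w") as fh:
        for r in regions:
            score = scores.get(r.id, 0) if scores else 0
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t{score:g}\t{r.strand}\n")


def read_tag_bed(path: str, sample_id: str = "") -> TagTrack:
    """Read a tag track stored as BED with 1-bp intervals (pos = start).

    Tags form a multiset, so duplicate positions are allowed (unlike region
    ids in :func:`read_bed`).
    """
    positions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                positions.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    return TagTrack.from_positions(sample_id or path, positions)


def write_tag_bed(track: TagTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.tags):
            for pos in track.tags[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


# ---------------------------------------------------------------------------
# Counting and peak calling


def count_tags_in_regions(track: TagTrack, regions: RegionSet) -> np.ndarray:
    """Count tags falling in each region (half-open; multi-overlap counted in all).

    Returns an integer vector in region order.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        pos = track.tags.get(r.chrom)
        if pos is None or pos.size == 0:
            continue
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end, side="left")
        counts[i] = hi - lo
    return counts


def call_peaks(
    track: TagTrack,
    window_bp: int = 200,
    fdr: float = 0.001,
    min_density: float = 35,
) -> RegionSet:
    """Sliding-window Poisson peak scan against a uniform genome background.

    Windows of ``window_bp`` advance in steps of half a window.  The
    background rate is global: (total tags / effective genome span) where the
    span is the sum per chromosome of the maximum tag coordinate + 1.
    Windows significant at BH-FDR < ``fdr`` with at least ``min_density``
    tags are kept and merged (overlapping or book-ended) into maximal peak
    regions; the reported score of a peak is its maximum window count.
    """
    from .difftest import bh_fdr  # local import avoids a cycle

    if track.total == 0:
        raise ValueError("tag track is empty")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if min_density <= 0:
        raise ValueError("min_density must be positive")

    span_total = sum(int(a[-1]) + 1 for a in track.tags.values() if a.size)
    lam = track.total / span_total * window_bp
    step = max(window_bp // 2, 1)

    window_meta = []  # (chrom, start, end, count)
    all_counts = []
    for chrom in sorted(track.tags):
        pos = track.tags[chrom]
        if pos.size == 0:
            continue
        chrom_span = int(pos[-1]) + 1
        starts = np.arange(0, max(chrom_span - window_bp, 0) + step, step)
        ends = starts + window_bp
        c = np.searchsorted(pos, ends, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        for s, e, k in zip(starts, ends, c):
            window_meta.append((chrom, int(s), int(e), int(k)))
        all_counts.append(c)

    counts = np.concatenate(all_counts)
    pvals = stats.poisson.sf(counts - 1, lam)
    qvals = bh_fdr(pvals)
    keep = (qvals < fdr) & (counts >= min_density)

    kept = [window_meta[i] for i in np.flatnonzero(keep)]
    kept.sort(key=lambda w: (w[0], w[1]))
    merged: list[list] = []
    for chrom, s, e, k in kept:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
            merged[-1][3] = max(merged[-1][3], k)
        else:
            merged.append([chrom, s, e, k])

    peaks = [
        GenomicInterval(chrom, s, e, ".", f"peak_{i + 1}")
        for i, (chrom, s, e, _k) in enumerate(merged)
    ]
    return RegionSet(peaks, name=f"peaks:{track.sample_id}")


# ---------------------------------------------------------------------------
# Set operations


def _overlap_pairs(a: RegionSet, b: RegionSet) -> list[tuple[int, int]]:
    """Indices (i, j) of all >=1 bp overlaps between regions of a and b."""
    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, r in enumerate(b):
        b_by_chrom.setdefault(r.chrom, []).append((r.start, r.end, j))
    for lst in b_by_chrom.values():
        lst.sort()
    pairs = []
    for i, r in enumerate(a):
        cands = b_by_chrom.get(r.chrom, ())
        if not cands:
            continue
        starts = np.array([c[0] for c in cands])
        # candidates whose start precedes r.end; filter by end > r.start
        hi = np.searchsorted(starts, r.end, side="left")
        for s, e, j in cands[:hi]:
            if e > r.start:
                pairs.append((i, j))
    return pairs


def concordant_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Regions of ``a`` supported by ``b``, expanded to the union span.

    Each a-region with at least 1 bp of overlap in ``b`` is returned with
    coordinates extended to cover itself and all overlapping b-regions (its
    id is kept).  Used to derive replicate-concordant accessible regions.
    """
    pairs = _overlap_pairs(a, b)
    hits: dict[int, list[int]] = {}
    for i, j in pairs:
        hits.setdefault(i, []).append(j)
    out = []
    for i in sorted(hits):
        r = a[i]
        s = min([r.start] + [b[j].start for j in hits[i]])
        e = max([r.end] + [b[j].end for j in hits[i]])
        out.append(GenomicInterval(r.chrom, s, e, r.strand, r.id))
    return RegionSet(out, name=f"concordant:{a.name}")


@dataclass
class OverlapClasses:
    """Partition of two region sets by coordinate overlap (Venn classes)."""

    a_only: list[str]
    b_only: list[str]
    shared: list[tuple[str, str]]  # (a_id, b_id) pairs

    @property
    def a_shared(self) -> set[str]:
        return {i for i, _ in self.shared}

    @property
    def b_shared(self) -> set[str]:
        return {j for _, j in self.shared}

    def counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "a_shared": len(self.a_shared),
            "b_shared": len(self.b_shared),
        }


def overlap_classes(a: RegionSet, b: RegionSet) -> OverlapClasses:
    """Classify regions of two sets as a-only, b-only, or shared pairs.

    A region overlapping several partners appears in multiple shared pairs
    but is counted once on its own side, so
    ``|a_only| + |a_shared| == |a|``.
    """
    pairs = _overlap_pairs(a, b)
    a_hit = {i for i, _ in pairs}
    b_hit = {j for _, j in pairs}
    return OverlapClasses(
        a_only=[a[i].id for i in range(len(a)) if i not in a_hit],
        b_only=[b[j].id for j in range(len(b)) if j not in b_hit],
        shared=[(a[i].id, b[j].id) for i, j in pairs],
    )
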