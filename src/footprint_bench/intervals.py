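"""Genomic interval primitives, interval arithmetic and BED input/output.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Under this convention abutting intervals (``a.end == b.start``) do *not*
overlap.  Every metric in this package — replicate overlap curves, ChIP-peak
labelling, genome binning — is built on the small set of operations defined
here.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "BedParseError",
    "GenomicInterval",
    "IntervalSet",
    "GenomeBinning",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "intersect",
    "merge",
    "overlap_fraction",
    "make_bins",
    "group_by_label",
]

_VALID_STRANDS = (None, "+", "-", ".")


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region, optionally scored, stranded and labelled.

    Parameters
    ----------
    chrom
        Chromosome name.
    start, end
        0-based half-open coordinates; ``end`` must be strictly greater than
        ``start`` and ``start`` must be non-negative.
    score
        Optional real-valued score (footprint score, peak height, ...).
    strand
        One of ``'+'``, ``'-'``, ``'.'`` or ``None``.  Carried through I/O but
        ignored by every overlap operation.
    label
        Optional free-text label, conventionally a TF name.
    """

    chrom: str
    start: int
    end: int
    score: float | None = None
    strand: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        # Ties broken by (start, end, label) for deterministic ordering.
        return (self.chrom, self.start, self.end, self.label or "")

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in base pairs under half-open semantics (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Members may overlap; :func:`merge` produces a non-overlapping set.  The
    ``is_sorted`` flag records whether members are ordered by
    ``(chrom, start, end, label)``.
    """

    __slots__ = ("intervals", "is_sorted")

    def __init__(
        self, intervals: Iterable[GenomicInterval] = (), *, is_sorted: bool = False
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.is_sorted = bool(is_sorted)

    def sorted(self) -> "IntervalSet":
        """Return a sorted view of this set (self if already flagged sorted)."""
        if self.is_sorted:
            return self
        return IntervalSet(
            sorted(self.intervals, key=GenomicInterval.sort_key), is_sorted=True
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, idx: int) -> GenomicInterval:
        return self.intervals[idx]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self.intervals)}, sorted={self.is_sorted})"


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width tiling of a genome into half-open windows.

    The genome is divided into ``bin_size`` windows per chromosome, the last
    window possibly shorter.  Chromosome order is the insertion order of
    ``chrom_sizes`` (use an ordered mapping; files preserve their line order).
    The conventional bin width for replicate-correlation metrics is 10 kb.
    """

    chrom_sizes: Mapping[str, int]
    bin_size: int = 10_000
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be > 0, got {self.bin_size}")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must not be empty")
        offsets: dict[str, int] = {}
        total = 0
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has length {size}")
            offsets[chrom] = total
            total += self.n_bins_for(size)
        object.__setattr__(self, "_offsets", offsets)

    def n_bins_for(self, length: int) -> int:
        return math.ceil(length / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins_for(s) for s in self.chrom_sizes.values())

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a position; raises KeyError on unknown chrom."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} of length {self.chrom_sizes[chrom]}")
        return self._offsets[chrom] + pos // self.bin_size

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeBinning):
            return NotImplemented
        return (
            dict(self.chrom_sizes) == dict(other.chrom_sizes)
            and self.bin_size == other.bin_size
        )


# ---------------------------------------------------------------------------
# BED / chrom.sizes I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, has_score: bool = False) -> IntervalSet:
    """Read a BED3/BED5/BED6 file into a sorted :class:`IntervalSet`.

    Column 4 (name) is stored as ``label``; column 5 is parsed as ``score``
    when ``has_score`` is true; column 6 as strand.  ``track``/``browser``/
    comment lines and blank lines are skipped.  An empty file yields an empty
    set.  Malformed coordinates raise :class:`BedParseError` naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            label = None
            if len(fields) >= 4 and fields[3] != ".":
                label = fields[3]
            score = None
            if has_score:
                if len(fields) < 5:
                    raise BedParseError(f"{path}:{lineno}: score column missing")
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            strand = None
            if len(fields) >= 6 and fields[5] in ("+", "-", "."):
                strand = fields[5]
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, score=score, strand=strand, label=label)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals).sorted()


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write an :class:`IntervalSet` as BED.

    Emits BED3 when no member carries score/strand/label; otherwise BED5 or
    BED6 with the name column filled with ``label`` or ``'.'``.  Round-trips
    through :func:`read_bed` losslessly for coordinates, scores and labels.
    """
    any_score = any(iv.score is not None for iv in iset)
    any_strand = any(iv.strand is not None for iv in iset)
    any_label = any(iv.label is not None for iv in iset)
    ncols = 3
    if any_label or any_score or any_strand:
        ncols = 5 if not any_strand else 6
    with open(path, "w") as fh:
        for iv in iset:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols >= 5:
                fields.append(iv.label if iv.label is not None else ".")
                fields.append(repr(float(iv.score)) if iv.score is not None else "0")
            if ncols >= 6:
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-dialect chrom.sizes file (2-column TSV: name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def intersect(
    a: IntervalSet, b: IntervalSet
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All overlapping pairs between two sets with their overlap in bp.

    Returns every pair ``(interval_from_a, interval_from_b, overlap_bp)`` with
    ``overlap_bp >= 1``.  Strand is ignored; sets are sorted internally when
    needed.  A sorted sweep keeps the cost near ``O(n + m + pairs)``.
    """
    sa, sb = a.sorted(), b.sorted()
    out: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    # Group b by chromosome for the per-chromosome sweep.
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sb:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    j_by_chrom: dict[str, int] = {c: 0 for c in b_by_chrom}
    for ia in sa:
        bs = b_by_chrom.get(ia.chrom)
        if not bs:
            continue
        j = j_by_chrom[ia.chrom]
        # b intervals ending at or before ia.start cannot overlap this or any
        # later a (a is sorted by start within the chromosome).
        while j < len(bs) and bs[j].end <= ia.start:
            j += 1
        j_by_chrom[ia.chrom] = j
        k = j
        while k < len(bs) and bs[k].start < ia.end:
            ov = ia.overlap_bp(bs[k])
            if ov > 0:
                out.append((ia, bs[k], ov))
            k += 1
    return out


def merge(iset: IntervalSet, min_dist: int = 0) -> IntervalSet:
    """Fuse intervals whose gap is at most ``min_dist`` base pairs.

    Consecutive intervals with ``next.start - prev.end <= min_dist`` are fused
    (inclusive rule); with ``min_dist = 0`` only overlapping or abutting
    intervals fuse.  Fused intervals keep a label only when all members agree;
    scores are dropped.  Output is sorted and non-overlapping.
    """
    if min_dist < 0:
        raise ValueError(f"min_dist must be >= 0, got {min_dist}")
    s = iset.sorted()
    if len(s) == 0:
        return IntervalSet([], is_sorted=True)
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = s[0].chrom, s[0].start, s[0].end
    cur_labels = {s[0].label}
    for iv in list(s)[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= min_dist:
            cur_end = max(cur_end, iv.end)
            cur_labels.add(iv.label)
        else:
            label = cur_labels.pop() if len(cur_labels) == 1 else None
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end, label=label))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_labels = {iv.label}
    label = cur_labels.pop() if len(cur_labels) == 1 else None
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end, label=label))
    return IntervalSet(out, is_sorted=True)


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, mode: str = "query"
) -> float:
    """Fraction of ``a`` covered by ``b`` (``mode='query'``, the default).

    The asymmetric convention matches how replicate footprint overlap is
    scored: the query footprint being tested is the denominator.  With
    ``mode='symmetric'`` the smaller of the two one-sided fractions is
    returned (overlap divided by the longer interval).
    """
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    if mode == "query":
        return ov / a.length
    if mode == "symmetric":
        return ov / max(a.length, b.length)
    raise ValueError(f"unknown mode {mode!r}")


def make_bins(binning: GenomeBinning) -> list[GenomicInterval]:
    """The ordered genome-tiling windows of a :class:`GenomeBinning`.

    Bins tile each chromosome exactly: ``[0, B), [B, 2B), ...`` with the last
    bin ending at the chromosome length, so every base is covered once.
    """
    bins: list[GenomicInterval] = []
    for chrom, size in binning.chrom_sizes.items():
        for start in range(0, size, binning.bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + binning.bin_size, size)))
    return bins


def group_by_label(iset: IntervalSet) -> dict[str, IntervalSet]:
    """Split a labelled set into one sorted IntervalSet per label."""
    groups: dict[str, list[GenomicInterval]] = {}
    for iv in iset:
        if iv.label is None:
            raise ValueError("interval without label in labelled set")
        groups.setdefault(iv.label, []).append(iv)
    return {k: IntervalSet(v).sorted() for k, v in sorted(groups.items())}
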