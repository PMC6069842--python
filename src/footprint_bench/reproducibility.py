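"""Replicate reproducibility metrics.

Three statistics summarise how well two replicate libraries agree:

* **alignment reproducibility** — Pearson correlation of per-bin read counts
  over a fixed genome binning (10 kb by default);
* **open-chromatin (OCR) reproducibility** — Pearson correlation of per-bin
  mean peak height, where each OCR contributes its height over the bases it
  covers and uncovered bases contribute height 0;
* **footprint overlap curves** — for a sweep of required overlap fractions,
  the proportion of replicate-1 footprints that have a replicate-2 footprint
  overlapping them by at least that fraction of their own length.

Correlations are computed on raw values (no log transform) by default; a
``log1p`` flag is available.  A constant input vector raises rather than
silently yielding NaN so degenerate simulations fail loudly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomeBinning, IntervalSet, intersect

__all__ = [
    "BinnedTrack",
    "OverlapCurve",
    "ConstantInputError",
    "bin_fragments",
    "pearson",
    "alignment_reproducibility",
    "ocr_mean_height_track",
    "footprint_overlap_curve",
    "DEFAULT_OVERLAP_THRESHOLDS",
]

#: Default sweep for overlap curves: 1% to 100% in 1% steps.
DEFAULT_OVERLAP_THRESHOLDS = np.arange(1, 101) / 100.0


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass
class BinnedTrack:
    """A real-valued vector with one entry per genome bin, in bin order."""

    binning: GenomeBinning
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.binning.total_bins:
            raise ValueError(
                f"values length {self.values.shape} does not match "
                f"{self.binning.total_bins} bins"
            )

    def to_tsv(self, path: str | Path) -> None:
        """2-column TSV: global bin index, value."""
        with open(path, "w") as fh:
            for i, v in enumerate(self.values):
                fh.write(f"{i}\t{float(v)!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, binning: GenomeBinning) -> "BinnedTrack":
        values = np.zeros(binning.total_bins)
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                idx, val = line.split("\t")
                values[int(idx)] = float(val)
        return cls(binning, values)

    def to_bedgraph(self, path: str | Path) -> None:
        """BEDGRAPH with one record per bin (fixed-step windows)."""
        bs = self.binning.bin_size
        with open(path, "w") as fh:
            i = 0
            for chrom, size in self.binning.chrom_sizes.items():
                for start in range(0, size, bs):
                    fh.write(
                        f"{chrom}\t{start}\t{min(start + bs, size)}\t{float(self.values[i])!r}\n"
                    )
                    i += 1

    @classmethod
    def from_bedgraph(cls, path: str | Path, binning: GenomeBinning) -> "BinnedTrack":
        values = np.zeros(binning.total_bins)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, start, _end, val = line.rstrip("\n").split("\t")
                values[binning.bin_index(chrom, int(start))] += float(val)
        return cls(binning, values)


@dataclass
class OverlapCurve:
    """Proportion of query footprints retained as required overlap grows."""

    thresholds: np.ndarray
    proportions: np.ndarray
    n_footprints: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.thresholds.shape != self.proportions.shape:
            raise ValueError("thresholds and proportions length mismatch")
        if np.any(np.diff(self.proportions) > 1e-12):
            raise ValueError("proportions must be non-increasing in threshold")

    def at(self, threshold: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        if abs(self.thresholds[idx] - threshold) > 1e-9:
            raise KeyError(f"threshold {threshold} not in curve")
        return float(self.proportions[idx])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tproportion\n")
            for t, p in zip(self.thresholds, self.proportions):
                fh.write(f"{t!r}\t{p!r}\n")


def bin_fragments(
    fragments: Iterable, binning: GenomeBinning, position: str = "start"
) -> BinnedTrack:
    """Count fragments per genome bin.

    Each fragment is assigned to exactly one bin by its start coordinate
    (``position='midpoint'`` uses the integer midpoint instead), so the track
    total equals the fragment count.  A fragment on a chromosome unknown to
    the binning raises a KeyError naming it.
    """
    if position not in ("start", "midpoint"):
        raise ValueError(f"unknown position rule {position!r}")
    per_chrom: dict[str, list[int]] = defaultdict(list)
    for frag in fragments:
        chrom, start, end = frag[0], frag[1], frag[2]
        pos = start if position == "start" else (start + end) // 2
        per_chrom[chrom].append(pos)
    values = np.zeros(binning.total_bins)
    for chrom, positions in per_chrom.items():
        if chrom not in binning.chrom_sizes:
            raise KeyError(f"fragment on unknown chromosome {chrom!r}")
        n_bins = binning.n_bins_for(binning.chrom_sizes[chrom])
        idx = np.asarray(positions) // binning.bin_size
        counts = np.bincount(idx, minlength=n_bins)
        off = binning.chrom_offset(chrom)
        values[off : off + n_bins] += counts
    return BinnedTrack(binning, values)


def pearson(x: Sequence[float], y: Sequence[float], log1p: bool = False) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raw values by default; ``log1p`` applies ``log(1 + v)`` first.  Raises
    :class:`ConstantInputError` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if log1p:
        x, y = np.log1p(x), np.log1p(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def alignment_reproducibility(
    track1: BinnedTrack, track2: BinnedTrack, log1p: bool = False,
    bin_filter: np.ndarray | None = None,
) -> float:
    """Pearson correlation of two replicates' per-bin read counts.

    All bins are included by default; ``bin_filter`` (boolean mask over the
    global bin vector) restricts the comparison, e.g. to non-zero bins.
    """
    if track1.binning != track2.binning:
        raise ValueError("tracks are on different binnings")
    x, y = track1.values, track2.values
    if bin_filter is not None:
        x, y = x[bin_filter], y[bin_filter]
    return pearson(x, y, log1p=log1p)


def ocr_mean_height_track(
    ocrs: IntervalSet, binning: GenomeBinning, covered_only: bool = False
) -> BinnedTrack:
    """Per-bin mean peak height of scored open-chromatin regions.

    Each OCR contributes ``height * bp-overlap`` to every bin it touches; the
    bin value is that mass divided by the bin length, i.e. a per-base average
    in which bases outside any OCR count as height 0.  With
    ``covered_only`` the average runs over OCR-covered bases only.  Mass is
    conserved in the default mode: sum(value * bin length) equals
    sum(height * OCR length) for OCRs inside the genome.
    """
    mass = np.zeros(binning.total_bins)
    covered = np.zeros(binning.total_bins)
    bs = binning.bin_size
    for ocr in ocrs:
        if ocr.score is None:
            raise ValueError(f"OCR {ocr.chrom}:{ocr.start}-{ocr.end} has no height")
        if ocr.chrom not in binning.chrom_sizes:
            raise KeyError(f"OCR on unknown chromosome {ocr.chrom!r}")
        chrom_len = binning.chrom_sizes[ocr.chrom]
        off = binning.chrom_offset(ocr.chrom)
        first = ocr.start // bs
        last = (min(ocr.end, chrom_len) - 1) // bs
        for b in range(first, last + 1):
            bin_start, bin_end = b * bs, min((b + 1) * bs, chrom_len)
            ov = min(ocr.end, bin_end) - max(ocr.start, bin_start)
            if ov > 0:
                mass[off + b] += ocr.score * ov
                covered[off + b] += ov
    if covered_only:
        values = np.divide(mass, covered, out=np.zeros_like(mass), where=covered > 0)
        return BinnedTrack(binning, values)
    lengths = np.empty(binning.total_bins)
    i = 0
    for chrom, size in binning.chrom_sizes.items():
        for start in range(0, size, bs):
            lengths[i] = min(start + bs, size) - start
            i += 1
    return BinnedTrack(binning, mass / lengths)


def footprint_overlap_curve(
    fpsA: IntervalSet,
    fpsB: IntervalSet,
    thresholds: Sequence[float] | None = None,
) -> OverlapCurve:
    """Replicate footprint overlap curve.

    For each required overlap fraction ``t`` the curve reports the proportion
    of footprints in ``fpsA`` whose best-overlapping footprint in ``fpsB``
    covers at least ``t`` of their length.  Thresholds must be strictly
    increasing values in (0, 1]; the default sweep is 1%..100% in 1% steps.
    """
    if thresholds is None:
        thresholds = DEFAULT_OVERLAP_THRESHOLDS
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds > 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    n = len(fpsA)
    if n == 0:
        raise ValueError("overlap proportion undefined for an empty query set")
    best = defaultdict(float)
    for a, _b, ov in intersect(fpsA, fpsB):
        key = (a.chrom, a.start, a.end, a.label)
        frac = ov / a.length
        if frac > best[key]:
            best[key] = frac
    # Count per query instance (duplicate intervals share one best fraction).
    fracs = np.array(
        [best.get((a.chrom, a.start, a.end, a.label), 0.0) for a in fpsA]
    )
    proportions = (fracs[:, None] >= thresholds[None, :]).mean(axis=0)
    return OverlapCurve(thresholds, proportions, n_footprints=n)
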