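"""Seeded generator of ground-truth footprinting worlds.

The simulator builds a miniature genome with the statistical structure of a
chromatin-accessibility footprinting study, so that every metric in this
package can be validated against known truth:

* open chromatin regions (OCRs) spaced along each chromosome, each carrying
  a peak height;
* motif sites packed inside OCRs, each assigned a TF cyclically so that
  same-TF sites are well separated, and bound with probability
  ``bound_fraction`` (default 1/11, i.e. ~10 negative sites per positive —
  the class imbalance typical of genome-wide motif scans);
* ChIP peaks constructed by padding bound sites and merging per TF, so a
  site is ChIP-positive exactly when it is truly bound;
* two replicate footprint sets: a bound site is detected with probability
  ``footprint_sensitivity`` and an unbound site with ``footprint_fpr``,
  independently per replicate; true-footprint scores are drawn
  ``Normal(mu + score_separation, 1)`` and false-footprint scores
  ``Normal(mu, 1)``, clipped at 0;
* replicate-correlated per-bin read counts, and PCR-duplicated fragment
  lists with geometric copy numbers ("PCR jackpotting").

Every operation is a pure function of its inputs and an integer seed;
independent sub-streams are derived from the world seed by fixed offsets so
adding an operation never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import chip
from .intervals import (
    GenomeBinning,
    GenomicInterval,
    IntervalSet,
    merge,
    write_bed,
    write_chrom_sizes,
)
from .reproducibility import BinnedTrack

__all__ = [
    "SimParams",
    "SimParamError",
    "SyntheticTruth",
    "Fragment",
    "FragmentSample",
    "simulate_world",
    "simulate_bin_counts",
    "simulate_fragments_with_duplicates",
    "simulate_ocr_heights",
    "deduplicate_fragments",
    "write_world",
]

# Geometry constants of the simulated world (base pairs).
SITE_LEN = 12           # motif site length
SITE_MARGIN = 6         # clearance between a site and its slot boundary
OCR_MARGIN = 150        # clearance between an OCR and its slot boundary
FOOTPRINT_PAD_MAX = 5   # max random extension of a footprint beyond its site
SCORE_MU = 3.0          # baseline mean of the (clipped-normal) score model

# Bin-count intensity model: per-bin gamma intensities with a small shape
# (heavy tail, as empirical accessibility is) and a moderate enrichment of
# OCR-containing bins over background.
GAMMA_SHAPE = 0.2
OCR_BIN_ENRICHMENT = 5.0

# Fraction of unique parent fragments that originate inside an OCR.
OCR_FRAGMENT_WEIGHT = 0.9
FRAGMENT_LEN_RANGE = (80, 200)

# Fixed sub-stream offsets per operation.
_STREAM_LAYOUT = 0
_STREAM_FOOTPRINTS_REP1 = 1
_STREAM_FOOTPRINTS_REP2 = 2
_STREAM_COUNTS = 3
_STREAM_FRAGMENTS_REP1 = 4
_STREAM_FRAGMENTS_REP2 = 5
_STREAM_OCR_HEIGHTS = 6


class SimParamError(ValueError):
    """Simulation parameters are infeasible (e.g. sites don't fit in OCRs)."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of a synthetic footprinting world.

    Defaults describe a desk-scale world: two 1-Mb chromosomes carrying 100
    OCRs of ~500 bp with 5 motif sites each (500 sites over 5 TFs), a 10:1
    unbound:bound imbalance, a conservative detector (moderate sensitivity,
    low false-positive rate), and libraries of 50,000 fragments.
    """

    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_ocrs: int = 100
    ocr_len_mean: int = 500
    sites_per_ocr: int = 5
    n_tfs: int = 5
    bound_fraction: float = 1.0 / 11.0
    footprint_sensitivity: float = 0.6
    footprint_fpr: float = 0.02
    score_separation: float = 2.0
    depth: int = 50_000
    replicate_share: float = 0.8
    dup_geom_p: float = 0.8
    chip_pad: int = 100
    bin_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bound_fraction", "footprint_sensitivity", "footprint_fpr",
                     "replicate_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimParamError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.dup_geom_p <= 1.0:
            raise SimParamError(f"dup_geom_p must be in (0, 1], got {self.dup_geom_p}")
        if self.score_separation < 0:
            raise SimParamError("score_separation must be >= 0")
        for name in ("n_chroms", "chrom_len", "n_ocrs", "ocr_len_mean",
                     "sites_per_ocr", "n_tfs", "depth", "bin_size"):
            if getattr(self, name) <= 0:
                raise SimParamError(f"{name} must be positive")
        if self.n_chroms * self.chrom_len < 2 * self.n_ocrs * self.ocr_len_mean:
            raise SimParamError(
                "genome too small: need n_chroms*chrom_len >= 2*n_ocrs*ocr_len_mean"
            )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_len for i in range(self.n_chroms)}

    @property
    def binning(self) -> GenomeBinning:
        return GenomeBinning(self.chrom_sizes, self.bin_size)


class Fragment(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class FragmentSample:
    """A replicate's fragment list with its unique-parent annotation.

    ``parent_index[i]`` identifies the unique pre-amplification fragment that
    read ``i`` is a PCR copy of; duplicates share identical coordinates and
    strand with their parent.
    """

    fragments: list[Fragment]
    parent_index: np.ndarray

    @property
    def n_parents(self) -> int:
        return int(self.parent_index.max()) + 1 if len(self.fragments) else 0

    def unique_parent_fragments(self) -> list[Fragment]:
        """First copy of each parent, in parent order."""
        seen: dict[int, Fragment] = {}
        for frag, p in zip(self.fragments, self.parent_index):
            seen.setdefault(int(p), frag)
        return [seen[p] for p in sorted(seen)]

    @property
    def duplicate_fraction(self) -> float:
        return 1.0 - self.n_parents / len(self.fragments)


@dataclass
class SyntheticTruth:
    """A complete simulated world with ground truth for every metric."""

    params: SimParams
    binning: GenomeBinning
    ocrs: IntervalSet
    sites: chip.MotifSiteTable        # includes a boolean 'bound' truth column
    chip_peaks: IntervalSet           # labelled by TF
    footprints_rep1: IntervalSet
    footprints_rep2: IntervalSet
    counts_rep1: BinnedTrack
    counts_rep2: BinnedTrack
    fragments_rep1: FragmentSample
    fragments_rep2: FragmentSample


def _rng(seed: int | Sequence[int], stream: int) -> np.random.Generator:
    if isinstance(seed, (int, np.integer)):
        return np.random.default_rng([int(seed), stream])
    return np.random.default_rng([*seed, stream])


def _layout(params: SimParams, rng: np.random.Generator):
    """Place OCRs in per-chromosome slots and sites in per-OCR slots.

    Slotted placement guarantees non-overlap and enforces the clearances
    that keep ChIP peaks from bleeding onto neighbouring same-TF sites.
    """
    min_ocr_len = int(0.7 * params.ocr_len_mean)
    site_slot_min = min_ocr_len // params.sites_per_ocr
    if site_slot_min < SITE_LEN + 2 * SITE_MARGIN:
        raise SimParamError(
            f"sites do not fit: {params.sites_per_ocr} sites need OCRs of at "
            f"least {params.sites_per_ocr * (SITE_LEN + 2 * SITE_MARGIN)} bp"
        )
    # Same-TF sites are sites_per-TF slots apart; the ChIP pad must not reach.
    worst_same_tf_gap = (params.n_tfs - 1) * site_slot_min + SITE_LEN + 2 * SITE_MARGIN
    if params.chip_pad + SITE_LEN >= worst_same_tf_gap:
        raise SimParamError(
            "chip_pad would reach a neighbouring same-TF site; reduce chip_pad "
            "or increase n_tfs / ocr_len_mean"
        )
    if params.chip_pad >= 2 * OCR_MARGIN:
        raise SimParamError("chip_pad must be smaller than the inter-OCR clearance")

    chroms = list(params.chrom_sizes)
    per_chrom = [params.n_ocrs // params.n_chroms] * params.n_chroms
    for i in range(params.n_ocrs % params.n_chroms):
        per_chrom[i] += 1

    ocrs: list[GenomicInterval] = []
    site_rows: list[dict] = []
    for ci, chrom in enumerate(chroms):
        k = per_chrom[ci]
        if k == 0:
            continue
        slot = params.chrom_len // k
        for oi in range(k):
            length = int(rng.uniform(0.7, 1.3) * params.ocr_len_mean)
            if slot < length + 2 * OCR_MARGIN:
                raise SimParamError(
                    f"OCRs do not fit: chromosome slot {slot} bp cannot hold an "
                    f"OCR of {length} bp plus {OCR_MARGIN} bp clearance each side"
                )
            lo = oi * slot + OCR_MARGIN
            hi = oi * slot + slot - length - OCR_MARGIN
            start = int(rng.integers(lo, hi + 1))
            height = float(rng.gamma(2.0, 3.0) + 1.0)
            ocrs.append(GenomicInterval(chrom, start, start + length, score=height))
            # Sites in per-OCR slots, TFs assigned cyclically.
            site_slot = length // params.sites_per_ocr
            tf_offset = int(rng.integers(0, params.n_tfs))
            for si in range(params.sites_per_ocr):
                s_lo = start + si * site_slot + SITE_MARGIN
                s_hi = start + (si + 1) * site_slot - SITE_LEN - SITE_MARGIN
                s_start = int(rng.integers(s_lo, s_hi + 1))
                tf = f"TF{(tf_offset + si) % params.n_tfs}"
                bound = bool(rng.random() < params.bound_fraction)
                site_rows.append(
                    {
                        "chrom": chrom,
                        "start": s_start,
                        "end": s_start + SITE_LEN,
                        "tf": tf,
                        "bound": bound,
                    }
                )
    return IntervalSet(ocrs, is_sorted=True), pd.DataFrame(site_rows)


def _simulate_footprints(
    site_df: pd.DataFrame, params: SimParams, rng: np.random.Generator
) -> IntervalSet:
    """One replicate's scored footprint calls over the site table."""
    fps: list[GenomicInterval] = []
    for row in site_df.itertuples():
        p_detect = params.footprint_sensitivity if row.bound else params.footprint_fpr
        if rng.random() >= p_detect:
            continue
        pad_l = int(rng.integers(0, FOOTPRINT_PAD_MAX + 1))
        pad_r = int(rng.integers(0, FOOTPRINT_PAD_MAX + 1))
        mu = SCORE_MU + (params.score_separation if row.bound else 0.0)
        score = max(0.0, float(rng.normal(mu, 1.0)))
        fps.append(
            GenomicInterval(
                row.chrom, row.start - pad_l, row.end + pad_r,
                score=score, label=row.tf,
            )
        )
    return IntervalSet(fps).sorted()


def _build_chip_peaks(site_df: pd.DataFrame, params: SimParams) -> IntervalSet:
    """Bound sites padded by ``chip_pad`` and merged per TF, labelled by TF."""
    peaks: list[GenomicInterval] = []
    bound = site_df[site_df["bound"]]
    for tf, grp in bound.groupby("tf"):
        ivs = [
            GenomicInterval(
                r.chrom,
                max(0, r.start - params.chip_pad),
                min(params.chrom_len, r.end + params.chip_pad),
                label=tf,
            )
            for r in grp.itertuples()
        ]
        peaks.extend(merge(IntervalSet(ivs)).intervals)
    return IntervalSet(peaks).sorted()


def _ocr_bin_mask(ocrs: IntervalSet, binning: GenomeBinning) -> np.ndarray:
    mask = np.zeros(binning.total_bins, dtype=bool)
    bs = binning.bin_size
    for ocr in ocrs:
        off = binning.chrom_offset(ocr.chrom)
        first = ocr.start // bs
        last = (ocr.end - 1) // bs
        mask[off + first : off + last + 1] = True
    return mask


def _bin_counts(
    binning: GenomeBinning,
    ocrs: IntervalSet,
    depth: int,
    replicate_share: float,
    rng: np.random.Generator,
) -> tuple[BinnedTrack, BinnedTrack]:
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= replicate_share <= 1.0:
        raise ValueError(f"replicate_share must be in [0, 1], got {replicate_share}")
    n = binning.total_bins
    enrich = np.where(_ocr_bin_mask(ocrs, binning), OCR_BIN_ENRICHMENT, 1.0)
    scale = enrich / GAMMA_SHAPE
    shared = rng.gamma(GAMMA_SHAPE, scale, size=n)
    private1 = rng.gamma(GAMMA_SHAPE, scale, size=n)
    private2 = rng.gamma(GAMMA_SHAPE, scale, size=n)
    tracks = []
    for private in (private1, private2):
        lam = replicate_share * shared + (1.0 - replicate_share) * private
        total = lam.sum()
        rate = lam / total if total > 0 else np.full(n, 1.0 / n)
        tracks.append(BinnedTrack(binning, rng.poisson(depth * rate).astype(float)))
    return tracks[0], tracks[1]


def simulate_bin_counts(
    truth: "SyntheticTruth",
    depth: int,
    replicate_share: float,
    seed: int,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Replicate-correlated per-bin read-count tracks.

    Each bin's intensity is ``share * shared + (1 - share) * private`` with
    shared and private components drawn from heavy-tailed gamma distributions
    enriched on OCR-containing bins; counts are Poisson at the given total
    depth.  The Pearson correlation between the two tracks increases
    monotonically with ``replicate_share``.
    """
    return _bin_counts(
        truth.binning, truth.ocrs, depth, replicate_share, _rng(seed, _STREAM_COUNTS)
    )


def _fragments(
    params: SimParams,
    ocrs: IntervalSet,
    depth: int,
    dup_geom_p: float,
    rng: np.random.Generator,
) -> FragmentSample:
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 < dup_geom_p <= 1.0:
        raise ValueError(f"dup_geom_p must be in (0, 1], got {dup_geom_p}")
    copies = rng.geometric(dup_geom_p, size=depth)
    cum = np.cumsum(copies)
    i = int(np.searchsorted(cum, depth, side="left"))
    copies = copies[: i + 1].copy()
    copies[i] -= int(cum[i] - depth)  # truncate so the total equals depth
    n_par = len(copies)

    chroms = np.array(list(params.chrom_sizes))
    ocr_starts = np.array([o.start for o in ocrs])
    ocr_ends = np.array([o.end for o in ocrs])
    ocr_chrom_idx = np.array(
        [list(params.chrom_sizes).index(o.chrom) for o in ocrs]
    )
    lengths = rng.integers(FRAGMENT_LEN_RANGE[0], FRAGMENT_LEN_RANGE[1] + 1, size=n_par)
    in_ocr = rng.random(n_par) < OCR_FRAGMENT_WEIGHT
    chrom_idx = np.empty(n_par, dtype=int)
    starts = np.empty(n_par, dtype=int)
    # OCR-weighted parents: start uniformly inside a random OCR.
    k = int(in_ocr.sum())
    if k and len(ocrs):
        oi = rng.integers(0, len(ocrs), size=k)
        starts[in_ocr] = ocr_starts[oi] + rng.integers(
            0, np.maximum(ocr_ends[oi] - ocr_starts[oi], 1)
        )
        chrom_idx[in_ocr] = ocr_chrom_idx[oi]
    bg = ~in_ocr if len(ocrs) else np.ones(n_par, dtype=bool)
    nb = int(bg.sum())
    if nb:
        chrom_idx[bg] = rng.integers(0, params.n_chroms, size=nb)
        starts[bg] = rng.integers(0, params.chrom_len - FRAGMENT_LEN_RANGE[1], size=nb)
    ends = np.minimum(starts + lengths, params.chrom_len)
    strands = np.where(rng.random(n_par) < 0.5, "+", "-")

    parent_index = np.repeat(np.arange(n_par), copies)
    frags = [
        Fragment(str(chroms[chrom_idx[p]]), int(starts[p]), int(ends[p]), str(strands[p]))
        for p in parent_index
    ]
    return FragmentSample(fragments=frags, parent_index=parent_index)


def simulate_fragments_with_duplicates(
    truth: "SyntheticTruth",
    depth: int,
    dup_geom_p: float,
    seed: int,
) -> FragmentSample:
    """PCR-jackpotted fragment list for one replicate.

    Unique parent fragments are sampled from OCR-weighted positions; each
    parent's copy number is geometric with success probability
    ``dup_geom_p`` (mean 1/p copies), truncated so the total fragment count
    equals ``depth``.  Duplicates share identical coordinates and strand.
    """
    return _fragments(
        truth.params, truth.ocrs, depth, dup_geom_p, _rng(seed, _STREAM_FRAGMENTS_REP1)
    )


def deduplicate_fragments(fragments: Sequence[Fragment]) -> list[Fragment]:
    """One representative per distinct (chrom, start, end, strand).

    Order-stable: the first occurrence is kept.  Idempotent.
    """
    return list(dict.fromkeys(Fragment(*f[:4]) for f in fragments))


def simulate_ocr_heights(
    truth: "SyntheticTruth", replicate_share: float, seed: int
) -> tuple[IntervalSet, IntervalSet]:
    """Per-replicate OCR peak heights with tunable replicate agreement.

    Each replicate's height is ``share * true_height + (1 - share) * private``
    with private noise drawn from the same gamma family as the true heights.
    """
    rng = _rng(seed, _STREAM_OCR_HEIGHTS)
    out = []
    for _rep in range(2):
        ivs = []
        for ocr in truth.ocrs:
            private = float(rng.gamma(2.0, 3.0) + 1.0)
            h = replicate_share * ocr.score + (1.0 - replicate_share) * private
            ivs.append(replace(ocr, score=h))
        out.append(IntervalSet(ivs, is_sorted=truth.ocrs.is_sorted))
    return out[0], out[1]


def simulate_world(params: SimParams) -> SyntheticTruth:
    """Generate a complete synthetic footprinting world.

    Deterministic given ``params.seed``.  Raises :class:`SimParamError` when
    the requested geometry cannot be packed.
    """
    binning = params.binning
    ocrs, site_df = _layout(params, _rng(params.seed, _STREAM_LAYOUT))
    chip_peaks = _build_chip_peaks(site_df, params)

    # ChIP labels are derived geometrically, exactly as a user would derive
    # them from peak files; construction guarantees they equal the truth flag.
    sites_iv = IntervalSet(
        [
            GenomicInterval(r.chrom, r.start, r.end, label=r.tf)
            for r in site_df.itertuples()
        ]
    ).sorted()
    peak_groups = {f"TF{i}": IntervalSet([], is_sorted=True) for i in range(params.n_tfs)}
    for tf, grp in _group_peaks(chip_peaks).items():
        peak_groups[tf] = grp
    table = chip.label_sites(sites_iv, peak_groups)
    # Attach the truth flag by coordinates.
    bound_map = {
        (r.chrom, r.start, r.end, r.tf): r.bound for r in site_df.itertuples()
    }
    table.df["bound"] = [
        bound_map[(r.chrom, r.start, r.end, r.tf)] for r in table.df.itertuples()
    ]
    table.provenance = {
        "generator": "footprint_bench.simulate",
        "params": asdict(params),
        "motif_scan_p_cutoff": 1e-4,  # provenance of the emulated PWM scan
    }

    fps1 = _simulate_footprints(site_df, params, _rng(params.seed, _STREAM_FOOTPRINTS_REP1))
    fps2 = _simulate_footprints(site_df, params, _rng(params.seed, _STREAM_FOOTPRINTS_REP2))
    counts1, counts2 = _bin_counts(
        binning, ocrs, params.depth, params.replicate_share,
        _rng(params.seed, _STREAM_COUNTS),
    )
    frags1 = _fragments(
        params, ocrs, params.depth, params.dup_geom_p,
        _rng(params.seed, _STREAM_FRAGMENTS_REP1),
    )
    frags2 = _fragments(
        params, ocrs, params.depth, params.dup_geom_p,
        _rng(params.seed, _STREAM_FRAGMENTS_REP2),
    )
    return SyntheticTruth(
        params=params,
        binning=binning,
        ocrs=ocrs,
        sites=table,
        chip_peaks=chip_peaks,
        footprints_rep1=fps1,
        footprints_rep2=fps2,
        counts_rep1=counts1,
        counts_rep2=counts2,
        fragments_rep1=frags1,
        fragments_rep2=frags2,
    )


def _group_peaks(chip_peaks: IntervalSet) -> dict[str, IntervalSet]:
    groups: dict[str, list[GenomicInterval]] = {}
    for iv in chip_peaks:
        groups.setdefault(iv.label, []).append(iv)
    return {k: IntervalSet(v).sorted() for k, v in groups.items()}


def write_world(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Emit a simulated world as standard files.

    OCRs, footprints and ChIP peaks as BED5 (score column carries the peak
    height or footprint score; name column the TF label), motif sites as
    BED6-style TSV via the site table, bin counts as BEDGRAPH, fragments as
    BED6, chromosome sizes as a 2-column TSV, and a JSON manifest of the
    simulation parameters for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(truth.ocrs, outdir / "ocrs.bed")
    write_bed(truth.chip_peaks, outdir / "chip_peaks.bed")
    write_bed(truth.footprints_rep1, outdir / "footprints_rep1.bed")
    write_bed(truth.footprints_rep2, outdir / "footprints_rep2.bed")
    truth.sites.to_tsv(outdir / "motif_sites.tsv")
    truth.counts_rep1.to_bedgraph(outdir / "counts_rep1.bedgraph")
    truth.counts_rep2.to_bedgraph(outdir / "counts_rep2.bedgraph")
    for rep, sample in (("rep1", truth.fragments_rep1), ("rep2", truth.fragments_rep2)):
        frag_set = IntervalSet(
            [
                GenomicInterval(f.chrom, f.start, f.end, strand=f.strand)
                for f in sample.fragments
            ]
        ).sorted()
        write_bed(frag_set, outdir / f"fragments_{rep}.bed")
    write_chrom_sizes(truth.params.chrom_sizes, outdir / "chrom.sizes")
    with open(outdir / "params.json", "w") as fh:
        json.dump(asdict(truth.params), fh, indent=2)
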