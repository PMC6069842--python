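"""ChIP-seq recovery: labelling motif sites, ranking by footprint score,
and per-TF ROC/AUC.

The evaluation universe is a table of motif sites (PWM hits), one row per
site, each carrying its TF identity.  A site is *ChIP-positive* when it
overlaps a ChIP-seq peak of its own TF by at least one base pair — the gold
standard for TF binding.  Footprint detections assign a score to every site
they overlap; sites are then ranked (footprinted sites first, by descending
score; unfootprinted sites form a block below all scored sites) and the
ranking is scored against the ChIP labels as a ROC curve.

Two ranking modes are provided.  ``expected`` treats the unfootprinted sites
— and any equal-score group — as exchangeable tied blocks with mid-rank
semantics; the resulting AUC is exactly the Mann–Whitney pair statistic

    AUC = (#(pos above neg) + 1/2 #(tied pairs)) / (n_pos * n_neg)

and equals the expectation over all random orderings of the tied sites.
``permutation`` draws one concrete random ordering of the unfootprinted
block (and of tied scores) from a seed, reproducing the stochastic
ranked-list procedure literally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .intervals import GenomicInterval, IntervalSet, group_by_label, intersect

__all__ = [
    "MotifSiteTable",
    "RocResult",
    "ConfusionCounts",
    "MissingChipPeaksError",
    "UndefinedAUCError",
    "label_sites",
    "assign_footprint_scores",
    "confusion_counts",
    "rank_sites",
    "roc_auc",
    "per_tf_roc",
    "mean_auc",
    "improvement_over_random",
]

_COLUMNS = ["chrom", "start", "end", "tf", "chip_positive", "footprint_score"]


class MissingChipPeaksError(KeyError):
    """A site's TF has no ChIP peak set at all (an empty set is allowed)."""


class UndefinedAUCError(ValueError):
    """AUC is undefined: the TF has zero positives or zero negatives."""


@dataclass
class MotifSiteTable:
    """Motif occurrences with ChIP labels and assigned footprint scores.

    ``df`` holds one row per site with columns ``chrom, start, end, tf,
    chip_positive, footprint_score`` (``footprint_score`` is NaN for sites no
    footprint overlaps).  Extra columns (e.g. a simulator's ``bound`` truth
    flag) are carried through untouched.  ``provenance`` records metadata such
    as the motif database and scan p-value cutoff of the upstream PWM scan.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"MotifSiteTable missing columns: {missing}")
        if self.df["chip_positive"].isna().any():
            raise ValueError("chip_positive must be defined for every row")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.df["tf"].unique())

    def for_tf(self, tf: str) -> pd.DataFrame:
        return self.df[self.df["tf"] == tf]

    def sites(self) -> IntervalSet:
        ivs = [
            GenomicInterval(r.chrom, r.start, r.end, label=r.tf)
            for r in self.df.itertuples()
        ]
        return IntervalSet(ivs).sorted()

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: dict | None = None) -> "MotifSiteTable":
        return cls(pd.read_csv(path, sep="\t"), provenance=provenance or {})


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class RocResult:
    """Per-TF ROC curve and area.

    ``curve`` is an array of (FPR, TPR) points from (0, 0) to (1, 1), both
    coordinates non-decreasing; tied score blocks appear as diagonal
    segments, so the trapezoidal area equals the Mann–Whitney statistic.
    """

    tf: str
    auc: float
    curve: np.ndarray
    n_pos: int
    n_neg: int
    ranking_mode: str
    seed: int | None = None

    def __post_init__(self) -> None:
        area = float(np.trapezoid(self.curve[:, 1], self.curve[:, 0]))
        if abs(area - self.auc) > 1e-9:
            raise ValueError(
                f"curve area {area} disagrees with auc {self.auc} for {self.tf}"
            )


def label_sites(
    sites: IntervalSet, chip_peaks: dict[str, IntervalSet] | IntervalSet
) -> MotifSiteTable:
    """Label motif sites positive/negative against per-TF ChIP peaks.

    A site is ChIP-positive iff it overlaps (>= 1 bp) a peak belonging to its
    own TF; a peak of another TF never confers positivity.  ``chip_peaks``
    may be a mapping TF -> peak set or a single labelled IntervalSet, which
    is grouped by label.  A TF present among the sites but absent from the
    mapping raises :class:`MissingChipPeaksError`; a TF mapped to an empty
    peak set is allowed (all its sites are negative).
    """
    if isinstance(chip_peaks, IntervalSet):
        chip_peaks = group_by_label(chip_peaks)
    site_list = list(sites)
    for iv in site_list:
        if iv.label is None:
            raise ValueError("every site must carry a TF label")
    missing = sorted({iv.label for iv in site_list} - set(chip_peaks))
    if missing:
        raise MissingChipPeaksError(f"no ChIP peak set for TFs: {missing}")

    by_tf: dict[str, list[GenomicInterval]] = {}
    for iv in site_list:
        by_tf.setdefault(iv.label, []).append(iv)
    rows = []
    for tf in sorted(by_tf):
        tf_sites = IntervalSet(by_tf[tf]).sorted()
        positive = {(p.chrom, p.start, p.end) for p, _, _ in intersect(tf_sites, chip_peaks[tf])}
        for iv in tf_sites:
            rows.append(
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "tf": tf,
                    "chip_positive": (iv.chrom, iv.start, iv.end) in positive,
                    "footprint_score": np.nan,
                }
            )
    return MotifSiteTable(pd.DataFrame(rows, columns=_COLUMNS))


def assign_footprint_scores(
    table: MotifSiteTable, footprints: IntervalSet, combine: str = "max"
) -> MotifSiteTable:
    """Attach to each site the score of the footprints overlapping it.

    ``combine='max'`` (default) takes the maximum score over all footprints
    overlapping the site by >= 1 bp — the usual detector-confidence
    convention; ``combine='mean'`` averages instead.  Sites no footprint
    overlaps keep a missing score.  Any unscored footprint raises.
    """
    if combine not in ("max", "mean"):
        raise ValueError(f"unknown combine rule {combine!r}")
    for fp in footprints:
        if fp.score is None:
            raise ValueError(f"unscored footprint {fp.chrom}:{fp.start}-{fp.end}")
    df = table.df.copy()
    site_ivs = [
        GenomicInterval(r.chrom, r.start, r.end, label=str(i))
        for i, r in enumerate(df.itertuples())
    ]
    hits: dict[int, list[float]] = {}
    for s, fp, _ in intersect(IntervalSet(site_ivs), footprints):
        hits.setdefault(int(s.label), []).append(fp.score)
    scores = np.full(len(df), np.nan)
    for i, vals in hits.items():
        scores[i] = max(vals) if combine == "max" else float(np.mean(vals))
    df["footprint_score"] = scores
    return MotifSiteTable(df, provenance=dict(table.provenance))


def confusion_counts(table: MotifSiteTable) -> ConfusionCounts:
    """TP/FP/FN/TN over the site table.

    A site counts as footprinted when it carries a footprint score.  TP =
    ChIP-positive and footprinted, FP = ChIP-negative and footprinted, FN =
    ChIP-positive and unfootprinted, TN = ChIP-negative and unfootprinted.
    """
    pos = table.df["chip_positive"].to_numpy(bool)
    fp_covered = table.df["footprint_score"].notna().to_numpy()
    return ConfusionCounts(
        tp=int((pos & fp_covered).sum()),
        fp=int((~pos & fp_covered).sum()),
        fn=int((pos & ~fp_covered).sum()),
        tn=int((~pos & ~fp_covered).sum()),
    )


def rank_sites(
    table: MotifSiteTable, mode: str = "expected", seed: int | None = None
) -> list[list[int]]:
    """Rank sites for ROC construction; returns blocks of row positions.

    Footprinted sites come first in descending score order; unfootprinted
    sites follow below every footprinted site.  In ``expected`` mode each
    equal-score group — and the whole unfootprinted set — is one exchangeable
    tied block.  In ``permutation`` mode ties are broken by a seeded shuffle
    and every block is a singleton; a seed is required so the ordering is
    reproducible.
    """
    if mode not in ("expected", "permutation"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    if mode == "permutation" and seed is None:
        raise ValueError("permutation mode requires a seed")
    scores = table.df["footprint_score"].to_numpy(float)
    footprinted = np.flatnonzero(~np.isnan(scores))
    unfootprinted = np.flatnonzero(np.isnan(scores))
    blocks: list[list[int]] = []
    for s in sorted({scores[i] for i in footprinted}, reverse=True):
        blocks.append([int(i) for i in footprinted if scores[i] == s])
    if len(unfootprinted):
        blocks.append([int(i) for i in unfootprinted])
    if mode == "expected":
        return blocks
    rng = np.random.default_rng(seed)
    out: list[list[int]] = []
    for block in blocks:
        order = rng.permutation(len(block))
        out.extend([[block[j]] for j in order])
    return out


def _roc_from_blocks(
    blocks: list[list[int]], positive: np.ndarray
) -> tuple[float, np.ndarray]:
    """Tie-aware ROC curve and trapezoidal area from ranked tie blocks."""
    n_pos = int(positive.sum())
    n_neg = int(len(positive) - n_pos)
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for block in blocks:
        bp = sum(1 for i in block if positive[i])
        bn = len(block) - bp
        tp += bp
        fp += bn
        pts.append((fp / n_neg, tp / n_pos))
    curve = np.array(pts)
    area = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return area, curve


def roc_auc(
    table: MotifSiteTable, tf: str, mode: str = "expected", seed: int | None = None
) -> RocResult:
    """Per-TF ROC curve and AUC from the ranked site list.

    In ``expected`` mode the AUC equals the Mann–Whitney pair statistic with
    half-credit for tied pairs (the unfootprinted block is one tie group).
    Requires at least one positive and one negative site for the TF.
    """
    sub = table.for_tf(tf)
    if len(sub) == 0:
        raise UndefinedAUCError(f"no sites for TF {tf!r}")
    positive = sub["chip_positive"].to_numpy(bool)
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined for TF {tf!r}: n_pos={n_pos}, n_neg={n_neg}"
        )
    sub_table = MotifSiteTable(sub.reset_index(drop=True), provenance=dict(table.provenance))
    blocks = rank_sites(sub_table, mode=mode, seed=seed)
    if mode == "expected":
        # Mid-rank Mann–Whitney on scores (missing -> -inf sentinel block).
        scores = sub_table.df["footprint_score"].to_numpy(float)
        scores = np.where(np.isnan(scores), -np.inf, scores)
        ranks = rankdata(scores, method="average")
        auc = (ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        area, curve = _roc_from_blocks(blocks, positive)
        assert abs(area - auc) < 1e-9
    else:
        auc, curve = _roc_from_blocks(blocks, positive)
    return RocResult(
        tf=tf, auc=float(auc), curve=curve, n_pos=n_pos, n_neg=n_neg,
        ranking_mode=mode, seed=seed,
    )


def per_tf_roc(
    table: MotifSiteTable,
    mode: str = "expected",
    seed: int | None = None,
    skip_undefined: bool = False,
) -> dict[str, RocResult]:
    """ROC/AUC for every TF in the table.

    With ``skip_undefined`` TFs lacking both classes are silently dropped
    (useful on small simulated worlds); otherwise they raise.
    """
    results: dict[str, RocResult] = {}
    for tf in table.tfs:
        try:
            results[tf] = roc_auc(table, tf, mode=mode, seed=seed)
        except UndefinedAUCError:
            if not skip_undefined:
                raise
    return results


def mean_auc(results: dict[str, RocResult] | list[RocResult]) -> float:
    """Unweighted arithmetic mean of per-TF AUCs."""
    vals = [r.auc for r in (results.values() if isinstance(results, dict) else results)]
    if not vals:
        raise ValueError("mean_auc of empty result collection")
    return float(np.mean(vals))


def improvement_over_random(auc_test: float, auc_reference: float) -> float:
    """Percent improvement in AUC-above-random relative to a reference.

    Both AUCs are first expressed as excess over the chance level 0.5; the
    return value is ``100 * (excess_test - excess_ref) / excess_ref``.  This
    is one consistent reading of "improvement in mean AUC over random" and is
    recorded as such in output metadata.
    """
    if auc_reference <= 0.5:
        raise ValueError(
            f"reference AUC must exceed the chance level 0.5, got {auc_reference}"
        )
    return 100.0 * ((auc_test - 0.5) - (auc_reference - 0.5)) / (auc_reference - 0.5)


def auc_table(results: dict[str, RocResult]) -> pd.DataFrame:
    """Long-format per-TF AUC table (tf, auc, n_pos, n_neg, mode, seed)."""
    rows = [
        {
            "tf": r.tf, "auc": r.auc, "n_pos": r.n_pos, "n_neg": r.n_neg,
            "mode": r.ranking_mode, "seed": r.seed,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows)


def write_summary(
    results: dict[str, RocResult], path: str | Path, provenance: dict | None = None
) -> None:
    """JSON summary with mean AUC, per-TF AUCs and provenance metadata."""
    payload = {
        "mean_auc": mean_auc(results),
        "per_tf_auc": {tf: r.auc for tf, r in results.items()},
        "improvement_definition": "100*((auc-0.5)-(ref-0.5))/(ref-0.5)",
        "provenance": provenance or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
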