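"""Pipeline-configuration grid: expansion, evaluation, optimum selection.

A footprinting pipeline is described by eight arguments across five steps:
aligner scope and sensitivity, BAM processing (with or without PCR-duplicate
removal), peak-caller window size and minimum inter-peak distance, the
footprinting algorithm, and its algorithm-specific settings (bias-correction
mode for HINT; p-value cutoff and FDR for Wellington).  :func:`expand_grid`
takes lists of candidate values per argument and produces the conditional
Cartesian product — footprinter-specific arguments are crossed only within
their own footprinter.

:func:`evaluate_config` scores one configuration on a synthetic world.  Real
aligners and footprinters are deliberately not executed; instead an explicit
*effects map* states how each configuration axis perturbs the simulation
parameters (e.g. smaller peak windows raise replicate agreement but shrink
the score separation), and duplicate removal is applied structurally to the
simulated fragment lists.  The harness therefore measures pipelines; it does
not run them.  Externally produced BED/TSV outputs can be scored with the
metric modules directly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _stats

from . import chip
from .reproducibility import (
    alignment_reproducibility,
    bin_fragments,
    footprint_overlap_curve,
    ocr_mean_height_track,
    pearson,
)
from .simulate import (
    SimParams,
    deduplicate_fragments,
    simulate_ocr_heights,
    simulate_world,
)

__all__ = [
    "PipelineConfig",
    "GridResult",
    "expand_grid",
    "evaluate_config",
    "select_optimal",
    "summarize",
    "default_effects",
    "paper_inspired_grid",
    "load_grid",
]

COMMON_AXES = (
    "align_scope",
    "align_sensitivity",
    "bam_processor",
    "peak_size",
    "min_dist",
    "footprinter",
)
CONDITIONAL_AXES = {
    "hint": ("hint_bias_mode",),
    "wellington": ("wellington_p_cutoff", "wellington_fdr"),
}
ALL_AXES = COMMON_AXES + ("hint_bias_mode", "wellington_p_cutoff", "wellington_fdr")

_CHOICES = {
    "align_scope": ("global", "local"),
    "align_sensitivity": ("sensitive", "very-sensitive"),
    "bam_processor": ("plain", "dedup"),
    "footprinter": ("hint", "wellington"),
    "hint_bias_mode": ("none", "known-enzyme", "estimated"),
}

DEFAULT_VALUES = {
    "align_scope": "global",
    "align_sensitivity": "sensitive",
    "bam_processor": "plain",
    "peak_size": 200,
    "min_dist": 50,
    "footprinter": "hint",
    "hint_bias_mode": "none",
    "wellington_p_cutoff": 1e-2,
    "wellington_fdr": 0.01,
}


@dataclass(frozen=True)
class PipelineConfig:
    """The eight-argument pipeline configuration record.

    Exactly the arguments meaningful for the chosen footprinter are set:
    ``hint_bias_mode`` for HINT, ``wellington_p_cutoff``/``wellington_fdr``
    for Wellington; the others must be ``None``.
    """

    align_scope: str
    align_sensitivity: str
    bam_processor: str
    peak_size: int
    min_dist: int
    footprinter: str
    hint_bias_mode: str | None = None
    wellington_p_cutoff: float | None = None
    wellington_fdr: float | None = None

    def __post_init__(self) -> None:
        for axis, choices in _CHOICES.items():
            v = getattr(self, axis)
            if v is not None and v not in choices:
                raise ValueError(f"{axis} must be one of {choices}, got {v!r}")
        if self.peak_size <= 0:
            raise ValueError("peak_size must be > 0")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")
        if self.footprinter == "hint":
            if self.hint_bias_mode is None:
                raise ValueError("HINT configs require hint_bias_mode")
            if self.wellington_p_cutoff is not None or self.wellington_fdr is not None:
                raise ValueError("Wellington arguments set on a HINT config")
        else:
            if self.wellington_p_cutoff is None or self.wellington_fdr is None:
                raise ValueError("Wellington configs require p cutoff and FDR")
            if self.hint_bias_mode is not None:
                raise ValueError("HINT argument set on a Wellington config")

    def axes(self) -> dict[str, object]:
        """The set axes of this config (Nones dropped), by name."""
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }


@dataclass
class GridResult:
    """One configuration's evaluated metric row."""

    config: PipelineConfig
    alignment_r: float
    ocr_r: float
    footprint_overlap_at_1pct: float
    mean_auc: float
    per_tf_auc: dict[str, float]
    n_footprints: int
    provenance: dict = field(default_factory=dict)

    METRICS = ("alignment_r", "ocr_r", "footprint_overlap_at_1pct", "mean_auc",
               "n_footprints")

    def __post_init__(self) -> None:
        for name in ("alignment_r", "ocr_r"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if not 0.0 <= self.mean_auc <= 1.0:
            raise ValueError(f"mean_auc={self.mean_auc} outside [0, 1]")


def expand_grid(space: Mapping[str, Sequence]) -> list[PipelineConfig]:
    """Conditional Cartesian expansion of an argument grid.

    ``space`` maps argument names to candidate-value lists; missing arguments
    take their single default value.  Footprinter-specific arguments multiply
    only configurations of their own footprinter, so the total count is
    ``prod(common) * sum_over_footprinters(prod(its own arguments))``.
    Order is deterministic: common axes iterate in alphabetical name order
    (values in the given order), then each footprinter's conditional axes.
    """
    unknown = sorted(set(space) - set(ALL_AXES))
    if unknown:
        raise ValueError(f"unknown grid argument(s): {unknown}")
    for k, v in space.items():
        if len(v) == 0:
            raise ValueError(f"empty value list for argument {k!r}")
    full = {k: list(space.get(k, [DEFAULT_VALUES[k]])) for k in ALL_AXES}

    common_names = sorted(COMMON_AXES)
    configs: list[PipelineConfig] = []
    for combo in itertools.product(*(full[n] for n in common_names)):
        base = dict(zip(common_names, combo))
        cond_names = sorted(CONDITIONAL_AXES[base["footprinter"]])
        for cond in itertools.product(*(full[n] for n in cond_names)):
            configs.append(PipelineConfig(**base, **dict(zip(cond_names, cond))))
    return configs


def paper_inspired_grid() -> dict[str, list]:
    """A full benchmark grid over all eight arguments.

    The value lists span the ranges commonly swept in pipeline benchmarks
    (peak windows 10–2000 bp, minimum peak distances 0/50/500, both
    footprinters with their own settings).  They are representative, not a
    reconstruction of any specific published sweep.
    """
    return {
        "align_scope": ["global", "local"],
        "align_sensitivity": ["sensitive", "very-sensitive"],
        "bam_processor": ["plain", "dedup"],
        "peak_size": [10, 50, 100, 200, 500, 1000, 2000],
        "min_dist": [0, 50, 500],
        "footprinter": ["hint", "wellington"],
        "hint_bias_mode": ["none", "known-enzyme", "estimated"],
        "wellington_p_cutoff": [1e-2, 1e-3, 1e-4],
        "wellington_fdr": [0.01, 0.05],
    }


def load_grid(path: str | Path) -> dict[str, list]:
    """Read a grid specification from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


# ---------------------------------------------------------------------------
# Effects: how configuration axes perturb the simulated world
# ---------------------------------------------------------------------------

Effect = Callable[[SimParams, object], SimParams]


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def default_effects() -> dict[str, Effect]:
    """A paper-inspired effects map for synthetic grid evaluation.

    Encodes the qualitative directions a benchmark must reproduce: local and
    very-sensitive alignment retain more reads; small peak windows raise
    replicate agreement of OCR calls while shrinking the searchable region
    and hence the score separation; the minimum peak distance has no effect;
    Wellington is somewhat less sensitive than HINT; bias correction raises
    reproducibility at a small cost in score separation; stricter Wellington
    cutoffs trade sensitivity for specificity.  Duplicate removal is handled
    structurally (on the fragment lists), so its entry is the identity.
    """

    def align_scope(p: SimParams, v) -> SimParams:
        return replace(p, depth=int(p.depth * (1.05 if v == "local" else 1.0)))

    def align_sensitivity(p: SimParams, v) -> SimParams:
        return replace(p, depth=int(p.depth * (1.1 if v == "very-sensitive" else 1.0)))

    def bam_processor(p: SimParams, v) -> SimParams:
        return p  # applied structurally to fragment lists

    def peak_size(p: SimParams, v) -> SimParams:
        frac = min(1.0, float(v) / 200.0)  # windows below ~200 bp fragment OCRs
        share = p.replicate_share + (1.0 - p.replicate_share) * 0.6 * (1.0 - frac)
        return replace(
            p,
            replicate_share=_clip01(share),
            score_separation=p.score_separation * (0.4 + 0.6 * frac),
        )

    def min_dist(p: SimParams, v) -> SimParams:
        return p  # no measurable effect on any metric

    def footprinter(p: SimParams, v) -> SimParams:
        if v == "wellington":
            return replace(p, footprint_sensitivity=_clip01(p.footprint_sensitivity * 0.9))
        return p

    def hint_bias_mode(p: SimParams, v) -> SimParams:
        if v == "known-enzyme":
            return replace(
                p,
                replicate_share=_clip01(p.replicate_share + 0.05),
                score_separation=p.score_separation * 0.95,
            )
        return p

    def wellington_p_cutoff(p: SimParams, v) -> SimParams:
        strict = min(1.0, float(v) / 1e-2)  # smaller cutoff = stricter calls
        return replace(
            p,
            footprint_sensitivity=_clip01(p.footprint_sensitivity * (0.8 + 0.2 * strict)),
            footprint_fpr=_clip01(p.footprint_fpr * strict),
        )

    def wellington_fdr(p: SimParams, v) -> SimParams:
        return replace(p, footprint_fpr=_clip01(p.footprint_fpr * min(1.0, float(v) / 0.05)))

    return {
        "align_scope": align_scope,
        "align_sensitivity": align_sensitivity,
        "bam_processor": bam_processor,
        "peak_size": peak_size,
        "min_dist": min_dist,
        "footprinter": footprinter,
        "hint_bias_mode": hint_bias_mode,
        "wellington_p_cutoff": wellington_p_cutoff,
        "wellington_fdr": wellington_fdr,
    }


def evaluate_config(
    config: PipelineConfig,
    base_params: SimParams,
    effects: Mapping[str, Effect] | None = None,
    seed: int | None = None,
) -> GridResult:
    """Score one pipeline configuration on a synthetic world.

    The effects map must define an entry for every axis set on the config
    (missing axes raise).  Axes are applied to the base simulation
    parameters in sorted name order, the world is simulated, and all four
    benchmark metrics are computed: alignment correlation of binned fragment
    counts (after duplicate removal when the config says so), OCR
    mean-height correlation, the replicate footprint-overlap proportion at
    the 1% threshold, and expected-mode mean AUC.  Pure function of
    (config, base_params, effects, seed).
    """
    if effects is None:
        effects = default_effects()
    axes = config.axes()
    missing = sorted(set(axes) - set(effects))
    if missing:
        raise KeyError(f"effects map missing entries for axes: {missing}")
    params = base_params if seed is None else replace(base_params, seed=seed)
    for name in sorted(axes):
        params = effects[name](params, axes[name])

    world = simulate_world(params)
    frags1 = world.fragments_rep1.fragments
    frags2 = world.fragments_rep2.fragments
    if config.bam_processor == "dedup":
        frags1 = deduplicate_fragments(frags1)
        frags2 = deduplicate_fragments(frags2)
    t1 = bin_fragments(frags1, world.binning)
    t2 = bin_fragments(frags2, world.binning)
    alignment_r = alignment_reproducibility(t1, t2)

    ocr1, ocr2 = simulate_ocr_heights(world, params.replicate_share, params.seed)
    h1 = ocr_mean_height_track(ocr1, world.binning)
    h2 = ocr_mean_height_track(ocr2, world.binning)
    ocr_r = pearson(h1.values, h2.values)

    if len(world.footprints_rep1) and len(world.footprints_rep2):
        curve = footprint_overlap_curve(
            world.footprints_rep1, world.footprints_rep2, thresholds=[0.01]
        )
        overlap_1pct = curve.at(0.01)
    else:
        overlap_1pct = 0.0

    table = chip.assign_footprint_scores(world.sites, world.footprints_rep1)
    rocs = chip.per_tf_roc(table, mode="expected", skip_undefined=True)
    return GridResult(
        config=config,
        alignment_r=alignment_r,
        ocr_r=ocr_r,
        footprint_overlap_at_1pct=overlap_1pct,
        mean_auc=chip.mean_auc(rocs),
        per_tf_auc={tf: r.auc for tf, r in rocs.items()},
        n_footprints=len(world.footprints_rep1),
        provenance={"seed": params.seed, "sim_params": params.__dict__.copy()},
    )


def select_optimal(results: Sequence[GridResult], objective: str) -> GridResult:
    """Pick the best configuration under an objective.

    ``objective='mean_auc'`` maximises ChIP-recovery mean AUC;
    ``objective='reproducibility'`` maximises the mean of the alignment and
    OCR correlations (a documented composite — no single published formula
    exists).  Ties break toward the earlier result, so the selection is
    deterministic given the input order.
    """
    if not results:
        raise ValueError("select_optimal of empty result list")
    if objective == "mean_auc":
        key = lambda r: r.mean_auc
    elif objective == "reproducibility":
        key = lambda r: (r.alignment_r + r.ocr_r) / 2.0
    else:
        raise ValueError(f"unknown objective {objective!r}")
    best = results[0]
    for r in results[1:]:
        if key(r) > key(best):
            best = r
    return best


def summarize(
    results: Sequence[GridResult], group_by: str | None = None
) -> pd.DataFrame:
    """Long-format metric table, optionally aggregated by one argument.

    Without ``group_by``: one row per (config index, metric, value).  With
    ``group_by``: per-level mean and 95% t-interval for each metric; the CI
    of a single-member group is undefined and emitted as missing.
    """
    if not results:
        raise ValueError("summarize of empty result list")
    rows = []
    for i, r in enumerate(results):
        for metric in GridResult.METRICS:
            rows.append(
                {
                    "config_index": i,
                    **{a: getattr(r.config, a) for a in ALL_AXES},
                    "metric": metric,
                    "value": float(getattr(r, metric)),
                }
            )
    long = pd.DataFrame(rows)
    if group_by is None:
        return long
    if group_by not in ALL_AXES:
        raise ValueError(f"unknown grouping argument {group_by!r}")
    out = []
    for (level, metric), grp in long.groupby([group_by, "metric"], dropna=False):
        vals = grp["value"].to_numpy()
        mean = float(vals.mean())
        if len(vals) > 1 and np.std(vals, ddof=1) > 0:
            lo, hi = _stats.t.interval(
                0.95, len(vals) - 1, loc=mean,
                scale=np.std(vals, ddof=1) / np.sqrt(len(vals)),
            )
        else:
            lo = hi = np.nan
        out.append(
            {
                group_by: level, "metric": metric, "mean": mean,
                "ci_low": float(lo), "ci_high": float(hi), "n": len(vals),
            }
        )
    return pd.DataFrame(out)


def results_to_tsv(results: Sequence[GridResult], path: str | Path) -> None:
    rows = []
    for r in results:
        row = {a: getattr(r.config, a) for a in ALL_AXES}
        for metric in GridResult.METRICS:
            row[metric] = getattr(r, metric)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
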