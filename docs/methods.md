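# Methods

This note documents the models behind `footprint-bench`: what each metric
computes, what the synthetic-data generator emulates (and does not), the
numerical conventions, and the design choices made where more than one
reasonable definition exists.

## Coordinate and overlap conventions

All intervals are 0-based half-open `[start, end)` (the BED convention used
by the interchange formats of the tools whose outputs this package scores:
BEDtools, BEDops, HOMER `pos2BED`).  Abutting intervals do not overlap.
Strand is carried through I/O but ignored by every overlap operation —
footprint/ChIP intersections are strand-agnostic.  Sorting breaks ties by
`(chrom, start, end, label)` so every operation is deterministic.

`merge(set, min_dist)` fuses consecutive intervals whose gap is **at most**
`min_dist` (inclusive rule).  The inclusive choice mirrors the reading of a
peak-caller's "minimum distance allowed between two peaks"; strict vs
non-strict is not universally defined, so the rule is fixed here and tested.

`overlap_fraction(a, b)` is asymmetric: overlap divided by `len(a)`.  The
replicate footprint-overlap metric asks "what fraction of *this* footprint
does its best replicate partner cover", so the query footprint is the
denominator.  A symmetric mode (overlap over the longer interval) exists
behind a flag.

## Reproducibility metrics

* **Alignment reproducibility**: fragments are counted per fixed genome bin
  (default 10 kb; last bin of a chromosome may be shorter) and the two
  replicate vectors are correlated with Pearson's r on the **raw** counts.
  No log transform is applied by default (a `log1p` flag exists).  All bins
  are included by default; a boolean `bin_filter` allows excluding, e.g.,
  zero bins.  Fragments are assigned to bins by start coordinate (midpoint
  mode behind a flag); tie handling at bin boundaries follows half-open
  semantics, so a fragment starting exactly at a boundary belongs to the
  right-hand bin.
* **OCR reproducibility**: each scored OCR spreads `height × bp-overlap`
  over the bins it touches; a bin's value is that mass divided by the bin
  length, i.e. a per-base mean in which bases outside any OCR count as
  height 0.  This conserves mass (Σ value·bin-length = Σ height·OCR-length)
  and is the default because the alternative — averaging over covered bases
  only — inflates sparsely covered bins; the alternative is available as
  `covered_only=True`.
* **Footprint overlap curve**: for thresholds t (default 1%–100% in 1%
  steps) the proportion of replicate-1 footprints whose best replicate-2
  partner covers ≥ t of their length.  The curve is non-increasing by
  construction and the proportion is undefined (an error) for an empty
  query set.
* A constant input vector makes Pearson's r undefined; the package raises
  rather than returning NaN so degenerate simulations fail loudly.

## ChIP recovery

Motif sites carry a TF identity; a site is ChIP-positive iff it overlaps
(≥ 1 bp) a ChIP peak **of its own TF**.  Peaks of other TFs never confer
positivity, and a TF with no peak set at all is an error distinct from a TF
with an empty (all-negative) peak set.

Footprint scores attach to sites by the **maximum** score over overlapping
footprints (the usual detector-confidence convention; `mean` behind a
flag).  Sites are ranked footprinted-first by descending score; sites no
footprint overlaps rank below every scored site.

Two ranking modes:

* **expected** (default): every equal-score group and the whole
  unfootprinted set are exchangeable tied blocks with mid-rank semantics.
  The AUC is then exactly the Mann–Whitney pair statistic with half-credit
  for ties, equals the trapezoidal area under the tie-aware ROC curve
  (tied blocks appear as diagonal segments), and equals the expectation of
  the AUC over all random orderings of the tied sites.  It is the default
  because randomly ordering unfootprinted sites makes reported AUCs
  stochastic; the expected value is reproducible.
* **permutation**: one concrete seeded shuffle of each tied block,
  reproducing the randomized ranked-list procedure literally.

`improvement_over_random(test, ref) = 100·((test−0.5)−(ref−0.5))/(ref−0.5)`
expresses an AUC gain relative to a reference's excess over the chance
level 0.5.  Several readings of "percent improvement over random" exist;
this definition is recorded in output metadata wherever it is reported.

Negatives are evaluated genome-wide as provided (no restriction to
accessible chromatin); a region-restriction option can be composed from the
interval operations when wanted.

## Synthetic worlds

`simulate_world(SimParams)` builds, deterministically from one integer
seed, a miniature genome with the statistical structure the metrics need.
Independent sub-streams are derived from the seed by fixed per-operation
offsets, so adding an operation never perturbs the others.

Geometry: OCRs are placed in equal per-chromosome slots with 150 bp
clearance on each side; motif sites (12 bp) sit in equal per-OCR slots with
6 bp clearance; TFs are assigned to sites cyclically within each OCR.  The
slotting has one purpose: with the default ±100 bp ChIP-peak padding, a
peak built from a bound site can never reach a neighbouring site of the
same TF, so *ChIP-positive ≡ truly bound* holds exactly and the confusion
matrix of the detector can be predicted in closed form.  Infeasible
packings raise `SimParamError` rather than silently bending the geometry.

Model components:

* **Binding truth**: each site is bound independently with probability
  `bound_fraction` (default 1/11, matching the ~10:1 negative:positive
  imbalance of genome-wide motif scans against ChIP truth).
* **ChIP peaks**: bound sites padded ±`chip_pad` (default 100 bp,
  configurable) and merged per TF.  Real benchmarks use experimental peak
  sets; this construction is the synthetic stand-in.
* **Footprints**: per replicate, a bound site is detected with probability
  `footprint_sensitivity` (default 0.6) and an unbound site with
  `footprint_fpr` (default 0.02) — footprint detectors are conservative,
  favouring specificity over sensitivity.  Scores are
  `Normal(3 + score_separation·bound, 1)` clipped at 0 (separation default
  2.0), so for fully footprinted site sets the theoretical AUC is
  Φ(separation/√2), a closed form the tests exploit.  Footprints extend
  0–5 bp beyond their site and always lie inside an OCR.
* **Bin counts**: per-bin intensity `share·shared + (1−share)·private`,
  with shared/private drawn from Gamma(shape 0.2) scaled 5× on
  OCR-containing bins (heavy-tailed accessibility, moderate OCR
  enrichment); counts are Poisson at the requested depth.  Correlation
  between replicate tracks rises monotonically with `replicate_share`
  (default 0.8); at share 0 the residual correlation from the shared
  OCR/background mean structure is small (≈0.05) by the choice of a small
  gamma shape.
* **Fragments and PCR duplicates**: unique parent fragments (80–200 bp)
  start inside a random OCR with probability 0.9 and uniformly otherwise;
  each parent's copy number is Geometric(`dup_geom_p`) — a single-parameter
  model of "PCR jackpotting" with a heavy-ish tail — truncated so the total
  equals `depth` exactly.  `dup_geom_p` defaults to 0.8 (≈20% duplicates); a
  duplicate-heavy library uses 0.3 (≈70%).  Duplicates are exact coordinate
  copies; `deduplicate_fragments` keeps the first occurrence per distinct
  `(chrom, start, end, strand)`.
* **Per-replicate OCR heights**: `share·true + (1−share)·private` with
  private noise from the same gamma family as the true heights, giving the
  OCR-reproducibility metric a tunable agreement axis.

Defaults describe a desk-scale study: two 1 Mb chromosomes, 100 OCRs of
~500 bp, 500 sites over 5 TFs, 50,000 fragments per replicate.  These sizes
are the package's chosen study conditions; they keep a full benchmark run
in seconds while leaving every statistical contract testable.

What the generator does **not** model — and therefore what passing tests do
not show about real data: no sequences, read qualities or aligner
behaviour; no enzyme cut-bias (Tn5 insertion or DNase cleavage preference),
so bias-correction effects on real data are out of reach; binding truth is
independent across sites (no co-binding or motif clustering beyond OCR
structure); ChIP peaks are derived from the truth rather than measured with
their own noise; and footprint detection errors are independent across
sites and replicates.

## Depth saturation

`downsample` samples uniformly without replacement; when no seed is given
the seed defaults to the target count itself (a convention that makes
repeated runs at one depth identical but couples seed to depth — noted in
the docstring).  No nesting consistency across depths is claimed: each
depth is an independent sample.

`fit_linear` regresses **all replicate points** on depth in millions of
reads (per-sampling scatter is informative for yield curves);
`fit_power` averages replicates per depth first and fits
`log(value) = log(a) + b·log(depth)` by OLS — deterministic and
closed-form, exactly recovering noiseless power laws; a nonlinear
refinement was considered and left out since the log–log fit is the
reproducible baseline.  The linear fit includes an intercept.
`predict_reads_for_auc` inverts the power curve, `(target/a)^(1/b)`, and
flags predictions beyond the maximum fitted depth as extrapolations;
exponents ≤ 1e-9 (flat curves) are rejected as never crossing the target.

`saturation_fraction` reports the ratio of depth means; the "within X% of
the reference depth" phrasing is ambiguous between raw AUC and AUC above
random, so both bases are implemented (`raw` default, `above_random`
optional) and the choice is the caller's to record.

`simulate_depth_series` ties the simulator to the fits: detection
sensitivity and score separation scale with `1 − exp(−depth/d0)`, giving a
near-linear footprint-yield regime at depths well below `d0` and a concave,
saturating mean-AUC curve — the qualitative shape that motivates the power
fit.  The packaged analyses run depth grids of 20k–200k fragments (the same
10× span as a 20M–200M read sweep) with three samplings per depth; these
scaled sizes are the package's chosen study conditions.

## Grid benchmarking

`PipelineConfig` validates the conditional argument structure: exactly the
arguments meaningful for the chosen footprinter may be set.
`expand_grid` forms the conditional Cartesian product — footprinter-specific
arguments multiply only their own footprinter's configurations — in a
deterministic order (alphabetical axis order, values as given).  The bundled
`paper_inspired_grid()` covers the commonly swept ranges (peak windows
10–2000 bp, minimum peak distances 0/50/500, both footprinters with their
sub-arguments) without claiming to reproduce any specific published sweep's
exact factorization.

`evaluate_config` deliberately does not execute aligners or footprinters.
An explicit *effects map* (axis name → function on `SimParams`) states how
each configuration axis perturbs the simulated world; the default map
encodes directional expectations only: duplicate removal is applied
structurally to the fragment lists; small peak windows raise replicate
agreement while shrinking score separation; the minimum peak distance does
nothing; Wellington is slightly less sensitive than HINT; bias correction
trades a little separation for agreement; stricter Wellington cutoffs lower
both sensitivity and false positives.  Users benchmarking real pipelines
feed externally produced BED/TSV files to the metric modules instead.

`select_optimal` maximizes either mean AUC or a composite reproducibility
objective defined as the mean of the alignment and OCR correlations (no
single published formula exists for "reproducibility-optimized"; the
composite is the documented choice).  Ties break toward the earlier
configuration for determinism.

## Numerical notes and limitations

* The ROC curve of the expected mode is validated internally: the
  trapezoidal area must match the rank statistic to 1e-9 or construction
  fails.
* Merged intervals keep a label only when all members agree; merged scores
  are dropped (a merged peak height has no single defensible definition).
* `fit_linear` on an exactly constant series returns slope 0 with R² = 1
  (the flat line is an exact fit; the regression formula would be 0/0).
* The overlap-curve denominator counts footprints, not base pairs; two
  identical query footprints count twice.
* Known limitation: the simulator has no enzyme-bias axis, so
  bias-correction effects can only be *postulated* through the effects map,
  not emulated; and at very small worlds (few TFs × few sites) some TFs may
  lack a class, which `per_tf_roc(skip_undefined=True)` drops explicitly.
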