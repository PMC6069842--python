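"""ChIP-recovery labelling, ranking and tie-aware ROC/AUC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from footprint_bench import SimParams, simulate_world
from footprint_bench.chip import (
    MissingChipPeaksError,
    MotifSiteTable,
    UndefinedAUCError,
    assign_footprint_scores,
    confusion_counts,
    improvement_over_random,
    label_sites,
    mean_auc,
    per_tf_roc,
    rank_sites,
    roc_auc,
)
from footprint_bench.intervals import GenomicInterval, IntervalSet


def make_table(rows):
    """rows: list of (tf, chip_positive, footprint_score-or-None)."""
    recs = []
    for i, (tf, pos, score) in enumerate(rows):
        recs.append(
            {
                "chrom": "chr1", "start": 100 * i, "end": 100 * i + 10,
                "tf": tf, "chip_positive": pos,
                "footprint_score": np.nan if score is None else float(score),
            }
        )
    return MotifSiteTable(pd.DataFrame(recs))


def auc_pair_oracle(positive, scores):
    """Brute-force Mann–Whitney AUC: all (pos, neg) pairs, ties get 1/2."""
    s = [(-math.inf if v is None or (isinstance(v, float) and math.isnan(v)) else v)
         for v in scores]
    num = n = 0.0
    for i, pi in enumerate(positive):
        if not pi:
            continue
        for j, pj in enumerate(positive):
            if pj:
                continue
            n += 1
            if s[i] > s[j]:
                num += 1
            elif s[i] == s[j]:
                num += 0.5
    return num / n


class TestLabelSites:
    def test_same_tf_overlap_is_positive(self):
        sites = IntervalSet([GenomicInterval("chr1", 100, 110, label="CTCF")])
        peaks = {"CTCF": IntervalSet([GenomicInterval("chr1", 105, 400)])}
        assert label_sites(sites, peaks).df.chip_positive.tolist() == [True]

    def test_cross_tf_peak_never_confers_positivity(self):
        sites = IntervalSet([GenomicInterval("chr1", 100, 110, label="STAT1")])
        peaks = {
            "STAT1": IntervalSet([]),
            "CTCF": IntervalSet([GenomicInterval("chr1", 105, 400)]),
        }
        assert label_sites(sites, peaks).df.chip_positive.tolist() == [False]

    def test_missing_tf_raises_but_empty_peak_set_allowed(self):
        sites = IntervalSet(
            [
                GenomicInterval("chr1", 0, 10, label="NRF1"),
                GenomicInterval("chr1", 50, 60, label="USF2"),
            ]
        )
        with pytest.raises(MissingChipPeaksError, match="NRF1"):
            label_sites(sites, {"USF2": IntervalSet([])})
        table = label_sites(sites, {"USF2": IntervalSet([]), "NRF1": IntervalSet([])})
        assert not table.df.chip_positive.any()

    def test_simulated_world_labels_equal_truth(self, default_world):
        df = default_world.sites.df
        assert (df.chip_positive == df.bound).all()


class TestAssignScores:
    def test_max_rule_and_absences(self):
        table = make_table([("TF0", True, None)])
        fps = IntervalSet(
            [
                GenomicInterval("chr1", 0, 5, score=4.0),
                GenomicInterval("chr1", 5, 10, score=7.0),
                GenomicInterval("chr1", 10, 20, score=99.0),  # abuts site [0,10)
            ]
        )
        out = assign_footprint_scores(table, fps)
        assert out.df.footprint_score.tolist() == [7.0]
        # site with no overlapping footprint stays unscored
        table2 = make_table([("TF0", True, None), ("TF0", False, None)])
        out2 = assign_footprint_scores(table2, IntervalSet([GenomicInterval("chr1", 0, 5, score=1.0)]))
        assert out2.df.footprint_score.isna().tolist() == [False, True]

    def test_mean_rule_and_unscored_footprint_error(self):
        table = make_table([("TF0", True, None)])
        fps = IntervalSet(
            [GenomicInterval("chr1", 0, 5, score=4.0), GenomicInterval("chr1", 5, 10, score=8.0)]
        )
        assert assign_footprint_scores(table, fps, combine="mean").df.footprint_score.tolist() == [6.0]
        with pytest.raises(ValueError, match="unscored"):
            assign_footprint_scores(table, IntervalSet([GenomicInterval("chr1", 0, 5)]))


class TestConfusion:
    def test_one_site_per_cell(self):
        table = make_table(
            [("A", True, 1.0), ("A", False, 1.0), ("A", True, None), ("A", False, None)]
        )
        assert confusion_counts(table) == (1, 1, 1, 1)

    def test_all_footprinted_positives(self):
        table = make_table([("A", True, 2.0)] * 5)
        assert confusion_counts(table) == (5, 0, 0, 0)

    def test_counts_sum_to_rows(self, default_world):
        table = assign_footprint_scores(default_world.sites, default_world.footprints_rep1)
        assert sum(confusion_counts(table)) == len(table)


class TestRankSites:
    def test_ordering_contract(self):
        table = make_table([("A", True, 5.0), ("A", False, 3.0), ("A", True, None), ("A", False, None)])
        blocks = rank_sites(table, mode="expected")
        assert blocks == [[0], [1], [2, 3]]

    def test_permutation_mode_deterministic_and_requires_seed(self):
        table = make_table([("A", True, None)] * 6)
        assert rank_sites(table, "permutation", seed=9) == rank_sites(table, "permutation", seed=9)
        with pytest.raises(ValueError, match="seed"):
            rank_sites(table, "permutation")


class TestRocAuc:
    def test_worked_four_site_example(self):
        table = make_table([("A", True, 5.0), ("A", False, 3.0), ("A", True, None), ("A", False, None)])
        res = roc_auc(table, "A")
        assert res.auc == pytest.approx(0.625, abs=1e-12)
        assert res.curve[0].tolist() == [0.0, 0.0] and res.curve[-1].tolist() == [1.0, 1.0]

    def test_perfect_separation_and_random_limits(self):
        table = make_table([("A", True, 2.0), ("A", True, 1.0), ("A", False, None), ("A", False, None)])
        assert roc_auc(table, "A").auc == 1.0
        none = make_table([("A", True, None), ("A", False, None), ("A", False, None)])
        assert roc_auc(none, "A").auc == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError, match="A"):
            roc_auc(make_table([("A", True, 1.0)]), "A")

    def test_matches_pair_oracle_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(5, 200))
            positive = rng.random(n) < 0.3
            if positive.all() or not positive.any():
                continue
            scores = [
                None if rng.random() < 0.4 else float(rng.integers(0, 6))
                for _ in range(n)
            ]
            table = make_table([("A", bool(p), s) for p, s in zip(positive, scores)])
            expected = auc_pair_oracle(positive, scores)
            assert roc_auc(table, "A").auc == pytest.approx(expected, abs=1e-12)

    def test_expected_mode_equals_mean_over_all_orderings(self):
        """Exhaustive enumeration at <=6 sites: the mid-rank AUC equals the
        average of step-curve AUCs over every ordering of unfootprinted sites."""
        rows = [("A", True, 5.0), ("A", False, 3.0), ("A", True, None),
                ("A", False, None), ("A", True, None), ("A", False, None)]
        table = make_table(rows)
        positive = [r[1] for r in rows]
        footprinted = [i for i, r in enumerate(rows) if r[2] is not None]
        unfootprinted = [i for i, r in enumerate(rows) if r[2] is None]
        footprinted.sort(key=lambda i: -rows[i][2])
        aucs = []
        for perm in itertools.permutations(unfootprinted):
            order = footprinted + list(perm)
            # strictly ranked list: pseudo-score = -position
            s = {idx: -pos for pos, idx in enumerate(order)}
            aucs.append(auc_pair_oracle(positive, [s[i] for i in range(len(rows))]))
        assert roc_auc(table, "A").auc == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        scores = [None if rng.random() < 0.3 else float(rng.normal()) for _ in range(60)]
        positive = rng.random(60) < 0.4
        t1 = make_table([("A", bool(p), s) for p, s in zip(positive, scores)])
        t2 = make_table(
            [("A", bool(p), None if s is None else math.exp(3 * s) + 7)
             for p, s in zip(positive, scores)]
        )
        assert roc_auc(t1, "A").auc == pytest.approx(roc_auc(t2, "A").auc, abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self):
        rng = np.random.default_rng(4)
        scores = [None if rng.random() < 0.3 else float(rng.integers(0, 4)) for _ in range(80)]
        positive = rng.random(80) < 0.4
        t = make_table([("A", bool(p), s) for p, s in zip(positive, scores)])
        t_swap = make_table([("A", not bool(p), s) for p, s in zip(positive, scores)])
        assert roc_auc(t, "A").auc == pytest.approx(1 - roc_auc(t_swap, "A").auc, abs=1e-12)

    def test_score_model_auc_tracks_gaussian_closed_form(self):
        """With every site footprinted, the expected AUC of the clipped-normal
        score model is Phi(separation/sqrt(2)) for separation well above the
        clipping region."""
        from scipy.stats import norm

        sep = 2.0
        params = SimParams(
            n_chroms=2, chrom_len=2_000_000, n_ocrs=2000, sites_per_ocr=5,
            footprint_sensitivity=1.0, footprint_fpr=1.0,
            score_separation=sep, depth=1000, seed=8,
        )
        world = simulate_world(params)
        table = assign_footprint_scores(world.sites, world.footprints_rep1)
        aucs = [r.auc for r in per_tf_roc(table, skip_undefined=True).values()]
        pooled = roc_auc(
            MotifSiteTable(table.df.assign(tf="ALL")), "ALL"
        ).auc
        assert pooled == pytest.approx(norm.cdf(sep / np.sqrt(2)), abs=0.02)
        assert all(0.8 < a < 1.0 for a in aucs)


class TestSummaries:
    def test_mean_auc(self):
        r1 = roc_auc(make_table([("A", True, 2.0), ("A", False, None)]), "A")
        assert mean_auc([r1]) == r1.auc
        assert mean_auc({"a": r1, "b": r1}) == r1.auc
        with pytest.raises(ValueError):
            mean_auc([])

    def test_improvement_over_random(self):
        assert improvement_over_random(0.7, 0.6) == pytest.approx(100.0)
        assert improvement_over_random(0.6, 0.6) == 0.0
        with pytest.raises(ValueError):
            improvement_over_random(0.7, 0.5)
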