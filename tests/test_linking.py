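import numpy as np
import pandas as pd
import pytest

import lipidwgs as lw
from lipidwgs.linking import (CorrelationLinker, LinkingConfig, abc_activity,
                              abc_candidate_elements, abc_links, abc_score,
                              mark_expression_correlations, train_link_classifier)


class TestCorrelationFeatures:
    def test_proportional_signal_gives_unit_correlation(self):
        expr = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        signal = np.tile((2.0 * expr[0] + 1.0)[None, :, None], (1, 1, 5))
        feats = mark_expression_correlations(signal, expr, 0, 0)
        assert np.allclose(feats, 1.0)

    def test_constant_signal_yields_missing_feature(self):
        expr = np.array([[1.0, 2.0, 3.0, 4.0]])
        signal = np.full((1, 4, 5), 3.0)
        feats = mark_expression_correlations(signal, expr, 0, 0)
        assert np.isnan(feats).all()

    def test_too_few_complete_pairs_yields_missing(self):
        expr = np.array([[1.0, 2.0, np.nan, np.nan]])
        signal = np.random.default_rng(0).normal(size=(1, 4, 5))
        feats = mark_expression_correlations(signal, expr, 0, 0)
        assert np.isnan(feats).all()

    def test_estimate_within_fisher_z_band_at_56_cell_types(self):
        rng = np.random.default_rng(5)
        rho = 0.8
        e = rng.normal(size=56)
        s = rho * (e - e.mean()) / e.std() + np.sqrt(1 - rho ** 2) * rng.normal(size=(5, 56))
        feats = mark_expression_correlations(np.transpose(s)[None, :, :], e[None, :], 0, 0)
        assert np.all(np.abs(feats - rho) < 0.15)


class TestTrainingAndScoring:
    def test_one_positive_and_one_negative_per_instance(self, small_landscape):
        _, ls = small_landscape
        linker = CorrelationLinker(ls)
        pairs = linker.candidate_pairs(0, states=("7_Enh",))
        offset = int(pairs["offset"].iloc[0])
        pos, neg = linker.build_training_set(0, "7_Enh", offset)
        k = (np.abs(pairs["offset"] - offset) <= linker.config.smoothing_bp).sum()
        assert len(pos) == len(neg) == k

    def test_negatives_reproducible_under_fixed_seed(self, small_landscape):
        _, ls = small_landscape
        a = CorrelationLinker(ls, LinkingConfig(seed=3))
        b = CorrelationLinker(ls, LinkingConfig(seed=3))
        pa = a.build_training_set(0, "7_Enh", 0)[1]
        pb = b.build_training_set(0, "7_Enh", 0)[1]
        assert np.array_equal(pa, pb)

    def test_separable_classes_reach_perfect_training_accuracy(self):
        pos = np.ones((20, 5))
        neg = np.zeros((20, 5))
        model = train_link_classifier(pos, neg)
        X = np.vstack([pos, neg])
        y = np.r_[np.ones(20), np.zeros(20)]
        assert model.score(X, y) == 1.0

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        X = rng.normal(size=(500, 5))
        y = rng.binomial(1, 0.5, 500)
        model = train_link_classifier(X[y == 1], X[y == 0])
        Xh = rng.normal(size=(500, 5))
        yh = rng.binomial(1, 0.5, 500)
        acc = model.score(Xh, yh)
        assert abs(acc - 0.5) < 0.1

    def test_odds_threshold_boundary(self):
        """Retention flips exactly at posterior p = 5/7 (odds 2.5)."""
        cfg = LinkingConfig()
        p_at = 5.0 / 7.0
        assert p_at / (1 - p_at) >= cfg.odds_threshold
        p_below = 0.70
        assert p_below / (1 - p_below) < cfg.odds_threshold  # odds 2.33 rejected

    def test_planted_links_recovered_with_high_precision_and_recall(self, small_landscape):
        _, ls = small_landscape
        links = CorrelationLinker(ls).score_links(0)
        bin_of = {int(s): b for b, s in enumerate(ls.bin_starts)}
        truth = set(zip(ls.true_links["bin_index"], ls.true_links["gene"]))
        pred = {(bin_of[l.start], l.gene) for l in links}
        tp = len(pred & truth)
        assert tp / len(pred) >= 0.8
        assert tp / len(truth) >= 0.8

    def test_exported_links_are_primary_enhancer_state_only(self, small_landscape):
        _, ls = small_landscape
        linker = CorrelationLinker(ls)
        bin_of = {int(s): b for b, s in enumerate(ls.bin_starts)}
        for l in linker.score_links(0):
            assert ls.states[bin_of[l.start], 0] == "7_Enh"


class TestAbc:
    def test_expand_and_merge_interval_arithmetic(self):
        peaks = pd.DataFrame({"chrom": "1", "start": [1000, 1900], "end": [1200, 2000]})
        out = abc_candidate_elements(peaks)
        assert out[["start", "end"]].values.tolist() == [[500, 2500]]

    def test_single_isolated_peak(self):
        peaks = pd.DataFrame({"chrom": "1", "start": [10_000], "end": [10_100]})
        out = abc_candidate_elements(peaks)
        assert out[["start", "end"]].values.tolist() == [[9500, 10_600]]

    def test_abutting_extended_intervals_merge(self):
        peaks = pd.DataFrame({"chrom": "1", "start": [0, 1100], "end": [100, 1200]})
        out = abc_candidate_elements(peaks)
        assert len(out) == 1

    def test_normalization_of_two_elements(self):
        elements = pd.DataFrame({"chrom": "1", "start": [0, 1000], "end": [100, 1100],
                                 "activity": [3.0, 1.0]})
        scores = abc_score(elements, tss=500, contact=lambda d: np.ones_like(d))
        assert scores.tolist() == pytest.approx([0.75, 0.25])

    def test_scores_sum_to_one_and_scale_invariant(self, rng):
        elements = pd.DataFrame({
            "chrom": "1",
            "start": np.arange(10) * 10_000,
            "end": np.arange(10) * 10_000 + 500,
            "dnase": rng.uniform(0, 50, 10),
            "h3k27ac": rng.uniform(0, 50, 10),
        })
        contact = lambda d: (np.abs(d) + 1.0) ** -1.0
        s1 = abc_score(elements, tss=40_000, contact=contact)
        assert s1.sum() == pytest.approx(1.0)
        doubled = elements.assign(activity=2 * abc_activity(elements["dnase"], elements["h3k27ac"]))
        s2 = abc_score(doubled, tss=40_000, contact=contact)
        assert np.allclose(s1, s2)
        s3 = abc_score(elements, tss=40_000, contact=lambda d: 7.0 * contact(d))
        assert np.allclose(s1, s3)

    def test_elements_beyond_radius_score_zero(self):
        elements = pd.DataFrame({"chrom": "1", "start": [0, 10_000_000],
                                 "end": [100, 10_000_100], "activity": [1.0, 1.0]})
        scores = abc_score(elements, tss=0, contact=lambda d: np.ones_like(d))
        assert scores.tolist() == pytest.approx([1.0, 0.0])

    def test_geometric_mean_activity(self):
        assert abc_activity(np.array([3.0]), np.array([7.0]))[0] == pytest.approx(np.sqrt(32.0))

    def test_cutoff_zero_returns_all_pairs(self):
        elements = pd.DataFrame({"chrom": "1", "start": [0, 2000], "end": [100, 2100],
                                 "activity": [1.0, 1.0]})
        genes = pd.DataFrame({"gene": ["G1"], "tss": [1000]})
        links = abc_links(elements, genes, lambda d: np.ones_like(d), cutoff=0.0)
        assert len(links) == 2

    def test_cutoff_one_keeps_only_sole_contributor(self):
        elements = pd.DataFrame({"chrom": "1", "start": [0, 2000], "end": [100, 2100],
                                 "activity": [1.0, 1.0]})
        genes = pd.DataFrame({"gene": ["G1"], "tss": [1000]})
        assert abc_links(elements, genes, lambda d: np.ones_like(d), cutoff=1.0) == []
        solo = elements.iloc[:1]
        links = abc_links(solo, genes, lambda d: np.ones_like(d), cutoff=1.0)
        assert len(links) == 1

    def test_dominant_enhancer_always_linked(self):
        elements = pd.DataFrame({"chrom": "1", "start": [0, 2000, 4000],
                                 "end": [100, 2100, 4100],
                                 "activity": [10.0, 1.0, 1.0]})
        genes = pd.DataFrame({"gene": ["G1"], "tss": [1000]})
        links = abc_links(elements, genes, lambda d: np.ones_like(d), cutoff=0.5)
        assert len(links) == 1 and links[0].start == 0
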