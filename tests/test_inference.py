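"""Inference tests: within-triplet permutation, the significance rule,
bootstrap intervals and coverage, the KDE credible contour, and the
group-test contracts."""

import numpy as np
import pytest
from scipy import stats

from hrdelay.inference import (
    bivariate_credible_contour,
    bootstrap_ci,
    correlation,
    decode_with_labels,
    one_sample_t,
    paired_t,
    permutation_null_auc,
    permutation_test,
    permute_labels,
    rm_anova,
    rm_anova_interaction,
    signed_rank,
)
from hrdelay.pipeline import all_condition_pairs


class TestPermuteLabels:
    def test_uniform_over_six_orderings(self):
        rng = np.random.default_rng(0)
        labels = np.array(["a", "b", "c"])
        counts = {}
        n = 12000
        for _ in range(n):
            key = tuple(permute_labels(labels, rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi2 = sum((c - n / 6) ** 2 / (n / 6) for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=5)

    def test_preserves_triplet_multisets(self):
        rng = np.random.default_rng(1)
        labels = np.array(["a", "b", "c", "c", "a", "b"])
        out = permute_labels(labels, rng)
        assert set(out[:3]) == {"a", "b", "c"}
        assert set(out[3:]) == {"a", "b", "c"}

    def test_incomplete_triplet_rejected(self):
        with pytest.raises(ValueError, match="triplet"):
            permute_labels(np.array(["a", "b"]), 0)

    def test_five_triplets_span_7776_sequences(self):
        # 6**5 distinct sequences are reachable; sample many and never exceed
        rng = np.random.default_rng(2)
        labels = np.array(["a", "b", "c"] * 5)
        seen = {tuple(permute_labels(labels, rng)) for _ in range(4000)}
        assert 6**5 == 7776
        assert len(seen) <= 7776
        assert len(seen) > 2000  # far more than a few orderings


class TestPermutationRule:
    def test_direct_count_examples(self):
        p, _ = permutation_test(0.9, np.array([0.4, 0.5, 0.6]))
        assert p == 0.0
        p, _ = permutation_test(0.5, np.full(100, 0.5))
        assert p == 1.0
        null = np.linspace(0, 1, 1001)
        p, _ = permutation_test(0.5, null)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_significance_is_95th_percentile_exceedance(self):
        null = np.linspace(0, 1, 1000)
        assert permutation_test(0.999, null)[1]
        assert not permutation_test(0.90, null)[1]

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(0.5, np.array([]))

    def test_identity_permutation_reproduces_observed(self, null_participant):
        _, _, selectors = null_participant
        labels = [s.labels_ for s in selectors]
        pair = ("-45", "+45")
        observed = decode_with_labels(selectors, labels, pair, "both")
        again = decode_with_labels(selectors, [l.copy() for l in labels], pair, "both")
        assert observed == again

    def test_early_permutation_equals_vector_relabeling(self, design):
        """Permuting labels before estimation (here: shuffling which run
        carries which label, then re-running the whole analysis from raw
        data) gives the same decoding as relabeling run-level vectors."""
        from hrdelay.pipeline import analyze_participant
        from hrdelay.synth import GeneratorParams, build_ground_truth, simulate_study

        params = GeneratorParams.null()
        truth, meta = build_ground_truth(design, 20, params, seed=5)
        sessions = simulate_study(design, truth, seed=6, params=params, meta=meta)
        selectors = analyze_participant(sessions)
        rng = np.random.default_rng(7)
        # reorder runs within triplets while keeping the label sequence:
        # run order[k] now carries labels[k] -- an "early" permutation
        orders = []
        for ds in sessions:
            order = np.concatenate(
                [s + rng.permutation(3) for s in range(0, ds.n_runs, 3)]
            )
            ds.runs = ds.runs[order]
            orders.append(order)
        early_selectors = analyze_participant(sessions)
        labels = [np.asarray(ds.conditions) for ds in sessions]
        early = decode_with_labels(early_selectors, labels, ("-45", "plaid"), "both")
        # equivalent late relabeling on the original vectors
        late_labels = []
        for sel, order in zip(selectors, orders):
            inv = np.empty_like(order)
            inv[order] = np.arange(order.size)
            late_labels.append(np.asarray(sel.labels_)[inv])
        late = decode_with_labels(selectors, late_labels, ("-45", "plaid"), "both")
        assert early == pytest.approx(late, abs=1e-9)

    def test_permutation_p_uniform_on_null(self, rng):
        # p-values of a rank-exchangeable statistic are uniform on the grid
        n_rep, n_perm = 400, 64
        hits_10, hits_25 = 0, 0
        for _ in range(n_rep):
            observed = rng.standard_normal()
            null = rng.standard_normal(n_perm)
            p, _ = permutation_test(observed, null)
            hits_10 += p <= 0.10
            hits_25 += p <= 0.25
        for hits, alpha in ((hits_10, 0.10), (hits_25, 0.25)):
            se = np.sqrt(alpha * (1 - alpha) / n_rep)
            # discreteness: p <= alpha occurs with prob floor(alpha*n)/n
            target = np.floor(alpha * n_perm) / n_perm
            assert abs(hits / n_rep - target) < 3.5 * se


class TestBootstrap:
    def test_constant_data_zero_width(self):
        ci = bootstrap_ci(np.mean, np.full(20, 3.3), n_resamples=200, seed=0)
        assert ci.low == ci.high == ci.point == pytest.approx(3.3)

    def test_width_matches_analytic_se(self, rng):
        x = rng.standard_normal(50)
        ci = bootstrap_ci(np.mean, x, n_resamples=4000, seed=1)
        expected = 2 * 1.96 * x.std(ddof=0) / np.sqrt(50)
        assert abs(float(ci.width) - expected) / expected < 0.15

    def test_point_inside_interval(self, rng):
        for seed in range(5):
            x = rng.standard_normal(30)
            ci = bootstrap_ci(np.median, x, n_resamples=500, seed=seed)
            assert ci.low <= ci.point <= ci.high

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal(25)
        a = bootstrap_ci(np.mean, x, n_resamples=300, seed=9)
        b = bootstrap_ci(np.mean, x, n_resamples=300, seed=9)
        assert np.array_equal(a.resamples, b.resamples)

    def test_coverage_on_gaussian_means(self):
        # true percentile-bootstrap coverage of a Gaussian mean at n=50 is
        # ~93.5-94%; the empirical estimate at n_rep replicates carries
        # binomial noise, so allow 3 SE around the [93%, 97%] band
        rng = np.random.default_rng(77)
        n_rep, covered = 800, 0
        for _ in range(n_rep):
            x = rng.standard_normal(50)
            ci = bootstrap_ci(np.mean, x, n_resamples=499, seed=rng)
            covered += ci.low <= 0.0 <= ci.high
        se = np.sqrt(0.95 * 0.05 / n_rep)
        assert 0.93 - 3 * se <= covered / n_rep <= 0.97 + 3 * se

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.array([1.0]), n_resamples=10)


class TestCredibleContour:
    def test_isotropic_cloud_encloses_95_to_97(self, rng):
        pts = rng.standard_normal((4000, 2))
        cc = bivariate_credible_contour(pts)
        assert 0.95 <= cc.enclosed_fraction <= 0.97
        assert cc.polygons  # a contour polygon was extracted

    def test_enclosure_by_construction_on_any_input(self, rng):
        pts = rng.exponential(size=(500, 2)) * np.array([3.0, 0.5])
        cc = bivariate_credible_contour(pts, coverage=0.95)
        assert cc.enclosed_fraction >= 0.95

    def test_anisotropic_axis_ratio(self, rng):
        pts = rng.standard_normal((4000, 2)) * np.array([3.0, 1.0])
        cc = bivariate_credible_contour(pts)
        poly = max(cc.polygons, key=len)
        extent = poly.max(axis=0) - poly.min(axis=0)
        ratio = extent[0] / extent[1]
        assert abs(ratio - 3.0) / 3.0 < 0.25

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            bivariate_credible_contour(np.ones((200, 2)))


class TestGroupTests:
    def test_identical_paired_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rep = paired_t(x, x)
        assert rep.statistic == pytest.approx(0.0) or np.isnan(rep.statistic)

    def test_paired_t_against_hand_formula(self):
        # worked example recomputed from the definitional formula
        before = np.array([12.0, 15.0, 9.0, 13.0, 14.0, 11.0])
        after = np.array([10.0, 14.0, 9.5, 11.0, 12.0, 11.5])
        d = before - after
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_hand = 2 * stats.t.sf(abs(t_hand), d.size - 1)
        rep = paired_t(before, after)
        assert rep.statistic == pytest.approx(t_hand, abs=1e-4)
        assert rep.p == pytest.approx(p_hand, abs=1e-4)
        assert rep.df == (5,)

    def test_one_sample_t_one_sided(self):
        x = np.array([0.55, 0.6, 0.62, 0.58, 0.61, 0.57])
        rep = one_sample_t(x, 0.5, alternative="greater")
        assert rep.statistic > 0
        assert rep.p < 0.01

    def test_signed_rank_matches_scipy(self):
        x = np.array([1.2, 0.8, 1.5, 1.1, 0.9, 1.4])
        y = np.array([1.0, 0.7, 1.2, 1.3, 0.85, 1.0])
        rep = signed_rank(x, y)
        w, p = stats.wilcoxon(x, y)
        assert rep.statistic == pytest.approx(w)
        assert rep.p == pytest.approx(p)

    def test_rm_anova_monotone_in_shift(self, rng):
        base = rng.standard_normal((8, 3)) * 0.2
        f_values = []
        for shift in (0.5, 1.0, 2.0):
            data = base.copy()
            data[:, 2] += shift
            rep = rm_anova(data)
            assert rep.df == (2.0, 14.0)
            f_values.append(rep.statistic)
        assert f_values[0] > 0
        assert f_values == sorted(f_values)

    def test_rm_anova_interaction_detects_crossover(self, rng):
        data = rng.standard_normal((8, 2, 2)) * 0.1
        data[:, 0, 0] += 1.0
        data[:, 1, 1] += 1.0
        rep = rm_anova_interaction(data)
        assert rep.name == "rm_anova_interaction"
        assert rep.df == (1.0, 7.0)
        assert rep.p < 0.01

    def test_correlations(self):
        x = np.arange(6.0)
        y = 2 * x + 1
        assert correlation(x, y, "pearson").statistic == pytest.approx(1.0)
        assert correlation(x, y[::-1], "spearman").statistic == pytest.approx(-1.0)

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t(np.ones(4), np.ones(5))
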