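import numpy as np
import pandas as pd
import pytest

from silicofem.stats import (
    fit_gmm2_em,
    gaussian_loglik,
    ks_two_sample,
    normality_suite,
    roc_equal_error_threshold,
    stratify,
)


def _mixture_sample(n, rng, mus=(0.29, 0.55), sds=(0.12, 0.13), w=0.5):
    comp = rng.random(n) < w
    x = np.where(
        comp, rng.normal(mus[0], sds[0], n), rng.normal(mus[1], sds[1], n)
    )
    return x


class TestGmmEM:
    def test_recovers_reference_mixture_means(self):
        rng = np.random.default_rng(101)
        x = _mixture_sample(10_000, rng)
        fit = fit_gmm2_em(x)
        assert fit.mu1 == pytest.approx(0.29, abs=0.02)
        assert fit.mu2 == pytest.approx(0.55, abs=0.02)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(7)
        x = _mixture_sample(2000, rng)
        fit = fit_gmm2_em(x)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-9)
        # with a looser gain threshold the same sample converges
        assert fit_gmm2_em(x, tol=1e-6).converged

    def test_well_separated_spikes_recover_proportion(self):
        rng = np.random.default_rng(11)
        n1 = 300
        x = np.concatenate(
            [rng.normal(0.0, 0.01, n1), rng.normal(1.0, 0.01, 700)]
        )
        fit = fit_gmm2_em(x)
        assert fit.weight == pytest.approx(0.3, abs=0.02)
        assert fit.mu1 == pytest.approx(0.0, abs=0.01)
        assert fit.mu2 == pytest.approx(1.0, abs=0.01)

    def test_mean_recovery_over_replicates(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = _mixture_sample(10_000, rng)
            fit = fit_gmm2_em(x)
            errs.append(abs(fit.mu1 - 0.29) + abs(fit.mu2 - 0.55))
        assert np.mean(errs) / 2 < 0.01

    def test_agrees_with_sklearn_em(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(42)
        x = _mixture_sample(5000, rng)
        ours = fit_gmm2_em(x)
        gm = sklearn.GaussianMixture(
            n_components=2, n_init=5, random_state=0, tol=1e-8
        ).fit(x[:, None])
        ref = np.sort(gm.means_.ravel())
        assert ours.mu1 == pytest.approx(ref[0], abs=0.01)
        assert ours.mu2 == pytest.approx(ref[1], abs=0.01)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            fit_gmm2_em(np.full(10, 0.3))
        with pytest.raises(ValueError):
            fit_gmm2_em(np.array([0.1, 0.2]))


class TestEER:
    def test_separable_toy_perfect_classification(self):
        t, sens, spec = roc_equal_error_threshold(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1])
        )
        assert t == pytest.approx(2.5)
        assert sens == 1.0 and spec == 1.0

    def test_symmetric_gaussians_threshold_at_midpoint(self):
        rng = np.random.default_rng(3)
        neg = rng.normal(0.0, 1.0, 20_000)
        pos = rng.normal(2.0, 1.0, 20_000)
        scores = np.concatenate([neg, pos])
        labels = np.concatenate([np.zeros(20_000), np.ones(20_000)])
        t, sens, spec = roc_equal_error_threshold(scores, labels)
        assert t == pytest.approx(1.0, abs=0.05)
        assert sens == pytest.approx(spec, abs=0.01)

    def test_eer_minimal_over_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=150)
        labels = rng.random(150) < 0.4
        t, sens, spec = roc_equal_error_threshold(scores, labels)
        best_gap = abs(sens - spec)
        pos, neg = scores[labels], scores[~labels]
        uniq = np.unique(scores)
        for cand in np.concatenate(
            [[uniq[0] - 1], 0.5 * (uniq[:-1] + uniq[1:]), [uniq[-1] + 1]]
        ):
            gap = abs(np.mean(pos > cand) - np.mean(neg <= cand))
            assert best_gap <= gap + 1e-12

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_equal_error_threshold(np.arange(4.0), np.ones(4))


class TestKS:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        D, _ = ks_two_sample(x, x)
        assert D == 0.0

    def test_disjoint_supports_give_one(self):
        D, _ = ks_two_sample(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert D == 1.0

    def test_hand_enumerated_ecdf_gap(self):
        D, _ = ks_two_sample(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        assert D == pytest.approx(1.0 / 3.0)

    def test_matches_brute_force_on_small_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 50))
            y = rng.normal(0.3, 1.1, size=rng.integers(2, 50))
            D, _ = ks_two_sample(x, y)
            pts = np.concatenate([x, y])
            brute = max(
                abs(np.mean(x <= t) - np.mean(y <= t)) for t in pts
            )
            assert D == pytest.approx(brute, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample(np.array([]), np.array([1.0]))


class TestNormality:
    def test_gaussian_null_rarely_rejected(self):
        n_reject = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=500)
            res = normality_suite(x)
            if res["non_gaussian"].note == "True":
                n_reject += 1
        assert n_reject <= 4  # ~alpha = 0.05 per test, three tests

    def test_bimodal_sample_flagged_non_gaussian(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.01, 200), rng.normal(5, 0.01, 200)])
        res = normality_suite(x)
        assert res["non_gaussian"].note == "True"
        assert all(
            res[k].p_value < 0.05 for k in ("shapiro", "dagostino", "anderson")
        )

    def test_constant_sample_is_guarded(self):
        res = normality_suite(np.full(30, 1.5))
        assert not res["shapiro"].available
        assert not res["non_gaussian"].available


class TestStratify:
    table = pd.DataFrame(
        dict(
            arf0=[0.2, 0.3, 0.5, 0.7],
            label=["non-fractured", "non-fractured", "fractured", "fractured"],
        )
    )

    def test_threshold_above_max(self):
        rep = stratify(self.table, 0.9)
        assert rep.fraction_above == 0.0

    def test_threshold_below_min(self):
        rep = stratify(self.table, 0.1)
        assert rep.fraction_above == 1.0

    def test_hand_count(self):
        rep = stratify(self.table, 0.39)
        assert rep.n_above == 2
        assert rep.fraction_above == 0.5
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_tie_goes_to_non_fractured(self):
        rep = stratify(self.table, 0.5)
        assert rep.n_above == 1

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="arf0"):
            stratify(pd.DataFrame(dict(x=[1.0])), 0.5)


def test_bimodality_preferred_on_mixture_by_loglik():
    rng = np.random.default_rng(21)
    x = _mixture_sample(2000, rng)
    fit = fit_gmm2_em(x)
    assert fit.loglik > gaussian_loglik(x)
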