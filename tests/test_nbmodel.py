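import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from clipscore.nbmodel import (
    bh_fdr,
    combine_fisher,
    estimate_dispersion,
    fit_count_regression,
    nb_pvalue,
    nb_test,
)
from clipscore.scoring import score_pipeline
from clipscore.simulate import SimConfig, simulate_experiment


def nb_tail_oracle(observed: int, mu: float, alpha: float, tol: float = 1e-15) -> float:
    """P(X >= observed) by term-by-term log-pmf summation of the complement."""
    if observed == 0:
        return 1.0
    ks = np.arange(observed)
    if alpha == 0:
        logpmf = -mu + ks * np.log(mu) - gammaln(ks + 1)
    else:
        r = 1.0 / alpha
        p = r / (r + mu)
        logpmf = gammaln(ks + r) - gammaln(r) - gammaln(ks + 1) + r * np.log(p) + ks * np.log1p(-p)
    return float(1.0 - np.exp(logpmf).sum())


class TestNbPvalue:
    def test_zero_observed_is_exactly_one(self):
        assert nb_pvalue(0, 5.0, 0.3) == 1.0
        assert nb_pvalue(0, 5.0, 0.0) == 1.0

    def test_poisson_tail_value(self):
        # P(X >= 5 | Poisson(2)) ~ 0.0527
        assert nb_pvalue(5, 2.0, 0.0) == pytest.approx(nb_tail_oracle(5, 2.0, 0.0), abs=1e-12)
        assert nb_pvalue(5, 2.0, 0.0) == pytest.approx(0.052653, abs=1e-5)

    def test_overdispersed_tail_matches_summation(self):
        assert nb_pvalue(25, 10.0, 0.5) == pytest.approx(nb_tail_oracle(25, 10.0, 0.5), abs=1e-10)

    def test_monotone_nonincreasing_in_observed(self):
        p = [nb_pvalue(k, 7.0, 0.2) for k in range(60)]
        assert np.all(np.diff(p) <= 0)

    def test_pmf_mass_conserved(self):
        # tail at k plus mass below k must reconstruct 1 on truncated support
        for alpha in (0.0, 0.4):
            k = 250
            below = 1.0 - nb_pvalue(k, 20.0, alpha)
            tail = nb_pvalue(k, 20.0, alpha)
            assert below + tail == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nb_pvalue(3, 0.0, 0.1)
        with pytest.raises(ValueError):
            nb_pvalue(3, 2.0, -0.1)


class TestFisher:
    def test_all_ones(self):
        res = combine_fisher([1.0, 1.0, 1.0])
        assert res["chi2"] == 0.0
        assert res["p_combined"] == 1.0

    def test_single_p_identity(self):
        for p in (0.5, 0.03, 0.9):
            assert combine_fisher([p])["p_combined"] == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_combine_pvalues(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 8))
            ours = combine_fisher(p)
            ref_stat, ref_p = stats.combine_pvalues(p, method="fisher")
            assert ours["chi2"] == pytest.approx(ref_stat, abs=1e-12)
            assert ours["p_combined"] == pytest.approx(ref_p, abs=1e-12)

    def test_zero_clipped_not_dropped(self):
        res = combine_fisher([0.0, 0.5])
        assert np.isfinite(res["chi2"]) and res["p_combined"] >= 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            combine_fisher([])


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force step-up: q_(i) = min_{j>=i} p_(j)*n/j, capped at 1."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * n / j for j in range(rank_i, n + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_single_and_tied(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 40))
    def test_matches_step_up_oracle(self, seed, n):
        p = np.random.default_rng(seed).uniform(size=n)
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


class TestDispersion:
    def _matrix(self, rng, n, reps, mu, alpha):
        mu = rng.lognormal(np.log(mu), 1.0, n)
        if alpha == 0:
            mat = rng.poisson(mu[:, None], size=(n, reps))
        else:
            r = 1 / alpha
            mat = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, reps))
        return pd.DataFrame(mat, index=[f"t{i}" for i in range(n)],
                            columns=[f"rep{j}" for j in range(reps)])

    def test_poisson_counts_give_near_zero_trend(self):
        rng = np.random.default_rng(7)
        disp = estimate_dispersion(self._matrix(rng, 2000, 4, 50, 0.0),
                                   size_factors=np.ones(4))
        assert disp.a1 < 0.01

    def test_recovers_constant_alpha(self):
        rng = np.random.default_rng(8)
        disp = estimate_dispersion(self._matrix(rng, 3000, 8, 100, 0.2),
                                   size_factors=np.ones(8))
        mus = np.array([20.0, 50.0, 100.0, 500.0, 2000.0])
        fitted = disp.alpha(mus)
        assert np.all(fitted > 0.1) and np.all(fitted < 0.3)

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError):
            estimate_dispersion(pd.DataFrame({"rep1": [1, 2, 3]}))


class TestCountRegression:
    def test_identity_when_clip_equals_trap(self):
        trap = np.array([10.0, 40.0, 160.0, 640.0])
        mu, fit = fit_count_regression(trap.copy(), trap)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.smear == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(mu, trap, rtol=1e-10)

    def test_nonpositive_subtracted_excluded_from_fit_but_scored(self):
        clip = np.array([10.0, -3.0, 160.0, 0.0, 640.0])
        trap = np.array([10.0, 40.0, 160.0, 320.0, 640.0])
        mu, fit = fit_count_regression(clip, trap)
        assert fit.n_fit == 3
        assert np.isfinite(mu).all()

    def test_matches_normal_equation_oracle(self, ols):
        rng = np.random.default_rng(9)
        trap = rng.lognormal(3, 1, 50)
        clip = rng.lognormal(2, 1, 50)
        mu, fit = fit_count_regression(clip, trap)
        slope, intercept = ols(np.log(trap), np.log(clip))
        raw = np.exp(intercept + slope * np.log(trap))
        smear = clip.sum() / raw.sum()
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert np.allclose(mu, raw * smear, rtol=1e-9)

    def test_degenerate_fit_errors(self):
        with pytest.raises(ValueError):
            fit_count_regression(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))


class TestNbTestPipeline:
    def test_count_scores_rank_match_rpkm_scores(self, small_sim):
        """The count-based residual score and the RPKM-based score rank
        transcripts near-identically (Spearman rho > 0.9)."""
        table, _ = score_pipeline(small_sim.clip, small_sim.abundance, small_sim.txome)
        res = nb_test(small_sim.clip, small_sim.abundance)
        shared = table.index.intersection(res.index)
        a = table.loc[shared, "mean_clip_score"]
        b = res.loc[shared, "clip_score_counts"]
        mask = a.notna() & b.notna()
        rho = stats.spearmanr(a[mask], b[mask]).statistic
        assert rho > 0.9

    def test_planted_targets_reach_low_fdr(self, small_sim):
        res = nb_test(small_sim.clip, small_sim.abundance)
        truth = small_sim.truth.df.set_index("transcript_id")
        strong = truth.index[truth.binding_factor_log2 >= 2].intersection(res.index)
        assert (res.loc[strong, "fdr"] <= 0.05).mean() > 0.9

    def test_output_schema(self, small_sim):
        res = nb_test(small_sim.clip, small_sim.abundance)
        for col in ("mu_rep1", "p_rep1", "clip_score_counts", "fisher_chi2",
                    "p_combined", "fdr"):
            assert col in res.columns
        assert res["p_combined"].between(0, 1).all()
        assert res["fdr"].between(0, 1).all()
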