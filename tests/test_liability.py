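import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from sphmm import (
    EffectGrid,
    MixturePrior,
    family_heritability_fraction,
    fold_enrichment,
    genotype_frequencies,
    liability_variance,
    snp_variance_from_prior,
    solve_alpha,
    total_variance,
)


def oracle_liability_variance(beta, p, K, mu0=0.0):
    """From-scratch liability variance with an arbitrary location anchor.

    Independent implementation: bisection for the intercept, genotype
    liabilities anchored at mu0 for genotype 0 (any anchor gives the same
    variance), explicit between-genotype variance, v*/(1+v*) rescale.
    """
    h = [(1 - p) ** 2, 2 * p * (1 - p), p**2]

    def prev(a):
        return sum(h[x] / (1 + np.exp(-a - beta * x)) for x in range(3)) - K

    a = brentq(prev, -60, 60, xtol=1e-14)
    phi = [1 / (1 + np.exp(-a - beta * x)) for x in range(3)]
    # threshold relative to genotype 0: T - mu0 = Phi^-1(1 - phi0)
    T = mu0 + norm.isf(phi[0])
    mu = [T - norm.isf(phi[x]) for x in range(3)]
    mu_all = sum(h[x] * mu[x] for x in range(3))
    v_star = sum(h[x] * (mu[x] - mu_all) ** 2 for x in range(3))
    return v_star / (1 + v_star)


class TestGenotypeFrequencies:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, (0.25, 0.5, 0.25)), (0.1, (0.81, 0.18, 0.01))],
    )
    def test_hardy_weinberg_examples(self, p, expected):
        assert genotype_frequencies(p) == pytest.approx(expected, abs=1e-12)

    def test_sum_to_one(self):
        p = np.random.default_rng(0).uniform(0.001, 0.999, 1000)
        h0, h1, h2 = genotype_frequencies(p)
        assert np.allclose(h0 + h1 + h2, 1.0, atol=1e-12)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            genotype_frequencies(0.0)


class TestSolveAlpha:
    def test_zero_effect_closed_form(self):
        K = 0.013
        assert solve_alpha(0.0, 0.3, K) == pytest.approx(np.log(K / (1 - K)), abs=1e-12)

    def test_prevalence_constraint_residual(self):
        for beta in (-0.3, -0.1, 0.1, 0.25):
            for p in (0.05, 0.3, 0.7, 0.95):
                for K in (0.001, 0.01, 0.1, 0.4):
                    a = solve_alpha(beta, p, K)
                    h0, h1, h2 = genotype_frequencies(p)
                    resid = (
                        h0 * expit(a) + h1 * expit(a + beta) + h2 * expit(a + 2 * beta)
                    ) - K
                    assert abs(resid) < 1e-10

    def test_alpha_decreases_in_beta(self):
        alphas = [solve_alpha(b, 0.3, 0.01) for b in (0.0, 0.1, 0.2, 0.3)]
        assert all(a1 > a2 for a1, a2 in zip(alphas, alphas[1:]))

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            solve_alpha(0.1, 0.3, 1.5)


class TestLiabilityVariance:
    def test_zero_effect_explains_nothing(self):
        assert liability_variance(0.0, 0.4, 0.01) == 0.0

    def test_allele_relabel_symmetry(self):
        for beta, p, K in [(0.1, 0.3, 0.01), (0.25, 0.7, 0.05), (0.05, 0.1, 0.2)]:
            assert liability_variance(beta, p, K) == pytest.approx(
                liability_variance(-beta, 1 - p, K), abs=1e-12
            )

    def test_matches_independent_oracle(self):
        for beta, p, K in [(0.05, 0.5, 0.01), (0.2, 0.3, 0.05), (-0.15, 0.8, 0.1)]:
            assert liability_variance(beta, p, K) == pytest.approx(
                oracle_liability_variance(beta, p, K), rel=1e-9
            )

    def test_location_anchor_is_irrelevant(self):
        # the oracle anchors genotype 0 anywhere; variance must not move
        a = oracle_liability_variance(0.1, 0.3, 0.01, mu0=0.0)
        b = oracle_liability_variance(0.1, 0.3, 0.01, mu0=-7.3)
        assert a == pytest.approx(b, abs=1e-12)
        assert liability_variance(0.1, 0.3, 0.01) == pytest.approx(a, rel=1e-9)

    def test_quadratic_small_effect_limit(self):
        # v(2b)/v(b) -> 4 as b -> 0
        for b in (1e-3, 1e-4):
            ratio = liability_variance(2 * b, 0.3, 0.01) / liability_variance(
                b, 0.3, 0.01
            )
            assert ratio == pytest.approx(4.0, rel=5e-3)

    def test_strictly_increasing_in_abs_beta(self):
        betas = np.array([0.01, 0.05, 0.1, 0.2, 0.3])
        vs = liability_variance(betas, 0.3, 0.01)
        assert np.all(np.diff(vs) > 0)
        vs_neg = liability_variance(-betas, 0.3, 0.01)
        assert np.all(np.diff(vs_neg) > 0)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        betas = rng.uniform(-3, 3, 50)
        ps = rng.uniform(0.01, 0.99, 50)
        vs = liability_variance(betas, ps, 0.05)
        assert np.all((vs >= 0) & (vs < 1))

    def test_continuous_in_prevalence(self):
        Ks = np.linspace(0.001, 0.5, 60)
        vs = np.array([liability_variance(0.1, 0.3, K) for K in Ks])
        assert np.all(np.abs(np.diff(vs)) < 0.01)


class TestSnpVariance:
    def test_null_prior_gives_zero(self, small_grid):
        pr = MixturePrior.uniform(4, 0.0)
        assert snp_variance_from_prior(pr, small_grid, 0.3, 0.05) == 0.0

    def test_degenerate_prior_collapses(self, small_grid):
        masses = np.array([0.0, 0.0, 1.0, 0.0])  # all mass at b = 0.05
        pr = MixturePrior(pi=1.0, masses=masses)
        assert snp_variance_from_prior(pr, small_grid, 0.3, 0.05) == pytest.approx(
            liability_variance(0.05, 0.3, 0.05), rel=1e-12
        )

    def test_four_term_average(self):
        grid = EffectGrid(np.array([-0.10, -0.05, 0.05, 0.10]))
        pr = MixturePrior(pi=0.5, masses=np.full(4, 0.25))
        expected = 0.5 * np.mean(
            [liability_variance(b, 0.3, 0.05) for b in grid.points]
        )
        assert snp_variance_from_prior(pr, grid, 0.3, 0.05) == pytest.approx(
            expected, rel=1e-12
        )


class TestTotalVariance:
    def _frame(self, n=10, seed=0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "beta": rng.normal(0, 0.05, n),
                "var": rng.uniform(0.001, 0.01, n),
                "daf": rng.uniform(0.05, 0.95, n),
            }
        )

    def test_null_prior_gives_zero_total(self, small_grid):
        rep = total_variance(self._frame(), MixturePrior.uniform(4, 0.0), small_grid, 0.01)
        assert rep.V_hat == 0.0

    def test_duplication_doubles_total(self, small_grid):
        import pandas as pd

        pr = MixturePrior(pi=0.3, masses=np.full(4, 0.25))
        frame = self._frame()
        single = total_variance(frame, pr, small_grid, 0.01)
        doubled_frame = pd.concat([frame, frame.assign(snp_id=frame.snp_id + "_b")])
        doubled = total_variance(doubled_frame, pr, small_grid, 0.01)
        assert doubled.V_hat == pytest.approx(2 * single.V_hat, rel=1e-12)

    def test_missing_frequencies_skipped(self, small_grid):
        frame = self._frame()
        frame.loc[frame.index[:3], "daf"] = np.nan
        pr = MixturePrior(pi=0.3, masses=np.full(4, 0.25))
        with pytest.warns(UserWarning):
            rep = total_variance(frame, pr, small_grid, 0.01)
        assert rep.n_skipped == 3
        assert rep.n_used == 7

    def test_all_missing_rejected(self, small_grid):
        frame = self._frame()
        frame["daf"] = np.nan
        with pytest.raises(ValueError):
            total_variance(frame, MixturePrior.uniform(4, 0.5), small_grid, 0.01)


class TestReportingHelpers:
    def test_family_heritability_fractions(self):
        # (V + MHC) / h2_family reporting arithmetic
        assert round(100 * family_heritability_fraction(0.14, 0.12, 0.55), 1) == 47.3
        assert round(100 * family_heritability_fraction(0.20, 0.12, 0.55), 1) == 58.2

    def test_fold_enrichment(self):
        assert fold_enrichment(0.002, 0.0004) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            fold_enrichment(0.1, 0.0)
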