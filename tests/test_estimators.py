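"""Causal-effect estimators: published-value regression and oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from nutrimr import datasets
from nutrimr.estimators import (
    BootstrapConfig,
    DegenerateInstrumentError,
    egger,
    ivw,
    penalized_weighted_median,
    radial_ivw,
    run_all_methods,
    simple_median,
    wald_ratios,
    weighted_median,
)
from nutrimr.summary_data import HarmonizedInstrument

from conftest import random_instruments


def inst(bx, sx, by, sy, snp="rs"):
    return HarmonizedInstrument(snp_id=snp, bx=bx, sx=sx, by=by, sy=sy)


class TestWaldRatios:
    def test_published_extreme_ratio(self):
        rs = wald_ratios([inst(-0.072, 0.014, 0.319, 0.351)])
        assert rs.ratios[0] == pytest.approx(-4.4306, abs=1e-4)

    def test_arithmetic(self):
        rs = wald_ratios([inst(0.5, 0.1, 1.0, 0.2)])
        assert rs.ratios[0] == 2.0
        assert rs.ratio_ses[0] == pytest.approx(0.4)
        assert rs.weights[0] == pytest.approx(6.25)

    def test_joint_sign_flip_invariance(self):
        a = wald_ratios([inst(0.3, 0.1, -0.6, 0.2)])
        b = wald_ratios([inst(-0.3, 0.1, 0.6, 0.2)])
        assert a.ratios[0] == b.ratios[0]
        assert a.weights[0] == b.weights[0]

    def test_zero_bx_raises_naming_snp(self):
        with pytest.raises(DegenerateInstrumentError, match="rsZ"):
            wald_ratios([inst(0.0, 0.1, 0.5, 0.2, snp="rsZ")])


class TestIvw:
    @pytest.mark.parametrize(
        "nutrient,beta,se",
        [("phosphorus", 1.110, 1.728), ("vitamin_b2", 2.637, 1.376),
         ("vitamin_b6", -4.014, 1.624), ("vitamin_c", 2.572, 1.275)],
    )
    def test_reproduces_published_estimates(self, nutrient, beta, se):
        est = ivw(datasets.instruments(nutrient))
        assert est.beta == pytest.approx(beta, abs=0.05)
        assert est.se == pytest.approx(se, abs=0.05)

    def test_equals_wls_through_origin_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            instruments = random_instruments(rng, 6)
            est = ivw(instruments)
            bx = np.array([i.bx for i in instruments])
            by = np.array([i.by for i in instruments])
            sy = np.array([i.sy for i in instruments])
            fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
            assert est.beta == pytest.approx(fit.params[0], abs=1e-12)

    def test_beta_within_ratio_range(self):
        rng = np.random.default_rng(6)
        instruments = random_instruments(rng, 8)
        est = ivw(instruments)
        r = wald_ratios(instruments).ratios
        assert r.min() <= est.beta <= r.max()

    def test_single_instrument_is_wald_ratio_with_warning(self):
        with pytest.warns(UserWarning):
            est = ivw([inst(0.5, 0.1, 1.0, 0.2)])
        assert est.beta == 2.0


class TestRadial:
    @pytest.mark.parametrize(
        "nutrient,beta,se",
        [("vitamin_b6", -4.016, 1.023), ("vitamin_c", 2.573, 0.592)],
    )
    def test_reproduces_published_estimates(self, nutrient, beta, se):
        fit = radial_ivw(datasets.instruments(nutrient))
        assert fit.beta == pytest.approx(beta, abs=0.05)
        assert fit.se == pytest.approx(se, abs=0.05)

    def test_first_order_beta_equals_ivw_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            instruments = random_instruments(rng, 5)
            assert radial_ivw(instruments, weight_order="first").beta == pytest.approx(
                ivw(instruments).beta, abs=1e-13
            )

    def test_residual_variance_se_identity(self):
        """Under first-order weights, radial SE / IVW SE = sqrt(Q/(k−1))."""
        rng = np.random.default_rng(8)
        instruments = random_instruments(rng, 7)
        fit = radial_ivw(instruments, weight_order="first")
        ratio = fit.se / ivw(instruments).se
        assert ratio == pytest.approx(np.sqrt(fit.q_statistic / (len(instruments) - 1)), abs=1e-12)

    def test_q_decomposition(self):
        fit = radial_ivw(datasets.instruments("vitamin_b2"))
        assert fit.q_statistic == pytest.approx(fit.q_contributions.sum())
        assert np.all(fit.q_contributions >= 0)


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        # by = 0.1 + 2·bx with all bx > 0: exact fit, zero residuals
        instruments = [inst(bx, 0.01, 0.1 + 2 * bx, 0.1, snp=f"rs{i}")
                       for i, bx in enumerate([0.02, 0.05, 0.08, 0.11])]
        fit = egger(instruments)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.slope.beta == pytest.approx(2.0, abs=1e-12)

    def test_matches_wls_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            instruments = random_instruments(rng, 6)
            fit = egger(instruments)
            sign = np.array([np.sign(i.bx) for i in instruments])
            bx = np.array([i.bx for i in instruments]) * sign
            by = np.array([i.by for i in instruments]) * sign
            sy = np.array([i.sy for i in instruments])
            oracle = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
            assert fit.intercept == pytest.approx(oracle.params[0], abs=1e-12)
            assert fit.slope.beta == pytest.approx(oracle.params[1], abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger([inst(0.1, 0.01, 0.1, 0.1), inst(0.2, 0.01, 0.2, 0.1)])


class TestMedians:
    def test_simple_median_published_b6(self, b6_instruments, fast_boot):
        est = simple_median(b6_instruments, boot=fast_boot)
        assert est.beta == pytest.approx(-4.431, abs=0.01)

    def test_odd_and_even_count_conventions(self, fast_boot):
        odd = [inst(1, 0.1, r, 0.5, snp=f"a{r}") for r in (1.0, 2.0, 9.0)]
        assert simple_median(odd, boot=fast_boot).beta == 2.0
        even = [inst(1, 0.1, r, 0.5, snp=f"b{r}") for r in (1.0, 2.0, 3.0, 9.0)]
        assert simple_median(even, boot=fast_boot).beta == 2.5

    def test_equal_weights_reduce_to_simple_median(self, fast_boot):
        instruments = [inst(1.0, 0.1, r, 0.5, snp=f"rs{r}") for r in (1.0, 2.0, 9.0)]
        wm = weighted_median(instruments, boot=fast_boot)
        assert wm.beta == pytest.approx(2.0)

    def test_weighted_median_near_published_b6(self, b6_instruments, fast_boot):
        est = weighted_median(b6_instruments, boot=fast_boot)
        assert est.beta == pytest.approx(-4.377, abs=0.1)

    def test_weighted_median_matches_piecewise_scan_oracle(self, fast_boot):
        rng = np.random.default_rng(10)
        for _ in range(20):
            instruments = random_instruments(rng, 4)
            est = weighted_median(instruments, boot=fast_boot)
            rs = wald_ratios(instruments)
            order = np.argsort(rs.ratios)
            r, w = rs.ratios[order], rs.weights[order] / rs.weights.sum()
            s = np.cumsum(w) - w / 2
            # brute-force scan over the piecewise-linear cumulative function
            grid = np.linspace(r.min(), r.max(), 200001)
            cum = np.interp(grid, r, s)
            oracle = grid[np.argmin(np.abs(cum - 0.5))]
            assert est.beta == pytest.approx(oracle, abs=(r.max() - r.min()) / 50000)

    def test_penalty_inactive_without_outliers(self, fast_boot):
        instruments = [inst(0.1, 0.01, 0.1 * 2.0 + eps, 0.5, snp=f"rs{j}")
                       for j, eps in enumerate((0.01, -0.02, 0.015, 0.0))]
        wm = weighted_median(instruments, boot=fast_boot)
        pwm = penalized_weighted_median(instruments, boot=fast_boot)
        assert pwm.beta == pytest.approx(wm.beta, abs=1e-12)

    def test_penalized_published_b6(self, b6_instruments, fast_boot):
        est = penalized_weighted_median(b6_instruments, boot=fast_boot)
        assert est.beta == pytest.approx(-4.377, abs=0.1)

    def test_penalty_moves_estimate_toward_clean_median(self, fast_boot):
        rng = np.random.default_rng(12)
        clean = [inst(0.1, 0.005, 0.1 * 1.5 + rng.normal(0, 0.01), 0.05, snp=f"c{j}")
                 for j in range(8)]
        outlier = inst(0.1, 0.005, 0.1 * 15.0, 0.05, snp="out")
        contaminated = [*clean, outlier]
        wm_clean = weighted_median(clean, boot=fast_boot).beta
        wm = weighted_median(contaminated, boot=fast_boot).beta
        pwm = penalized_weighted_median(contaminated, boot=fast_boot).beta
        assert abs(pwm - wm_clean) < abs(wm - wm_clean)


class TestBalancedPleiotropyRobustness:
    """With balanced direct effects satisfying InSIDE, median estimators stay
    centred on the true effect while the IVW sampling variance inflates."""

    @staticmethod
    def _simulate(rng, tau, k=50, beta=1.5):
        bx = rng.uniform(0.03, 0.1, size=k) * rng.choice([-1, 1], size=k)
        sy = rng.uniform(0.05, 0.15, size=k)
        delta = np.zeros(k)
        which = rng.choice(k, size=k // 3, replace=False)
        delta[which] = rng.normal(0.0, tau, size=k // 3)  # independent of bx: InSIDE
        by = rng.normal(beta * bx + delta, sy)
        return [
            HarmonizedInstrument(snp_id=f"rs{i}", bx=bx[i], sx=0.005, by=by[i], sy=sy[i])
            for i in range(k)
        ]

    def test_median_unbiased_and_ivw_variance_inflates(self):
        rng = np.random.default_rng(2021)
        beta = 1.5
        boot = BootstrapConfig(n_boot=50, seed=0)
        ivw_clean, ivw_pleio, wm_pleio = [], [], []
        for _ in range(200):
            ivw_clean.append(ivw(self._simulate(rng, tau=0.0, beta=beta)).beta)
            instruments = self._simulate(rng, tau=0.3, beta=beta)
            ivw_pleio.append(ivw(instruments).beta)
            wm_pleio.append(weighted_median(instruments, boot=boot).beta)
        wm = np.asarray(wm_pleio)
        mc_se = wm.std(ddof=1) / np.sqrt(len(wm))
        assert abs(wm.mean() - beta) <= 2 * mc_se
        assert np.var(ivw_pleio) > 2 * np.var(ivw_clean)


class TestSuite:
    def test_all_methods_deterministic_under_seed(self, b6_instruments):
        a = run_all_methods(b6_instruments, seed=3, n_boot=300)
        b = run_all_methods(b6_instruments, seed=3, n_boot=300)
        assert a == b

    def test_all_methods_report_all_six(self, b6_instruments):
        ests = run_all_methods(b6_instruments, seed=0, n_boot=200)
        assert {e.method for e in ests} == {
            "ivw", "ivw_radial", "egger", "penalized_weighted_median",
            "weighted_median", "simple_median",
        }
        assert all(e.n_snp == 11 for e in ests)

    def test_sign_flip_invariance_of_all_methods(self, b6_instruments):
        flipped = [
            HarmonizedInstrument(snp_id=i.snp_id, bx=-i.bx, sx=i.sx, by=-i.by, sy=i.sy)
            for i in b6_instruments
        ]
        a = run_all_methods(b6_instruments, seed=1, n_boot=300)
        b = run_all_methods(flipped, seed=1, n_boot=300)
        for ea, eb in zip(a, b):
            assert ea.beta == pytest.approx(eb.beta, abs=1e-9)

    def test_bootstrap_se_converges(self, b6_instruments):
        se1 = simple_median(b6_instruments, boot=BootstrapConfig(10_000, 21)).se
        se2 = simple_median(b6_instruments, boot=BootstrapConfig(20_000, 22)).se
        assert abs(se2 - se1) / se1 < 0.05
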