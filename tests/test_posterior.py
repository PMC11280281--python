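"""Derived ratios, HPDI, summaries and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest

from matvar.gibbs import VarianceState
from matvar.posterior import (autocorrelation, derived_ratios, diagnostics,
                              effective_sample_size, geweke_z, hpdi, summarize)


class TestDerivedRatios:
    @pytest.mark.parametrize("components, expected_h2a, expected_h2m, expected_c2", [
        # published posterior-mean components for age at sexual maturity:
        # direct-additive-only fit, then the full maternal fit
        ((15.64, 0, 0, 0, 63.76), 0.20, 0.0, 0.0),
        ((27.26, 5.87, -9.52, 1.71, 60.11), 0.32, 0.07, 0.02),
        ((1, 0, 0, 0, 0), 1.0, 0.0, 0.0),
    ])
    def test_ratios_round_to_published_values(self, components, expected_h2a,
                                              expected_h2m, expected_c2):
        h2a, h2m, c2, s2p = derived_ratios(VarianceState(*components))
        assert round(h2a, 2) == expected_h2a
        assert round(h2m, 2) == expected_h2m
        assert round(c2, 2) == expected_c2

    def test_phenotypic_variance_includes_covariance(self):
        st = VarianceState(27.26, 5.87, -9.52, 1.71, 60.11)
        _, _, _, s2p = derived_ratios(st)
        assert s2p == pytest.approx(85.43)
        _, _, _, s2p_ex = derived_ratios(st, include_covariance=False)
        assert s2p_ex == pytest.approx(94.95)

    def test_fractions_sum_to_one_per_draw(self):
        st = VarianceState(27.26, 5.87, -9.52, 1.71, 60.11)
        h2a, h2m, c2, s2p = derived_ratios(st)
        total = h2a + h2m + c2 + st.sigma_am / s2p + st.sigma2_e / s2p
        assert total == pytest.approx(1.0)

    def test_nonpositive_phenotypic_variance_raises(self):
        with pytest.raises(ValueError, match="phenotypic"):
            derived_ratios(VarianceState(1.0, 1.0, -10.0, 0.0, 1.0))


class TestHPDI:
    def test_constant_chain(self):
        assert hpdi(np.full(500, 3.7)) == (3.7, 3.7)

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10_000)
        lo, hi = hpdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_uniform_interval_width(self):
        rng = np.random.default_rng(3)
        lo, hi = hpdi(rng.random(20_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_never_wider_than_equal_tailed(self):
        rng = np.random.default_rng(4)
        for x in (rng.standard_normal(3000), rng.gamma(2, size=3000),
                  rng.exponential(size=3000)):
            lo, hi = hpdi(x, 0.9)
            qlo, qhi = np.quantile(x, [0.05, 0.95])
            assert (hi - lo) <= (qhi - qlo) + 1e-12

    def test_matches_arviz_on_skewed_sample(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        x = rng.gamma(2.0, size=5000)
        lo, hi = hpdi(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)


class TestSummarize:
    def test_summary_table_fields(self, m3_chain):
        s = summarize(m3_chain)
        for p in ("sigma2_a", "sigma2_m", "sigma_am", "sigma2_pe", "sigma2_e",
                  "h2_additive", "h2_maternal", "c2_mpe", "sigma2_p"):
            row = s.table.loc[p]
            assert row["hpdi_low"] <= row["posterior_mean"] <= row["hpdi_high"]
        assert s.n_flagged == 0

    def test_ratio_of_means_agrees_with_mean_of_ratios(self, m3_chain):
        s = summarize(m3_chain)
        assert s.ratio_of_means["h2_additive"] == pytest.approx(
            s.table.loc["h2_additive", "posterior_mean"], abs=0.02)

    def test_order_invariance_of_mean_sd_hpdi(self, m3_chain):
        s1 = summarize(m3_chain)
        shuffled = m3_chain.draws.sample(frac=1.0, random_state=0).reset_index(drop=True)
        chain2 = type(m3_chain)(
            draws=shuffled, model=m3_chain.model, config=m3_chain.config,
            n_records=m3_chain.n_records, y=m3_chain.y,
            mean_fitted=m3_chain.mean_fitted, trait_name=m3_chain.trait_name)
        s2 = summarize(chain2)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_too_few_draws_rejected(self, m3_chain):
        short = type(m3_chain)(
            draws=m3_chain.draws.head(50), model=m3_chain.model,
            config=m3_chain.config, n_records=m3_chain.n_records, y=m3_chain.y,
            mean_fitted=m3_chain.mean_fitted)
        with pytest.raises(ValueError, match="100"):
            summarize(short)


class TestDiagnostics:
    def test_iid_chain_full_ess_and_stationary(self):
        rng = np.random.default_rng(6)
        n = 4000
        x = rng.standard_normal(n)
        assert effective_sample_size(x) == pytest.approx(n, rel=0.2)
        assert abs(geweke_z(x)) < 3

    def test_ar1_chain_ess_matches_closed_form(self):
        rng = np.random.default_rng(7)
        n, phi = 20_000, 0.9
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        # ESS ~ n (1-phi)/(1+phi) = n/19
        assert effective_sample_size(x) == pytest.approx(n / 19, rel=0.3)

    def test_ess_agrees_with_arviz_on_ar1(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        n, phi = 10_000, 0.8
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        mine = effective_sample_size(x)
        ref = float(az.ess(x[None, :]))
        assert mine == pytest.approx(ref, rel=0.25)

    def test_trending_chain_fails_geweke(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 5, 2000) + 0.1 * rng.standard_normal(2000)
        assert abs(geweke_z(x)) > 3

    def test_autocorrelation_of_ar1_decays_geometrically(self):
        rng = np.random.default_rng(10)
        n, phi = 50_000, 0.7
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        rho = autocorrelation(x, 3)
        assert rho[1] == pytest.approx(phi, abs=0.03)
        assert rho[2] == pytest.approx(phi ** 2, abs=0.03)

    def test_diagnostics_table_from_chain(self, m3_chain):
        table = diagnostics(m3_chain)
        assert {"geweke_z", "ess"}.issubset(table.columns)
        assert "sigma2_a" in table.index
        assert (table["ess"] > 0).all()

    def test_nonfinite_draws_rejected(self):
        df = pd.DataFrame({"x": np.r_[np.ones(300), np.nan, np.ones(99) + 0.5]})
        with pytest.raises(ValueError, match="non-finite"):
            diagnostics(df)
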