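"""Abbott correction, probit fitting and fiducial limits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mycosynergy.dose_response import (
    BioassaySeries,
    DoseGroup,
    ProbitFit,
    abbott_correct,
    angular_transform,
    continuity_adjust,
    empirical_probit,
    fit_probit_ml,
    fit_probit_ols,
    lc50_with_limits,
)
from mycosynergy.errors import InsufficientDataError, InvalidControlError


def model_series(slope, log_lc50, concentrations, n=250, label="model"):
    """A noiseless series whose mortalities sit exactly on a probit line."""
    groups = tuple(
        DoseGroup(
            concentration=c,
            mortality_pct=100.0 * stats.norm.cdf(slope * (np.log10(c) - log_lc50)),
            n_exposed=n,
        )
        for c in concentrations
    )
    return BioassaySeries(label=label, groups=groups)


class TestAbbott:
    @pytest.mark.parametrize(
        "treated, control, expected",
        [(56.8, 0.0, 56.8), (60.0, 20.0, 50.0), (20.0, 20.0, 0.0), (10.0, 20.0, 0.0)],
    )
    def test_examples(self, treated, control, expected):
        assert abbott_correct(treated, control) == pytest.approx(expected)

    def test_degenerate_control_rejected(self):
        with pytest.raises(InvalidControlError):
            abbott_correct(50.0, 100.0)

    @given(t=st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_zero_control_is_identity(self, t):
        assert abbott_correct(t, 0.0) == pytest.approx(t)

    @given(
        t=st.floats(min_value=0, max_value=100),
        c=st.floats(min_value=0, max_value=99),
        dt=st.floats(min_value=0.01, max_value=10),
    )
    def test_monotone_in_treated(self, t, c, dt):
        assert abbott_correct(min(t + dt, 100.0), c) >= abbott_correct(t, c)

    @given(
        t=st.floats(min_value=30, max_value=100),
        c=st.floats(min_value=0, max_value=25),
        dc=st.floats(min_value=0.01, max_value=4),
    )
    def test_decreasing_in_control_when_treated_above(self, t, c, dc):
        assert abbott_correct(t, c + dc) <= abbott_correct(t, c)


class TestTransforms:
    @pytest.mark.parametrize("p, deg", [(0.0, 0.0), (0.5, 45.0), (1.0, 90.0)])
    def test_angular(self, p, deg):
        assert angular_transform(p) == pytest.approx(deg)

    def test_angular_domain(self):
        with pytest.raises(ValueError):
            angular_transform(1.2)

    @pytest.mark.parametrize(
        "p, probit", [(0.5, 5.0), (0.975, 6.95996), (0.158655, 4.0)]
    )
    def test_empirical_probit(self, p, probit):
        assert empirical_probit(p) == pytest.approx(probit, abs=1e-4)

    def test_probit_boundary_mentions_continuity_rule(self):
        with pytest.raises(ValueError, match="continuity"):
            empirical_probit(1.0)

    @pytest.mark.parametrize(
        "dead, n, expected", [(0, 250, 0.002), (250, 250, 0.998), (125, 250, 0.5)]
    )
    def test_continuity_adjust(self, dead, n, expected):
        assert continuity_adjust(dead, n) == pytest.approx(expected)

    def test_continuity_adjust_zero_n(self):
        with pytest.raises(ValueError):
            continuity_adjust(0, 0)


class TestNoiselessRecovery:
    def test_ols_recovers_generating_line(self):
        series = model_series(2.0, 0.5, (0.7, 1.4, 2.1, 2.8, 3.5))
        fit = fit_probit_ols(series)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.log_lc50 == pytest.approx(0.5, abs=1e-9)

    def test_ml_equals_ols_on_noiseless_data(self):
        series = model_series(3.0, 0.2, (0.5, 1.0, 2.0, 4.0))
        ols = fit_probit_ols(series)
        ml = fit_probit_ml(series)
        assert ml.log_lc50 == pytest.approx(ols.log_lc50, abs=1e-6)
        assert ml.slope == pytest.approx(ols.slope, abs=1e-6)

    def test_two_point_symmetry(self):
        """40%/60% mortality symmetric about c* on the log scale -> LC50 = c*."""
        c_star = 2.5
        shift = 0.3
        z = stats.norm.ppf(0.6)
        groups = tuple(
            DoseGroup(concentration=10 ** (np.log10(c_star) + s), mortality_pct=m)
            for s, m in [(-shift, 40.0), (shift, 60.0)]
        )
        del z
        series = BioassaySeries(label="sym", groups=groups)
        assert fit_probit_ols(series).lc50 == pytest.approx(c_star, rel=1e-9)


class TestReferenceSeries:
    def test_pinene_ols_lc50_near_published(self, table4_4d):
        fit = fit_probit_ols(table4_4d["pinene"])
        assert fit.lc50 == pytest.approx(3.41, rel=0.05)

    def test_ml_agrees_with_glm_oracle(self, table4_4d):
        """Our IRLS equals an independent GLM binomial-probit fit."""
        sm = pytest.importorskip("statsmodels.api")
        for label in ("pinene", "conidia", "scheme_IV"):
            series = table4_4d[label]
            x = np.log10([g.concentration for g in series.groups])
            r = np.array([g.n_dead for g in series.groups])
            n = np.array([g.n_exposed for g in series.groups], dtype=float)
            glm = sm.GLM(
                np.column_stack([r, n - r]),
                sm.add_constant(x),
                family=sm.families.Binomial(sm.families.links.Probit()),
            ).fit()
            a, b = glm.params
            fit = fit_probit_ml(series)
            assert fit.log_lc50 == pytest.approx(-a / b, abs=1e-5)
            assert fit.slope == pytest.approx(b, rel=1e-4)

    def test_ml_agrees_with_grid_likelihood_oracle(self, table4_4d):
        """IRLS maximises the binomial likelihood: compare with a brute-force
        coarse-to-fine grid search over (log LC50, slope)."""
        series = table4_4d["scheme_III"]
        x = np.log10([g.concentration for g in series.groups])
        r = np.array([g.n_dead for g in series.groups])
        n = np.array([g.n_exposed for g in series.groups], dtype=float)

        def loglik(m, b):
            P = np.clip(stats.norm.cdf(b * (x - m)), 1e-12, 1 - 1e-12)
            return float(np.sum(r * np.log(P) + (n - r) * np.log(1 - P)))

        m_lo, m_hi, b_lo, b_hi = -0.5, 1.0, 0.5, 8.0
        best = None
        for _ in range(4):
            ms = np.linspace(m_lo, m_hi, 60)
            bs = np.linspace(b_lo, b_hi, 60)
            ll = np.array([[loglik(m, b) for b in bs] for m in ms])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            best = (ms[i], bs[j])
            dm, db = (m_hi - m_lo) / 59, (b_hi - b_lo) / 59
            m_lo, m_hi = best[0] - 2 * dm, best[0] + 2 * dm
            b_lo, b_hi = max(0.01, best[1] - 2 * db), best[1] + 2 * db
        fit = fit_probit_ml(series)
        assert fit.log_lc50 == pytest.approx(best[0], abs=2e-3)
        assert fit.slope == pytest.approx(best[1], rel=5e-3)
        assert fit.lc50 == pytest.approx(2.40, rel=0.10)

    def test_ols_and_ml_agree_within_15pct(self, table4_4d):
        for series in table4_4d.values():
            ols = fit_probit_ols(series)
            ml = fit_probit_ml(series)
            assert ml.lc50 == pytest.approx(ols.lc50, rel=0.15)

    def test_heterogeneity_factor_floor(self, table4_4d):
        fit = fit_probit_ml(table4_4d["scheme_IV"])  # chi2/df < 1 here
        assert fit.heterogeneity_factor == 1.0


class TestFiducialLimits:
    def test_noiseless_limits_collapse_to_point(self):
        series = model_series(2.0, 0.5, (0.7, 1.4, 2.1, 2.8, 3.5))
        est = lc50_with_limits(fit_probit_ols(series))
        assert est.limits_defined
        assert est.lower == pytest.approx(est.lc50, rel=1e-4)
        assert est.upper == pytest.approx(est.lc50, rel=1e-4)

    def test_reference_limits_bracket_estimate(self, table4_4d):
        fit = fit_probit_ml(table4_4d["scheme_IV"])
        est = lc50_with_limits(fit)
        assert est.limits_defined
        assert est.lower < est.lc50 < est.upper
        assert est.lc50 == pytest.approx(1.32, rel=0.10)

    def test_g_at_least_one_flags_unbounded(self):
        fit = ProbitFit(
            slope=0.05,
            intercept=5.0,
            log_lc50=0.0,
            cov=np.eye(2),
            chi2_het=0.0,
            df=3,
            method="ML-IRLS",
            sum_w=100.0,
            x_wbar=0.0,
            sxx=1.0,
        )
        est = lc50_with_limits(fit)
        assert not est.limits_defined
        assert est.g >= 1.0
        assert np.isnan(est.lower) and np.isnan(est.upper)

    def test_negative_slope_rejected(self):
        groups = tuple(
            DoseGroup(concentration=c, mortality_pct=m)
            for c, m in [(1.0, 60.0), (2.0, 40.0)]
        )
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_probit_ols(BioassaySeries(label="down", groups=groups))
        with pytest.raises(ValueError):
            lc50_with_limits(fit)


class TestSeriesHandling:
    def test_insufficient_distinct_concentrations(self):
        groups = (DoseGroup(concentration=1.0, mortality_pct=40.0),)
        with pytest.raises(InsufficientDataError):
            fit_probit_ols(BioassaySeries(label="one", groups=groups))

    def test_duplicate_concentrations_pooled(self):
        base = model_series(2.0, 0.5, (0.7, 1.4, 2.8))
        split = BioassaySeries(
            label="split",
            groups=base.groups
            + tuple(
                DoseGroup(
                    concentration=g.concentration,
                    mortality_pct=g.mortality_pct,
                    n_exposed=g.n_exposed,
                )
                for g in base.groups
            ),
        )
        assert fit_probit_ols(split).log_lc50 == pytest.approx(
            fit_probit_ols(base).log_lc50, abs=1e-9
        )

    def test_abbott_applied_for_user_control_mortality(self):
        series = model_series(2.0, 0.5, (0.7, 1.4, 2.1, 2.8, 3.5))
        fit0 = fit_probit_ml(series)
        fit20 = fit_probit_ml(series, control_mortality_pct=20.0)
        assert fit20.lc50 > fit0.lc50  # deflating kill shifts LC50 up
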