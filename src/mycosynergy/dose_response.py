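"""Concentration-mortality probit analysis for quantal acaricide bioassays.

A bioassay exposes batches of mites (here 50 per leaf disk, 5 replicate
disks, so 250 per dose group) to a ladder of concentrations and records
cumulative mortality.  The analysis chain is classical quantal-response
methodology:

1. Treated mortality is corrected for natural (control) death with
   Abbott's formula, (T - C) / (100 - C) * 100.
2. Corrected proportions are related to log10 concentration through the
   probit link.  The probit of a proportion p is Phi^{-1}(p) + 5 (the
   +5 offset is the traditional convention keeping working values
   positive), so the model is probit(p) = a + b * log10(conc).
3. The median lethal concentration is LC50 = 10^((5 - a)/b), and 95%
   fiducial limits follow from Fieller's theorem on the ratio
   (5 - a)/b, widened by the heterogeneity factor chi2/df when the
   replicate scatter exceeds binomial expectation.

Two fitters are provided.  ``fit_probit_ols`` regresses empirical
probits on log10 concentration by unweighted least squares - the
transparent hand-calculation variant.  ``fit_probit_ml`` is the maximum
likelihood fit of the binomial probit model via Fisher scoring
(iteratively reweighted least squares with the classical working-probit
weights n z^2 / (P Q)); it is the default for analysis.

The angular (arcsine square-root) transform used for ANOVA of mortality
percentages is provided as a standalone utility; it is not part of the
probit chain (probit regression operates on proportions directly).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConvergenceError, InsufficientDataError, InvalidControlError

__all__ = [
    "DoseGroup",
    "BioassaySeries",
    "ProbitFit",
    "LC50Estimate",
    "abbott_correct",
    "angular_transform",
    "empirical_probit",
    "continuity_adjust",
    "fit_probit_ols",
    "fit_probit_ml",
    "lc50_with_limits",
]

#: Default mites per dose group: 50 per leaf disk x 5 replicate disks.
DEFAULT_N_EXPOSED = 250


@dataclass(frozen=True)
class DoseGroup:
    """Mortality observed in one dose group at one time point."""

    concentration: float  # total treatment concentration, mg/mL, > 0
    mortality_pct: float  # cumulative percent mortality in [0, 100]
    n_exposed: int = DEFAULT_N_EXPOSED
    time_d: float = 4.0  # days post-exposure

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"concentration must be positive, got {self.concentration}")
        if not 0.0 <= self.mortality_pct <= 100.0:
            raise ValueError(
                f"mortality_pct must be in [0, 100], got {self.mortality_pct}"
            )
        if self.n_exposed <= 0:
            raise ValueError(f"n_exposed must be positive, got {self.n_exposed}")

    @property
    def n_dead(self) -> float:
        """Implied death count (may be fractional when built from a percent)."""
        return self.mortality_pct / 100.0 * self.n_exposed


@dataclass(frozen=True)
class BioassaySeries:
    """One treatment's concentration ladder at a common time point.

    ``components`` optionally records the mixture composition as
    ``(name, proportion, concentration ladder)`` triples; for sole
    applications it holds a single entry.  ``control_mortality_pct`` is
    the natural mortality used for Abbott correction (0 when the
    mortality data are already corrected).
    """

    label: str
    groups: tuple[DoseGroup, ...]
    control_mortality_pct: float = 0.0
    components: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.control_mortality_pct < 100.0:
            raise InvalidControlError(
                f"control mortality must be in [0, 100), got "
                f"{self.control_mortality_pct}"
            )
        times = {g.time_d for g in self.groups}
        if len(times) > 1:
            raise ValueError(f"groups must share one time point, got {sorted(times)}")

    @property
    def time_d(self) -> float | None:
        return self.groups[0].time_d if self.groups else None

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([g.concentration for g in self.groups])


@dataclass(frozen=True)
class ProbitFit:
    """A fitted probit concentration-mortality line.

    The line is probit(p) = intercept + slope * log10(conc); under the
    probit-plus-5 convention log_lc50 = (5 - intercept)/slope.  ``cov``
    is the 2x2 covariance of (intercept, slope), already inflated by the
    heterogeneity factor when chi2_het/df > 1 (Finney's practice).
    The weighted moments (sum_w, x_wbar, sxx) are retained because
    Fieller's fiducial limits are expressed in them.
    """

    slope: float
    intercept: float
    log_lc50: float
    cov: np.ndarray
    chi2_het: float
    df: int
    method: str  # "empirical-OLS" or "ML-IRLS"
    sum_w: float = field(repr=False, default=np.nan)
    x_wbar: float = field(repr=False, default=np.nan)
    sxx: float = field(repr=False, default=np.nan)
    n_iter: int = field(repr=False, default=0)

    @property
    def lc50(self) -> float:
        return 10.0 ** self.log_lc50

    @property
    def heterogeneity_factor(self) -> float:
        if self.df <= 0:
            return 1.0
        return max(1.0, self.chi2_het / self.df)


@dataclass(frozen=True)
class LC50Estimate:
    """LC50 point estimate with 95% fiducial limits.

    When Fieller's g-statistic reaches 1 the limits are unbounded;
    ``limits_defined`` is then False and lower/upper are NaN.
    """

    lc50: float
    lower: float
    upper: float
    g: float
    heterogeneity_factor: float
    limits_defined: bool = True


# ---------------------------------------------------------------------------
# elementary transforms


def abbott_correct(treated_pct: float, control_pct: float) -> float:
    """Abbott's correction of treated mortality for natural mortality.

    Returns 100 * (T - C) / (100 - C), floored at 0 (a treated group
    that dies less than the control is treated as zero response).
    """
    if not 0.0 <= control_pct < 100.0:
        raise InvalidControlError(
            f"control mortality must be in [0, 100), got {control_pct}"
        )
    if not 0.0 <= treated_pct <= 100.0:
        raise ValueError(f"treated mortality must be in [0, 100], got {treated_pct}")
    corrected = 100.0 * (treated_pct - control_pct) / (100.0 - control_pct)
    return max(0.0, corrected)


def angular_transform(p: float) -> float:
    """Arcsine square-root transform of a proportion, in degrees [0, 90].

    Standard variance-stabilising transform for percentage data ahead
    of ANOVA; not used inside the probit fit.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    return math.degrees(math.asin(math.sqrt(p)))


def empirical_probit(p: float) -> float:
    """Empirical probit 5 + Phi^{-1}(p) of a mortality proportion.

    Requires 0 < p < 1; apply :func:`continuity_adjust` first for
    all-dead or all-alive groups.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"probit undefined for p={p}; apply continuity_adjust to map "
            f"0 -> 1/(2n) and 1 -> 1 - 1/(2n) first"
        )
    return 5.0 + stats.norm.ppf(p)


def continuity_adjust(n_dead: float, n_exposed: int) -> float:
    """Observed proportion with 0 and 1 pulled inside the open interval.

    Returns n_dead/n_exposed, replacing 0 with 1/(2n) and 1 with
    1 - 1/(2n) so the probit transform is defined for every group.
    """
    if n_exposed <= 0:
        raise ValueError(f"n_exposed must be positive, got {n_exposed}")
    if not 0 <= n_dead <= n_exposed:
        raise ValueError(f"n_dead={n_dead} outside [0, {n_exposed}]")
    p = n_dead / n_exposed
    half = 1.0 / (2.0 * n_exposed)
    if p == 0.0:
        return half
    if p == 1.0:
        return 1.0 - half
    return p


# ---------------------------------------------------------------------------
# fitting


def _prepare(series: BioassaySeries, control_mortality_pct: float | None):
    """Pool duplicate concentrations, Abbott-correct, continuity-adjust.

    Returns (x, p, n): log10 concentrations, adjusted proportions and
    group sizes as arrays sorted by concentration.
    """
    control = (
        series.control_mortality_pct
        if control_mortality_pct is None
        else control_mortality_pct
    )
    pooled: dict[float, list[float]] = {}
    for g in series.groups:
        pooled.setdefault(g.concentration, [0.0, 0])
        acc = pooled[g.concentration]
        acc[0] += g.n_dead
        acc[1] += g.n_exposed
    concs = sorted(pooled)
    if len(concs) < 2:
        raise InsufficientDataError(
            f"series {series.label!r}: need >=2 distinct concentrations, "
            f"got {len(concs)}"
        )
    x, p, n = [], [], []
    for c in concs:
        dead, exposed = pooled[c]
        pct = abbott_correct(100.0 * dead / exposed, control)
        x.append(math.log10(c))
        p.append(continuity_adjust(pct / 100.0 * exposed, exposed))
        n.append(exposed)
    return np.asarray(x), np.asarray(p), np.asarray(n, dtype=float)


def _chi2_heterogeneity(x, p, n, intercept, slope) -> float:
    """Pearson goodness-of-fit chi-square of observed vs fitted kill."""
    fitted = stats.norm.cdf(intercept + slope * x - 5.0)
    fitted = np.clip(fitted, 1e-12, 1.0 - 1e-12)
    return float(np.sum(n * (p - fitted) ** 2 / (fitted * (1.0 - fitted))))


def fit_probit_ols(
    series: BioassaySeries, control_mortality_pct: float | None = None
) -> ProbitFit:
    """Unweighted least-squares fit of empirical probits on log10 dose.

    The transparent cross-check variant: every step can be reproduced
    on paper from a probit table.  Parameter covariance uses the
    residual mean square with k - 2 degrees of freedom, so fiducial
    limits for this method use Student's t throughout.
    """
    x, p, n = _prepare(series, control_mortality_pct)
    y = np.array([empirical_probit(pi) for pi in p])
    k = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * xbar
    if slope <= 0:
        warnings.warn(
            f"series {series.label!r}: non-positive probit slope {slope:.3g}; "
            "not a concentration-dependent response",
            stacklevel=2,
        )
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2) / (k - 2)) if k > 2 else 0.0
    s2 = max(s2, 1e-300)  # all-collinear data: degenerate but defined
    cov = s2 * np.array(
        [[1.0 / k + xbar**2 / sxx, -xbar / sxx], [-xbar / sxx, 1.0 / sxx]]
    )
    return ProbitFit(
        slope=slope,
        intercept=intercept,
        log_lc50=(5.0 - intercept) / slope,
        cov=cov,
        chi2_het=_chi2_heterogeneity(x, p, n, intercept, slope),
        df=k - 2,
        method="empirical-OLS",
        sum_w=k / s2,
        x_wbar=xbar,
        sxx=sxx / s2,
    )


def fit_probit_ml(
    series: BioassaySeries,
    control_mortality_pct: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProbitFit:
    """Maximum-likelihood binomial probit fit via Fisher scoring.

    Iteratively reweighted least squares on the working probit with
    weights w = n z^2 / (P Q), started from the OLS fit; converged when
    successive log-LC50 estimates change by less than ``tol``.
    Reports the Pearson heterogeneity chi-square on k - 2 df; when
    chi2/df > 1 the covariance is inflated by that factor.
    """
    x, p, n = _prepare(series, control_mortality_pct)
    k = len(x)
    start = fit_probit_ols(series, control_mortality_pct)
    a, b = start.intercept, start.slope
    if b <= 0:
        # scoring needs a rising line to start from; a flat guess recovers
        b = 1.0
        a = 5.0 - x.mean()

    sum_w = x_wbar = sxx = np.nan
    log_lc50 = (5.0 - a) / b
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = a + b * x - 5.0
        P = np.clip(stats.norm.cdf(eta), 1e-12, 1.0 - 1e-12)
        Z = stats.norm.pdf(eta)
        if np.any(Z < 1e-290):
            raise ConvergenceError(
                f"series {series.label!r}: working weights vanished "
                "(complete separation / infinite slope)",
                last_fit=(a, b),
            )
        w = n * Z**2 / (P * (1.0 - P))
        y_work = 5.0 + eta + (p - P) / Z
        sum_w = float(w.sum())
        x_wbar = float((w * x).sum() / sum_w)
        y_wbar = float((w * y_work).sum() / sum_w)
        sxx = float((w * (x - x_wbar) ** 2).sum())
        sxy = float((w * (x - x_wbar) * (y_work - y_wbar)).sum())
        b = sxy / sxx
        a = y_wbar - b * x_wbar
        new_log_lc50 = (5.0 - a) / b
        if abs(new_log_lc50 - log_lc50) < tol:
            log_lc50 = new_log_lc50
            converged = True
            break
        log_lc50 = new_log_lc50
    if not converged:
        raise ConvergenceError(
            f"series {series.label!r}: IRLS did not converge in "
            f"{max_iter} iterations (last log LC50 {log_lc50:.6f})",
            last_fit=(a, b),
        )
    if b <= 0:
        warnings.warn(
            f"series {series.label!r}: non-positive probit slope {b:.3g}",
            stacklevel=2,
        )

    chi2 = _chi2_heterogeneity(x, p, n, a, b)
    df = k - 2
    h = max(1.0, chi2 / df) if df > 0 else 1.0
    cov = h * np.array(
        [
            [1.0 / sum_w + x_wbar**2 / sxx, -x_wbar / sxx],
            [-x_wbar / sxx, 1.0 / sxx],
        ]
    )
    return ProbitFit(
        slope=b,
        intercept=a,
        log_lc50=log_lc50,
        cov=cov,
        chi2_het=chi2,
        df=df,
        method="ML-IRLS",
        sum_w=sum_w,
        x_wbar=x_wbar,
        sxx=sxx,
        n_iter=n_iter,
    )


def lc50_with_limits(fit: ProbitFit, confidence: float = 0.95) -> LC50Estimate:
    """LC50 with Fieller fiducial limits from a probit fit.

    Limits follow Finney's expression for the ratio m = (5 - a)/b on
    the log scale,

        m_{L,U} = m + g/(1-g) (m - xbar)
                  +/- t / (b (1-g)) sqrt(h [(1-g)/Sum(w) + (m-xbar)^2/Sxx])

    with g = h t^2 / (b^2 Sxx).  For the ML fit, h is the
    heterogeneity factor and t is the normal deviate unless chi2/df > 1,
    in which case Student's t on df replaces it; the OLS fit always
    uses Student's t (its variance is residual-based).  When g >= 1 the
    slope is not significantly positive and the limits are unbounded.
    """
    if fit.slope <= 0:
        raise ValueError("fiducial limits require a positive probit slope")
    if not np.isfinite(fit.sum_w) or not np.isfinite(fit.sxx):
        raise ValueError("fit carries no weighted moments; refit required")

    alpha = 1.0 - confidence
    if fit.method == "empirical-OLS":
        h = 1.0  # scatter already absorbed in the residual variance
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, fit.df) if fit.df > 0 else np.inf
    else:
        h = fit.heterogeneity_factor
        if fit.df > 0 and fit.chi2_het / fit.df > 1.0:
            tcrit = stats.t.ppf(1.0 - alpha / 2.0, fit.df)
        else:
            tcrit = stats.norm.ppf(1.0 - alpha / 2.0)

    m = fit.log_lc50
    g = h * tcrit**2 / (fit.slope**2 * fit.sxx)
    if g >= 1.0:
        return LC50Estimate(
            lc50=fit.lc50,
            lower=math.nan,
            upper=math.nan,
            g=g,
            heterogeneity_factor=h,
            limits_defined=False,
        )
    centre = m + g / (1.0 - g) * (m - fit.x_wbar)
    half = (
        tcrit
        / (fit.slope * (1.0 - g))
        * math.sqrt(h * ((1.0 - g) / fit.sum_w + (m - fit.x_wbar) ** 2 / fit.sxx))
    )
    return LC50Estimate(
        lc50=fit.lc50,
        lower=10.0 ** (centre - half),
        upper=10.0 ** (centre + half),
        g=g,
        heterogeneity_factor=h,
        limits_defined=True,
    )
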