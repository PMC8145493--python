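"""Synthetic bioassay and growth-assay generators.

These generators emulate the statistical structure the analysis modules
assume, so the whole pipeline is testable without wet-lab data.

Mortality bioassays follow the binomial probit model.  Each leaf disk
holds ``n_per_replicate`` mites (default 50) and each dose group has
``replicates`` disks (default 5, so 250 mites per group - the published
assay design).  The kill probability at concentration ``conc`` is

    p = c + (1 - c) * Phi(slope * (log10(conc) - log_lc50))

where ``c`` is the natural (control) mortality, composed as an
independent competing risk - exactly the model Abbott's correction
inverts, so the correction is unbiased in expectation here.  An
optional per-day response profile multiplies the asymptotic kill
probability; per-mite uniform thresholds make the cumulative counts
monotone over days.

Growth assays draw replicate measurements normally around means that
decline linearly with concentration; germination is clipped to
[0, 100].  Default control means and inhibition slopes mirror the
magnitudes of the reference compatibility assay.

Every generator is a pure function of (config, seed): re-running with
the same seed reproduces the output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compatibility import GrowthRecord
from .dose_response import BioassaySeries, DoseGroup
from .mixture_toxicity import expected_lc50

__all__ = [
    "BioassaySimConfig",
    "GrowthSimConfig",
    "SimulatedBioassay",
    "MixtureSimResult",
    "simulate_bioassay",
    "simulate_mixture_experiment",
    "simulate_growth_assay",
    "mean_growth_records",
]


def _validation_errors(conditions: dict[str, bool]) -> list[str]:
    return [msg for msg, ok in conditions.items() if not ok]


@dataclass(frozen=True)
class BioassaySimConfig:
    """Ground truth and design of one simulated mortality bioassay.

    slope        probit slope per log10(mg/mL), > 0
    log_lc50     log10 LC50, log10(mg/mL)
    control_mortality  natural mortality proportion in [0, 1)
    concentrations     tested ladder, mg/mL (control handled separately)
    n_per_replicate    mites per leaf disk (default 50)
    replicates         leaf disks per dose group (default 5)
    time_profile       optional {day: fraction of asymptotic response};
                       None simulates only the 4-day snapshot
    seed               RNG seed
    """

    slope: float = 2.0
    log_lc50: float = 0.5
    control_mortality: float = 0.02
    concentrations: tuple[float, ...] = (0.7, 1.4, 2.1, 2.8, 3.5)
    n_per_replicate: int = 50
    replicates: int = 5
    time_profile: dict[float, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        problems = _validation_errors(
            {
                "slope must be > 0": self.slope > 0,
                "log_lc50 must be finite": np.isfinite(self.log_lc50),
                "control_mortality must be in [0, 1)": 0
                <= self.control_mortality
                < 1,
                "concentrations must be positive": all(
                    c > 0 for c in self.concentrations
                ),
                "concentrations must be non-empty": len(self.concentrations) > 0,
                "n_per_replicate must be > 0": self.n_per_replicate > 0,
                "replicates must be > 0": self.replicates > 0,
                "time_profile fractions must be in (0, 1]": self.time_profile is None
                or all(0 < f <= 1 for f in self.time_profile.values()),
            }
        )
        if problems:
            raise ValueError("invalid BioassaySimConfig: " + "; ".join(problems))

    def kill_probability(self, conc: float, day_fraction: float = 1.0) -> float:
        """Model mortality probability at one concentration."""
        target = day_fraction * stats.norm.cdf(
            self.slope * (np.log10(conc) - self.log_lc50)
        )
        return float(self.control_mortality + (1 - self.control_mortality) * target)


@dataclass(frozen=True)
class GrowthSimConfig:
    """Design of one simulated compatibility (growth) assay.

    control_means       (germination %, radial growth mm, conidia/mL)
    inhibition_per_unit fractional decline of each mean per mg/mL
    noise_sd            per-replicate normal SDs for the three measures
    replicates          Petri dishes per concentration (default 10)
    seed                RNG seed

    Defaults mirror the reference assay's magnitudes: control means
    (98.9, 86.6, 7.9) and SDs of roughly SE * sqrt(10) of its printed
    standard errors.
    """

    control_means: tuple[float, float, float] = (98.9, 86.6, 7.9)
    inhibition_per_unit: tuple[float, float, float] = (0.011, 0.041, 0.094)
    noise_sd: tuple[float, float, float] = (2.8, 6.3, 1.7)
    replicates: int = 10
    seed: int = 0

    def validate(self) -> None:
        problems = _validation_errors(
            {
                "control_means must be positive": all(m > 0 for m in self.control_means),
                "noise_sd must be non-negative": all(s >= 0 for s in self.noise_sd),
                "replicates must be > 0": self.replicates > 0,
            }
        )
        if problems:
            raise ValueError("invalid GrowthSimConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class SimulatedBioassay:
    """A simulated assay: aggregated series plus replicate-level detail."""

    series: BioassaySeries
    replicates: pd.DataFrame  # columns: concentration, replicate, time_d, n, n_dead
    config: BioassaySimConfig

    @property
    def control_mortality_pct(self) -> float:
        return self.series.control_mortality_pct


@dataclass(frozen=True)
class MixtureSimResult:
    """Three simulated series with the mixture ground truth attached."""

    assay_a: SimulatedBioassay
    assay_b: SimulatedBioassay
    assay_mix: SimulatedBioassay
    p_a: float
    interaction: float
    true_mix_lc50: float


def simulate_bioassay(
    config: BioassaySimConfig,
    rng: np.random.Generator | None = None,
    label: str = "simulated",
) -> SimulatedBioassay:
    """Draw one bioassay under the binomial probit model.

    Per-mite uniform thresholds are drawn once and compared against the
    (monotone) per-day kill probabilities, so cumulative counts never
    decrease over time.  The control group (concentration 0) is
    simulated the same way and its observed mortality stored on the
    series for Abbott correction downstream.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    days = sorted(config.time_profile) if config.time_profile else [4.0]
    fractions = (
        [config.time_profile[d] for d in days] if config.time_profile else [1.0]
    )

    rows = []
    n = config.n_per_replicate
    for conc in (0.0, *config.concentrations):
        for rep in range(config.replicates):
            u = rng.random(n)
            for day, frac in zip(days, fractions):
                if conc == 0.0:
                    p = config.control_mortality * frac
                else:
                    p = config.kill_probability(conc, frac)
                rows.append(
                    {
                        "concentration": conc,
                        "replicate": rep,
                        "time_d": day,
                        "n": n,
                        "n_dead": int(np.sum(u < p)),
                    }
                )
    detail = pd.DataFrame(rows)

    last_day = days[-1]
    final = detail[detail["time_d"] == last_day]
    grouped = final.groupby("concentration")[["n", "n_dead"]].sum()
    control_pct = 100.0 * grouped.loc[0.0, "n_dead"] / grouped.loc[0.0, "n"]
    groups = tuple(
        DoseGroup(
            concentration=float(conc),
            mortality_pct=100.0 * row["n_dead"] / row["n"],
            n_exposed=int(row["n"]),
            time_d=last_day,
        )
        for conc, row in grouped.iterrows()
        if conc > 0
    )
    series = BioassaySeries(
        label=label, groups=groups, control_mortality_pct=float(control_pct)
    )
    return SimulatedBioassay(series=series, replicates=detail, config=config)


def simulate_mixture_experiment(
    config_a: BioassaySimConfig,
    config_b: BioassaySimConfig,
    p_a: float,
    interaction: float = 1.0,
    seed: int | None = None,
) -> MixtureSimResult:
    """Simulate two sole-component assays and their proportional mixture.

    The mixture's true LC50 (on the total-concentration scale) is the
    standard harmonic-additivity expectation divided by ``interaction``:
    1 is exact additivity, > 1 potentiation, < 1 antagonism.  The
    mixture ladder pairs p_a of ladder A with (1 - p_a) of ladder B and
    its probit slope is the mean of the component slopes.  One RNG
    stream (seeded from ``seed``, default config_a.seed) drives all
    three assays.
    """
    if interaction <= 0:
        raise ValueError(f"interaction multiplier must be > 0, got {interaction}")
    if not 0.0 < p_a < 1.0:
        raise ValueError(f"p_a must lie strictly in (0, 1), got {p_a}")
    config_a.validate()
    config_b.validate()
    if len(config_a.concentrations) != len(config_b.concentrations):
        raise ValueError("component ladders must have equal length")
    rng = np.random.default_rng(config_a.seed if seed is None else seed)

    additive = expected_lc50(
        10.0**config_a.log_lc50, 10.0**config_b.log_lc50, p_a, variant="standard"
    )
    true_mix_lc50 = additive / interaction
    totals = tuple(
        p_a * a + (1 - p_a) * b
        for a, b in zip(config_a.concentrations, config_b.concentrations)
    )
    config_mix = BioassaySimConfig(
        slope=(config_a.slope + config_b.slope) / 2.0,
        log_lc50=float(np.log10(true_mix_lc50)),
        control_mortality=(config_a.control_mortality + config_b.control_mortality)
        / 2.0,
        concentrations=totals,
        n_per_replicate=config_a.n_per_replicate,
        replicates=config_a.replicates,
        time_profile=config_a.time_profile,
        seed=config_a.seed,
    )
    return MixtureSimResult(
        assay_a=simulate_bioassay(config_a, rng=rng, label="component_a"),
        assay_b=simulate_bioassay(config_b, rng=rng, label="component_b"),
        assay_mix=simulate_bioassay(config_mix, rng=rng, label="mixture"),
        p_a=p_a,
        interaction=interaction,
        true_mix_lc50=true_mix_lc50,
    )


def simulate_growth_assay(
    config: GrowthSimConfig,
    concentrations: tuple[float, ...],
    rng: np.random.Generator | None = None,
) -> list[GrowthRecord]:
    """Draw replicate-level growth records, control included.

    Each mean declines linearly with concentration (floored at zero);
    replicates are independent normal draws.  Germination is clipped to
    [0, 100], the other measures to >= 0.  Aggregate with
    :func:`mean_growth_records` before running a compatibility report.
    """
    config.validate()
    if any(c <= 0 for c in concentrations):
        raise ValueError("treated concentrations must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    records = []
    for conc in (0.0, *concentrations):
        means = [
            m * max(0.0, 1.0 - k * conc)
            for m, k in zip(config.control_means, config.inhibition_per_unit)
        ]
        for _ in range(config.replicates):
            draws = rng.normal(means, config.noise_sd)
            records.append(
                GrowthRecord(
                    concentration=conc,
                    germination_pct=float(np.clip(draws[0], 0.0, 100.0)),
                    vegetative_growth_mm=float(max(0.0, draws[1])),
                    conidiation=float(max(0.0, draws[2])),
                )
            )
    return records


def mean_growth_records(records: list[GrowthRecord]) -> list[GrowthRecord]:
    """Average replicate-level records to one record per concentration."""
    frame = pd.DataFrame(
        {
            "concentration": [r.concentration for r in records],
            "germination_pct": [r.germination_pct for r in records],
            "vegetative_growth_mm": [r.vegetative_growth_mm for r in records],
            "conidiation": [r.conidiation for r in records],
        }
    )
    means = frame.groupby("concentration", sort=True).mean().reset_index()
    return [
        GrowthRecord(
            concentration=float(row.concentration),
            germination_pct=float(row.germination_pct),
            vegetative_growth_mm=float(row.vegetative_growth_mm),
            conidiation=float(row.conidiation),
        )
        for row in means.itertuples()
    ]
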