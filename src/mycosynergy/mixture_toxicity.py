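"""Joint-toxicity analysis of two-component acaricide mixtures.

A mixture trial pairs fractions of the two sole-component concentration
ladders.  With category weights p_A : p_B (e.g. 80% toxin : 20%
conidia), level i of the mixture contains p_A * A_i of component A and
p_B * B_i of component B, and the mixture dose metric is their sum.

Under dose additivity, the expected mixture LC50 follows from the
sole-component LC50s.  Two additivity conventions are implemented:

``standard``
    harmonic (Finney/co-toxicity-coefficient style) additivity,
    1/E = p_A/LC50_A + p_B/LC50_B.

``paper``
    the convention with the component proportions exchanged,
    E = LC50_A * LC50_B / (p_A * LC50_A + p_B * LC50_B).
    It reproduces the published joint-toxicity indices of this assay
    family digit-for-digit, but note that it violates the
    pure-component identity: at p_A = 1 it does not return LC50_A.
    A warning is emitted when it is selected; use ``standard`` for new
    analyses.

The joint-toxicity index is 100 * E / observed mixture LC50; an index
of at least 100 is classed synergistic, below 100 antagonistic.  In the
``paper`` convention the expected LC50 is quantised to 0.01 mg/mL
before the index is formed, matching the two-decimal hand-calculation
chain the published indices are consistent with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

from .errors import DesignError
from ._utils import round_half_away
from .dose_response import BioassaySeries, ProbitFit, fit_probit_ml, fit_probit_ols

__all__ = [
    "MixtureScheme",
    "JointToxicityResult",
    "InteractionClass",
    "SCHEME_PRESETS",
    "PINENE_LADDER",
    "CONIDIA_LADDER",
    "design_scheme",
    "expected_lc50",
    "joint_toxicity_index",
    "classify_interaction",
    "joint_toxicity_from_lc50s",
    "joint_toxicity_pipeline",
]

#: Sole-component concentration ladders (mg/mL) of the reference assay.
PINENE_LADDER = (0.7, 1.4, 2.1, 2.8, 3.5)
CONIDIA_LADDER = (4.0, 8.0, 12.0, 16.0, 20.0)


class InteractionClass(str, Enum):
    SYNERGISTIC = "Synergistic"
    ANTAGONISTIC = "Antagonistic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MixtureScheme:
    """A proportional two-component mixture design.

    ``p_a`` is the category weight of component A: the fraction of
    component A's sole ladder carried into the mixture (component B
    contributes 1 - p_a of its own ladder).  Category weights are not
    mass fractions of the mixture; the latter are exposed as
    :attr:`mass_fraction_a`.
    """

    p_a: float
    base_series_a: tuple[float, ...]
    base_series_b: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.p_a < 1.0:
            raise DesignError(f"p_a must lie strictly in (0, 1), got {self.p_a}")
        if len(self.base_series_a) != len(self.base_series_b):
            raise DesignError(
                f"base ladders differ in length: {len(self.base_series_a)} vs "
                f"{len(self.base_series_b)}"
            )
        for name, series in (("a", self.base_series_a), ("b", self.base_series_b)):
            arr = list(series)
            if any(v <= 0 for v in arr):
                raise DesignError(f"base series {name} must be strictly positive")
            if any(b <= a for a, b in zip(arr, arr[1:])):
                raise DesignError(f"base series {name} must be strictly increasing")

    @property
    def p_b(self) -> float:
        return 1.0 - self.p_a

    @property
    def levels(self) -> tuple[tuple[float, float], ...]:
        """Per-level (component A, component B) concentrations, mg/mL."""
        return tuple(
            (self.p_a * a, self.p_b * b)
            for a, b in zip(self.base_series_a, self.base_series_b)
        )

    @property
    def totals(self) -> tuple[float, ...]:
        """Total mixture concentration per level (the dose metric)."""
        return tuple(a + b for a, b in self.levels)

    @property
    def mass_fraction_a(self) -> tuple[float, ...]:
        """Component A's share of the total concentration at each level."""
        return tuple(a / (a + b) for a, b in self.levels)


#: The four published scheme presets (component A = toxin, B = conidia).
SCHEME_PRESETS: dict[str, MixtureScheme] = {
    "I": MixtureScheme(0.2, PINENE_LADDER, CONIDIA_LADDER),
    "II": MixtureScheme(0.4, PINENE_LADDER, CONIDIA_LADDER),
    "III": MixtureScheme(0.6, PINENE_LADDER, CONIDIA_LADDER),
    "IV": MixtureScheme(0.8, PINENE_LADDER, CONIDIA_LADDER),
}


@dataclass(frozen=True)
class JointToxicityResult:
    """Observed vs additivity-expected mixture LC50 and the verdict."""

    lc50_a: float
    lc50_b: float
    lc50_mix: float
    expected_lc50: float
    index: float
    classification: InteractionClass
    variant: str
    fit_a: ProbitFit | None = None
    fit_b: ProbitFit | None = None
    fit_mix: ProbitFit | None = None

    @property
    def index_rounded(self) -> int:
        """Integer presentation value (ties away from zero)."""
        return round_half_away(self.index)


def design_scheme(
    p_a: float, base_a: tuple[float, ...], base_b: tuple[float, ...]
) -> MixtureScheme:
    """Build a proportional mixture scheme from category weight ``p_a``
    and the two sole-component concentration ladders."""
    return MixtureScheme(p_a=p_a, base_series_a=tuple(base_a), base_series_b=tuple(base_b))


def expected_lc50(
    lc50_a: float, lc50_b: float, p_a: float, variant: str = "standard"
) -> float:
    """Additivity-expected mixture LC50 from the sole-component LC50s.

    ``standard`` is harmonic additivity 1/E = p_a/LC50_A + p_b/LC50_B;
    ``paper`` exchanges the proportions, E = A*B/(p_a*A + p_b*B), and
    is provided solely to reproduce the published indices.
    """
    if lc50_a <= 0 or lc50_b <= 0:
        raise ValueError("component LC50s must be positive")
    if not 0.0 <= p_a <= 1.0:
        raise ValueError(f"p_a must be in [0, 1], got {p_a}")
    p_b = 1.0 - p_a
    if variant == "standard":
        return 1.0 / (p_a / lc50_a + p_b / lc50_b)
    if variant == "paper":
        warnings.warn(
            "the 'paper' additivity variant swaps the component proportions "
            "and violates the pure-component identity (p_a=1 does not return "
            "LC50_A); it exists to reproduce the published indices - use "
            "'standard' for new analyses",
            stacklevel=2,
        )
        return lc50_a * lc50_b / (p_a * lc50_a + p_b * lc50_b)
    raise ValueError(f"unknown additivity variant {variant!r}")


def joint_toxicity_index(expected: float, observed: float) -> float:
    """Joint-toxicity index, 100 * expected / observed mixture LC50."""
    if observed <= 0:
        raise ValueError(f"observed LC50 must be positive, got {observed}")
    if expected <= 0:
        raise ValueError(f"expected LC50 must be positive, got {expected}")
    return 100.0 * expected / observed


def classify_interaction(index: float) -> InteractionClass:
    """Class boundary at 100, inclusive on the synergistic side."""
    if not math.isfinite(index) or index <= 0:
        raise ValueError(f"index must be finite and positive, got {index!r}")
    return (
        InteractionClass.SYNERGISTIC
        if index >= 100.0
        else InteractionClass.ANTAGONISTIC
    )


def joint_toxicity_from_lc50s(
    lc50_a: float,
    lc50_b: float,
    lc50_mix: float,
    p_a: float,
    variant: str = "standard",
) -> JointToxicityResult:
    """Index and classification directly from three LC50s.

    In the ``paper`` variant the expected LC50 is rounded to two
    decimals before the index is formed (the published indices follow
    that hand-calculation chain); the ``standard`` variant is computed
    at full precision.
    """
    with warnings.catch_warnings():
        if variant == "paper":
            warnings.simplefilter("ignore")  # variant caveat surfaced at call site
        expected = expected_lc50(lc50_a, lc50_b, p_a, variant=variant)
    if variant == "paper":
        expected = round(expected, 2)
    index = joint_toxicity_index(expected, lc50_mix)
    return JointToxicityResult(
        lc50_a=lc50_a,
        lc50_b=lc50_b,
        lc50_mix=lc50_mix,
        expected_lc50=expected,
        index=index,
        classification=classify_interaction(index),
        variant=variant,
    )


def joint_toxicity_pipeline(
    series_a: BioassaySeries,
    series_b: BioassaySeries,
    scheme_series: BioassaySeries,
    p_a: float,
    variant: str = "standard",
    method: str = "ml",
) -> JointToxicityResult:
    """Fit three probit models and derive the joint-toxicity verdict.

    ``series_a`` and ``series_b`` are the sole-component assays,
    ``scheme_series`` the mixture assay on the total-concentration
    scale.  Fitting errors are re-raised with the offending series'
    label attached.
    """
    fitter = {"ml": fit_probit_ml, "ols": fit_probit_ols}.get(method)
    if fitter is None:
        raise ValueError(f"unknown fitting method {method!r}")
    fits = {}
    for name, series in (
        ("a", series_a),
        ("b", series_b),
        ("mix", scheme_series),
    ):
        try:
            fits[name] = fitter(series)
        except Exception as exc:
            raise type(exc)(f"[series {series.label!r}] {exc}") from exc
    base = joint_toxicity_from_lc50s(
        fits["a"].lc50, fits["b"].lc50, fits["mix"].lc50, p_a, variant=variant
    )
    return JointToxicityResult(
        lc50_a=base.lc50_a,
        lc50_b=base.lc50_b,
        lc50_mix=base.lc50_mix,
        expected_lc50=base.expected_lc50,
        index=base.index,
        classification=base.classification,
        variant=variant,
        fit_a=fits["a"],
        fit_b=fits["b"],
        fit_mix=fits["mix"],
    )
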