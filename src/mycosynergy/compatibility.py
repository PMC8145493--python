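"""Fungus-toxin compatibility scoring via the Biological Index.

Before combining an entomopathogenic fungus with a candidate chemical,
the chemical's effect on the fungus itself is assayed on three growth
parameters: conidial germination (GR, percent), vegetative growth
(VG, colony radius in mm) and conidiation (SP, conidia per mL).  Each
parameter is expressed as a percentage of the untreated control and the
three are combined into a single Biological Index

    BI = (47 * VG + 43 * SP + 10 * GR) / 100

where VG, SP and GR are the relative-to-control percentages.  The
weights reflect how strongly each parameter predicts field performance
of the fungus; they sum to 100, so a chemical with no effect scores 100.
The index is banded into three compatibility classes: BI > 66 is
Compatible, 42 <= BI <= 66 is Moderately Toxic, BI < 42 is Toxic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import DesignError, InvalidControlError
from ._utils import round_half_away

__all__ = [
    "GrowthRecord",
    "CompatibilityResult",
    "CompatibilityClass",
    "BI_WEIGHTS",
    "relative_percent",
    "inhibition_percent",
    "biological_index",
    "classify_compatibility",
    "compatibility_report",
]

#: Biological Index weights (vegetative growth, conidiation, germination).
BI_WEIGHTS = {"vg": 47.0, "sp": 43.0, "gr": 10.0}


class CompatibilityClass(str, Enum):
    COMPATIBLE = "Compatible"
    MODERATELY_TOXIC = "Moderately Toxic"
    TOXIC = "Toxic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GrowthRecord:
    """One concentration's fungal growth measurements.

    Parameters
    ----------
    concentration
        Toxin concentration in mg/mL; 0 marks the untreated control.
    germination_pct
        Percent conidial germination, in [0, 100].
    vegetative_growth_mm
        Colony radial length in mm, non-negative.
    conidiation
        Conidia per mL (any consistent unit, e.g. value x 10^7),
        non-negative.
    """

    concentration: float
    germination_pct: float
    vegetative_growth_mm: float
    conidiation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.germination_pct <= 100.0:
            raise ValueError(
                f"germination_pct must be in [0, 100], got {self.germination_pct}"
            )
        if self.vegetative_growth_mm < 0 or self.conidiation < 0:
            raise ValueError("growth measurements must be non-negative")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def is_control(self) -> bool:
        return self.concentration == 0


@dataclass(frozen=True)
class CompatibilityResult:
    """Relative growth parameters and Biological Index for one concentration."""

    concentration: float
    gr_rel: float
    vg_rel: float
    sp_rel: float
    bi: float
    bi_class: CompatibilityClass

    @property
    def bi_rounded(self) -> int:
        """Integer presentation value (ties round away from zero)."""
        return round_half_away(self.bi)


def relative_percent(treated: float, control: float) -> float:
    """Express a treated measurement as a percentage of its control.

    Not clipped above 100: a treated value exceeding the control simply
    yields a relative value above 100.
    """
    if control <= 0:
        raise InvalidControlError(f"control must be positive, got {control}")
    if treated < 0:
        raise ValueError(f"treated measurement must be non-negative, got {treated}")
    return 100.0 * treated / control


def inhibition_percent(control: float, treated: float) -> float:
    """Percent reduction of a measurement relative to its control.

    May be negative when the treated value exceeds the control.
    Complementary to :func:`relative_percent`:
    ``inhibition_percent(c, t) + relative_percent(t, c) == 100``.
    """
    if control <= 0:
        raise InvalidControlError(f"control must be positive, got {control}")
    return 100.0 * (control - treated) / control


def biological_index(gr_rel: float, vg_rel: float, sp_rel: float) -> float:
    """Weighted Biological Index from relative-to-control percentages.

    BI = (47*VG + 43*SP + 10*GR) / 100.  The weights sum to 100, so
    equal inputs are returned unchanged (BI(x, x, x) == x).
    """
    if gr_rel < 0 or vg_rel < 0 or sp_rel < 0:
        raise ValueError("relative growth percentages must be non-negative")
    return (
        BI_WEIGHTS["vg"] * vg_rel
        + BI_WEIGHTS["sp"] * sp_rel
        + BI_WEIGHTS["gr"] * gr_rel
    ) / 100.0


def classify_compatibility(bi: float) -> CompatibilityClass:
    """Band a Biological Index value into a compatibility class.

    BI > 66 -> Compatible; 42 <= BI <= 66 -> Moderately Toxic;
    BI < 42 -> Toxic.  The middle band is closed at both ends.
    """
    if not math.isfinite(bi):
        raise ValueError(f"Biological Index must be finite, got {bi!r}")
    if bi > 66:
        return CompatibilityClass.COMPATIBLE
    if bi >= 42:
        return CompatibilityClass.MODERATELY_TOXIC
    return CompatibilityClass.TOXIC


def compatibility_report(records: list[GrowthRecord]) -> list[CompatibilityResult]:
    """Score every treated record of one assay against its control.

    `records` must contain exactly one control (concentration 0) and at
    least one treated record.  Results are ordered by concentration and
    each is internally consistent: `bi` is re-derivable from the three
    relative values.
    """
    controls = [r for r in records if r.is_control]
    treated = [r for r in records if not r.is_control]
    if len(controls) != 1:
        raise DesignError(
            f"expected exactly one control record (concentration 0), "
            f"found {len(controls)}"
        )
    if not treated:
        raise DesignError("no treated records to score")
    control = controls[0]

    results = []
    for rec in sorted(treated, key=lambda r: r.concentration):
        gr = relative_percent(rec.germination_pct, control.germination_pct)
        vg = relative_percent(rec.vegetative_growth_mm, control.vegetative_growth_mm)
        sp = relative_percent(rec.conidiation, control.conidiation)
        bi = biological_index(gr, vg, sp)
        results.append(
            CompatibilityResult(
                concentration=rec.concentration,
                gr_rel=gr,
                vg_rel=vg,
                sp_rel=sp,
                bi=bi,
                bi_class=classify_compatibility(bi),
            )
        )
    return results
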