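"""CSV readers/writers, packaged reference fixtures and the combined report.

All file formats are plain comma-separated UTF-8 with a mandatory
header row and '.' decimals.  Two input schemas exist:

growth assays
    ``concentration,germination_pct,vegetative_growth_mm,conidiation``
    with the control encoded as concentration 0.

mortality assays
    ``treatment,component_a_conc,component_b_conc,total_conc,time_d,
    n_exposed,mortality_pct``; one series is assembled per
    treatment x time point, doses on the total-concentration scale.

The packaged fixtures carry the reference study's printed tables:
growth-parameter means, the six cumulative-mortality blocks at 2/4/6
days (treatment means, n recorded as 250 = 50 mites x 5 replicates so
likelihood weighting is well defined) and the published LC50s/indices
for regression testing.  The fixture mortalities are shipped as printed,
i.e. already corrected for natural mortality, so their series carry
``control_mortality_pct = 0``.
"""

from __future__ import annotations

import logging
import sys
from importlib import resources
from pathlib import Path

import pandas as pd

from .compatibility import CompatibilityResult, GrowthRecord, compatibility_report
from .dose_response import (
    BioassaySeries,
    DoseGroup,
    LC50Estimate,
    ProbitFit,
    fit_probit_ml,
    fit_probit_ols,
    lc50_with_limits,
)
from .errors import DesignError, SchemaError
from .mixture_toxicity import SCHEME_PRESETS, joint_toxicity_pipeline

__all__ = [
    "GROWTH_COLUMNS",
    "MORTALITY_COLUMNS",
    "read_growth_csv",
    "read_mortality_csv",
    "write_compatibility_csv",
    "write_fit_csv",
    "write_joint_toxicity_csv",
    "load_table3",
    "load_table4",
    "load_table5_reference",
    "run_report",
]

logger = logging.getLogger("mycosynergy")

GROWTH_COLUMNS = (
    "concentration",
    "germination_pct",
    "vegetative_growth_mm",
    "conidiation",
)
MORTALITY_COLUMNS = (
    "treatment",
    "component_a_conc",
    "component_b_conc",
    "total_conc",
    "time_d",
    "n_exposed",
    "mortality_pct",
)

#: Series labels of the sole components and schemes in the fixture set.
FIXTURE_TREATMENTS = (
    "pinene",
    "scheme_I",
    "scheme_II",
    "scheme_III",
    "scheme_IV",
    "conidia",
)


def _read_csv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    numeric = [c for c in columns if c != "treatment"]
    for col in numeric:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[converted.isna() & frame[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}"
            )
        if converted.isna().any():
            row = int(frame.index[converted.isna()][0]) + 2
            raise SchemaError(f"{path}: empty cell in column {col!r}, row {row}")
        frame[col] = converted
    return frame


def read_growth_csv(path) -> list[GrowthRecord]:
    """Read one growth assay; exactly one control row (concentration 0)."""
    frame = _read_csv(path, GROWTH_COLUMNS)
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                GrowthRecord(
                    concentration=float(row["concentration"]),
                    germination_pct=float(row["germination_pct"]),
                    vegetative_growth_mm=float(row["vegetative_growth_mm"]),
                    conidiation=float(row["conidiation"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    n_controls = sum(r.is_control for r in records)
    if n_controls != 1:
        raise DesignError(
            f"{path}: expected exactly one control row (concentration 0), "
            f"found {n_controls}"
        )
    return records


def read_mortality_csv(path, control_mortality_pct: float = 0.0) -> list[BioassaySeries]:
    """Read mortality data, assembling one series per treatment x time.

    Series order follows first appearance in the file; within a series
    groups are ordered by total concentration.
    """
    frame = _read_csv(path, MORTALITY_COLUMNS)
    series_list = []
    for (treatment, time_d), block in frame.groupby(
        ["treatment", "time_d"], sort=False
    ):
        groups = []
        components_a, components_b = [], []
        for idx, row in block.sort_values("total_conc").iterrows():
            try:
                groups.append(
                    DoseGroup(
                        concentration=float(row["total_conc"]),
                        mortality_pct=float(row["mortality_pct"]),
                        n_exposed=int(row["n_exposed"]),
                        time_d=float(time_d),
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
            components_a.append(float(row["component_a_conc"]))
            components_b.append(float(row["component_b_conc"]))
        components = []
        for name, ladder in (("a", components_a), ("b", components_b)):
            if any(c > 0 for c in ladder):
                share = sum(ladder) / (sum(components_a) + sum(components_b))
                components.append((name, share, tuple(ladder)))
        series_list.append(
            BioassaySeries(
                label=str(treatment),
                groups=tuple(groups),
                control_mortality_pct=control_mortality_pct,
                components=tuple(components),
            )
        )
    return series_list


def write_growth_csv(records: list[GrowthRecord], path):
    frame = pd.DataFrame(
        {
            "concentration": [r.concentration for r in records],
            "germination_pct": [r.germination_pct for r in records],
            "vegetative_growth_mm": [r.vegetative_growth_mm for r in records],
            "conidiation": [r.conidiation for r in records],
        }
    )
    frame.to_csv(path, index=False)
    return frame


def write_mortality_csv(series_list: list[BioassaySeries], path):
    rows = []
    for series in series_list:
        ladders = {name: ladder for name, _, ladder in series.components}
        for i, g in enumerate(series.groups):
            a = ladders.get("a", (0.0,) * len(series.groups))[i]
            b = ladders.get("b", (0.0,) * len(series.groups))[i]
            rows.append(
                {
                    "treatment": series.label,
                    "component_a_conc": a,
                    "component_b_conc": b,
                    "total_conc": g.concentration,
                    "time_d": g.time_d,
                    "n_exposed": g.n_exposed,
                    "mortality_pct": g.mortality_pct,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def write_compatibility_csv(results: list[CompatibilityResult], path, rounded=True):
    frame = pd.DataFrame(
        {
            "concentration": [r.concentration for r in results],
            "gr_rel": [r.gr_rel for r in results],
            "vg_rel": [r.vg_rel for r in results],
            "sp_rel": [r.sp_rel for r in results],
            "bi": [r.bi_rounded if rounded else r.bi for r in results],
            "bi_class": [str(r.bi_class) for r in results],
        }
    )
    frame.to_csv(path, index=False)
    return frame


def write_fit_csv(fits: list[tuple[str, ProbitFit, LC50Estimate]], path):
    frame = pd.DataFrame(
        {
            "treatment": [label for label, _, _ in fits],
            "slope": [f.slope for _, f, _ in fits],
            "intercept": [f.intercept for _, f, _ in fits],
            "lc50": [e.lc50 for _, _, e in fits],
            "lower": [e.lower for _, _, e in fits],
            "upper": [e.upper for _, _, e in fits],
            "chi2_het": [f.chi2_het for _, f, _ in fits],
            "df": [f.df for _, f, _ in fits],
            "method": [f.method for _, f, _ in fits],
        }
    )
    frame.to_csv(path, index=False)
    return frame


def write_joint_toxicity_csv(rows: list[dict], path):
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def _fixture_path(name: str):
    return resources.files("mycosynergy.fixtures") / name


def load_table3() -> list[GrowthRecord]:
    """Packaged growth-parameter means of the reference assay."""
    with resources.as_file(_fixture_path("table3.csv")) as p:
        return read_growth_csv(p)


def load_table4(time_d: float | None = None) -> list[BioassaySeries]:
    """Packaged cumulative-mortality blocks; optionally one time point."""
    with resources.as_file(_fixture_path("table4.csv")) as p:
        series = read_mortality_csv(p)
    if time_d is not None:
        series = [s for s in series if s.time_d == time_d]
    return series


def load_table5_reference() -> pd.DataFrame:
    """Published LC50s, fiducial ranges and joint-toxicity indices."""
    with resources.as_file(_fixture_path("table5_reference.csv")) as p:
        return pd.read_csv(p)


def run_report(
    outdir,
    growth_records: list[GrowthRecord] | None = None,
    mortality_series: list[BioassaySeries] | None = None,
    time_d: float = 4.0,
    method: str = "ml",
    variant: str = "paper",
) -> dict[str, Path]:
    """Run the full pipeline and write the three report CSVs.

    Defaults reproduce the reference study end to end from the packaged
    fixtures: compatibility report, LC50 table at 4 days, and the
    joint-toxicity table for schemes I-IV.  Active defaults are logged
    to standard error; report data go to files only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run_report defaults: time_d=%s, method=%s, additivity variant=%s, "
        "fixture mortalities treated as already corrected (control=0)",
        time_d,
        method,
        variant,
    )
    if growth_records is None:
        growth_records = load_table3()
    if mortality_series is None:
        mortality_series = load_table4()
    at_time = {s.label: s for s in mortality_series if s.time_d == time_d}
    missing = [t for t in ("pinene", "conidia") if t not in at_time]
    if missing:
        raise DesignError(
            f"mortality data lack sole-component series {missing} at {time_d} d"
        )

    paths = {}
    compat = compatibility_report(growth_records)
    paths["compatibility"] = outdir / "compatibility.csv"
    write_compatibility_csv(compat, paths["compatibility"])

    fitter = {"ml": fit_probit_ml, "ols": fit_probit_ols}[method]
    fits = []
    for label, series in at_time.items():
        fit = fitter(series)
        fits.append((label, fit, lc50_with_limits(fit)))
    paths["lc50"] = outdir / "lc50.csv"
    write_fit_csv(fits, paths["lc50"])

    joint_rows = []
    for roman, scheme in SCHEME_PRESETS.items():
        label = f"scheme_{roman}"
        if label not in at_time:
            continue
        result = joint_toxicity_pipeline(
            at_time["pinene"],
            at_time["conidia"],
            at_time[label],
            p_a=scheme.p_a,
            variant=variant,
            method=method,
        )
        joint_rows.append(
            {
                "scheme": roman,
                "p_a": scheme.p_a,
                "lc50_a": result.lc50_a,
                "lc50_b": result.lc50_b,
                "lc50_mix": result.lc50_mix,
                "expected_lc50": result.expected_lc50,
                "index": result.index_rounded,
                "classification": str(result.classification),
                "variant": variant,
            }
        )
    paths["joint_toxicity"] = outdir / "joint_toxicity.csv"
    write_joint_toxicity_csv(joint_rows, paths["joint_toxicity"])
    logger.info("report written to %s", outdir)
    return paths


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s: %(levelname)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
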