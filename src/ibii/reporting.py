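"""Robust statistical reductions of per-specimen results.

Biological test batches carry outliers (registration problems, grid
defects), so batch summaries use the median, the median absolute deviation
(MAD, the robust counterpart of the standard deviation) and a robust
coefficient of variation COV = 100 * MAD / |median|.  The module also ships
the published per-specimen results of the bovine cortical bone campaign
this package models (quasi-static dogbone tests and IBII tests, both
orientations, stiffness and failure stress), so the reductions and the
orthotropy cross-checks can be reproduced from the raw per-specimen values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStats",
    "median_mad_cov",
    "dynamic_amplification",
    "parse_specimen_id",
    "load_campaign_table",
    "summarize_columns",
    "campaign_summary",
]

CAMPAIGN_TABLES = (
    "qs_longitudinal",
    "qs_transverse",
    "ibii_longitudinal",
    "ibii_transverse",
    "failure_longitudinal",
    "failure_transverse",
)


@dataclass(frozen=True)
class SummaryStats:
    """Median / MAD / robust COV of a batch of per-specimen values."""

    median: float
    mad: float
    cov_pct: float
    n: int


def median_mad_cov(values) -> SummaryStats:
    """Robust batch summary.

    The median of an even count is the mean of the two central values; MAD
    is the median absolute deviation from the median; COV normalizes by
    |median| so a negative-valued series (e.g. signed strain rates) still
    yields a positive scatter percentage.  Missing entries must be dropped
    before the call.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("need at least one finite value")
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    cov = 100.0 * mad / abs(med) if med != 0 else np.inf if mad > 0 else 0.0
    return SummaryStats(median=med, mad=mad, cov_pct=cov, n=len(vals))


def dynamic_amplification(dynamic_value: float, quasistatic_value: float) -> float:
    """Relative difference between high-rate and quasi-static values, %."""
    if quasistatic_value == 0:
        raise ValueError("quasi-static value must be nonzero")
    return 100.0 * (dynamic_value - quasistatic_value) / quasistatic_value


_ID_RE = re.compile(
    r"^(?P<number>\d+)-C(?P<animal>[1-4])(?:-(?P<qs>QS))?-(?P<bone>[FT])-(?P<orientation>[LT])$"
)


def parse_specimen_id(spec_id: str) -> dict:
    """Parse a specimen name like ``12-C1-F-T`` or ``1-C1-QS-F-L``.

    Fields: specimen number, animal (C1-C4), femur/tibia, longitudinal or
    transverse orientation, and whether it is a quasi-static specimen.
    """
    m = _ID_RE.match(spec_id.strip())
    if not m:
        raise ValueError(f"specimen id {spec_id!r} does not match the naming convention")
    return {
        "number": int(m["number"]),
        "animal": f"C{m['animal']}",
        "bone": "femur" if m["bone"] == "F" else "tibia",
        "orientation": "longitudinal" if m["orientation"] == "L" else "transverse",
        "quasi_static": m["qs"] is not None,
    }


def load_campaign_table(name: str) -> pd.DataFrame:
    """Load one of the packaged per-specimen campaign tables."""
    if name not in CAMPAIGN_TABLES:
        raise KeyError(f"unknown table {name!r}; choose from {CAMPAIGN_TABLES}")
    with resources.files("ibii.data").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_columns(df: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Median / MAD / COV rows for the numeric columns of a specimen table,
    excluding missing entries per column."""
    if columns is None:
        columns = [c for c in df.columns if c != "specimen"]
    rows = {}
    for stat in ("median", "MAD", "COV_pct", "n"):
        rows[stat] = {}
    for c in columns:
        s = median_mad_cov(df[c].dropna().to_numpy())
        rows["median"][c] = s.median
        rows["MAD"][c] = s.mad
        rows["COV_pct"][c] = s.cov_pct
        rows["n"][c] = s.n
    return pd.DataFrame(rows).T[columns]


def campaign_summary() -> dict:
    """Cross-campaign elastic-constant comparison and rate amplification.

    Reduces the packaged per-specimen tables to the quasi-static and
    dynamic medians, averages the two dynamic identification routes
    (optimized virtual fields and stress-gauge) for the dominant
    stiffnesses, and computes the dynamic amplification percentages and the
    reciprocity-implied minor Poisson's ratios.
    """
    from .material import minor_poisson_from_reciprocity

    qs_l = load_campaign_table("qs_longitudinal")
    qs_t = load_campaign_table("qs_transverse")
    dy_l = load_campaign_table("ibii_longitudinal")
    dy_t = load_campaign_table("ibii_transverse")

    E11 = median_mad_cov(qs_l["E11_GPa"]).median
    nu12_qs = median_mad_cov(qs_l["nu12"]).median
    E22 = median_mad_cov(qs_t["E22_GPa"]).median
    nu21_qs = median_mad_cov(qs_t["nu21"]).median
    nu21_qs_recalc = minor_poisson_from_reciprocity(nu12_qs, E11, E22)
    # the QS stiffnesses use the *measured* Poisson medians
    q11_qs = E11 / (1.0 - nu12_qs * nu21_qs)
    q22_qs = E22 / (1.0 - nu12_qs * nu21_qs)

    q11_dyn = 0.5 * (
        median_mad_cov(dy_l["ovf_Q11_GPa"].dropna()).median
        + median_mad_cov(dy_l["sg_Q11_GPa"].dropna()).median
    )
    q22_dyn = 0.5 * (
        median_mad_cov(dy_t["ovf_Q22_GPa"].dropna()).median
        + median_mad_cov(dy_t["sg_Q22_GPa"].dropna()).median
    )
    nu12_dyn = median_mad_cov(dy_l["ovf_nu12"].dropna()).median
    nu21_dyn = 0.5 * (
        median_mad_cov(dy_l["ovf_nu21"].dropna()).median
        + median_mad_cov(dy_t["ovf_nu21"].dropna()).median
    )
    nu21_dyn_recalc = minor_poisson_from_reciprocity(nu12_dyn, q11_dyn, q22_dyn)

    return {
        "Q11_GPa": {"dynamic": q11_dyn, "quasi_static": round(q11_qs, 1),
                    "amplification_pct": dynamic_amplification(q11_dyn, round(q11_qs, 1))},
        "Q22_GPa": {"dynamic": q22_dyn, "quasi_static": round(q22_qs, 1),
                    "amplification_pct": dynamic_amplification(q22_dyn, round(q22_qs, 1))},
        "nu12": {"dynamic": nu12_dyn, "quasi_static": nu12_qs,
                 "amplification_pct": dynamic_amplification(nu12_dyn, nu12_qs)},
        "nu21": {"dynamic": nu21_dyn, "quasi_static": nu21_qs,
                 "amplification_pct": dynamic_amplification(nu21_dyn, nu21_qs)},
        "nu21_reciprocity": {"dynamic": nu21_dyn_recalc, "quasi_static": nu21_qs_recalc},
    }
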