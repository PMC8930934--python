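"""Paired group comparisons and central-slice surrogate correlations.

Progressor vs non-progressor meniscus measures are compared pairwise
(matched design): group mean ± SD, mean within-pair difference with 95%
CI, a paired t-test, and Cohen's D (pooled-SD two-group form) as effect
size.  Central-slice surrogate validity is quantified by Pearson's r
between measures from the entire meniscus and from the central (or central
five) coronal slices, with r² reported as integer percent variance
explained.

Tables are returned as raw-precision DataFrames; rounding (half away from
zero, 1 dp for measures, 2 dp for effect sizes and p, with a "< 0.01"
floor) is applied only by the formatting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import MeniscusMeasures

__all__ = [
    "StatsError",
    "PairedComparison",
    "CorrelationEntry",
    "cohens_d_pooled",
    "paired_t_test",
    "mean_diff_ci95",
    "pearson_r",
    "variance_explained_pct",
    "comparison_table",
    "correlation_table",
    "format_comparison_table",
    "format_correlation_table",
    "COMPARISON_ROWS",
    "CORRELATION_ROWS",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairedComparison:
    """One row of a paired case-control comparison table."""

    measure: str
    n_pairs: int
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    mean_diff: float
    ci95_low: float
    ci95_high: float
    cohens_d: float
    p_value: float


@dataclass(frozen=True)
class CorrelationEntry:
    """One entire-vs-central correlation: Pearson r and r² in percent."""

    comparison: str
    r: float
    r2_pct: int


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

def cohens_d_pooled(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's D with the pooled (root-mean-square) SD of the two groups.

    ``d = (mean1 − mean2) / sqrt((sd1² + sd2²) / 2)``.
    """
    if sd1 < 0 or sd2 < 0:
        raise StatsError("standard deviations must be >= 0")
    pooled = math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    if pooled == 0:
        raise StatsError("both SDs are zero; effect size undefined")
    return (mean1 - mean2) / pooled


def paired_t_test(diffs: Sequence[float]) -> tuple[float, int, float]:
    """Paired t-test on within-pair differences: (t, df, two-sided p)."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise StatsError("paired t-test needs n >= 2 differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise StatsError("zero-variance differences; t undefined")
    n = d.size
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, p


def mean_diff_ci95(diffs: Sequence[float]) -> tuple[float, float, float]:
    """Mean within-pair difference and its 95% CI: mean ± t(0.975, n−1)·SD/√n."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise StatsError("CI needs n >= 2 differences")
    n = d.size
    mean = float(np.mean(d))
    half = float(sps.t.ppf(0.975, n - 1)) * float(np.std(d, ddof=1)) / math.sqrt(n)
    return mean, mean - half, mean + half


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient (n ≥ 3, non-constant inputs)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise StatsError("x and y must have equal length")
    if xa.size < 3:
        raise StatsError("pearson_r needs n >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise StatsError("constant input; correlation undefined")
    return float(sps.pearsonr(xa, ya).statistic)


def variance_explained_pct(r: float) -> int:
    """round(100·r²) — the linear-regression variance explained in percent."""
    if abs(r) > 1:
        raise StatsError(f"|r| must be <= 1, got {r}")
    return int(_round_half_away(100.0 * r * r, 0))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

#: (measure field, display label) in canonical comparison-table order.
COMPARISON_ROWS: list[tuple[str, str]] = [
    ("extrusion_area_pct", "Extrusion area (%)"),
    ("mean_extrusion_mm", "Mean extrusion distance (mm)"),
    ("max_extrusion_mm", "Max. extrusion distance (mm)"),
    ("mean_extrusion_central5_mm", "Mean extrusion 5 central slices (mm)"),
    ("mean_extrusion_central1_mm", "Mean extrusion central slice (mm)"),
    ("coverage_pct", "Tibial plateau coverage (%)"),
    ("width_mean_mm", "Width mean total (mm)"),
    ("height_mean_mm", "Height mean (mm)"),
    ("volume_ml", "Volume (ml)"),
]

#: (measure field, central window, display label) for the surrogate table.
CORRELATION_ROWS: list[tuple[str, str, str]] = [
    ("mean_extrusion_mm", "central5", "Mean extrusion distance: entire vs. central 5 slices"),
    ("mean_extrusion_mm", "central1", "Mean extrusion distance: entire vs. central slice"),
    ("coverage_pct", "central5", "Tibia plateau coverage (%): entire vs. central 5 slices"),
    ("volume_ml", "central5", "Volume: entire vs. central 5 slices"),
    ("height_mean_mm", "central5", "Mean height: entire vs. central 5 slices"),
    ("width_mean_mm", "central5", "Mean width: entire vs. central 5 slices"),
]


def _measures_frame(measures) -> pd.DataFrame:
    """Accept a DataFrame or a sequence of MeniscusMeasures."""
    if isinstance(measures, pd.DataFrame):
        return measures
    rows = []
    for m in measures:
        if isinstance(m, MeniscusMeasures):
            rows.append(m.as_dict())
        else:
            rows.append(dict(m))
    return pd.DataFrame(rows)


def comparison_table(measures_cases, measures_controls) -> pd.DataFrame:
    """Paired case-control comparison, one row per measure.

    Inputs are pair-aligned sequences of :class:`MeniscusMeasures` (or
    DataFrames with the measure columns); row i of cases is matched to row
    i of controls.  Returns a raw-precision DataFrame with columns
    measure/label/n_pairs/mean_case/sd_case/mean_control/sd_control/
    mean_diff/ci95_low/ci95_high/cohens_d/p_value.
    """
    cases = _measures_frame(measures_cases)
    controls = _measures_frame(measures_controls)
    if len(cases) != len(controls):
        raise StatsError(
            f"unpaired inputs: {len(cases)} cases vs {len(controls)} controls"
        )
    rows = []
    for field, label in COMPARISON_ROWS:
        x = cases[field].to_numpy(dtype=float)
        y = controls[field].to_numpy(dtype=float)
        diffs = x - y
        mean_diff, lo, hi = mean_diff_ci95(diffs)
        _, _, p = paired_t_test(diffs)
        d = cohens_d_pooled(float(x.mean()), float(x.std(ddof=1)),
                            float(y.mean()), float(y.std(ddof=1)))
        rows.append({
            "measure": field,
            "label": label,
            "n_pairs": len(x),
            "mean_case": float(x.mean()),
            "sd_case": float(x.std(ddof=1)),
            "mean_control": float(y.mean()),
            "sd_control": float(y.std(ddof=1)),
            "mean_diff": mean_diff,
            "ci95_low": lo,
            "ci95_high": hi,
            "cohens_d": d,
            "p_value": p,
        })
    return pd.DataFrame(rows)


def correlation_table(entire_measures, central5_measures, central1_measures) -> pd.DataFrame:
    """Entire-vs-central correlations, one row per surrogate comparison.

    The three inputs are per-knee aligned sequences of measures computed
    from the entire meniscus, the central 5 slices and the central slice.
    """
    entire = _measures_frame(entire_measures)
    c5 = _measures_frame(central5_measures)
    c1 = _measures_frame(central1_measures)
    if not (len(entire) == len(c5) == len(c1)):
        raise StatsError(
            f"misaligned inputs: {len(entire)}/{len(c5)}/{len(c1)} knees"
        )
    central = {"central5": c5, "central1": c1}
    rows = []
    for field, window, label in CORRELATION_ROWS:
        r = pearson_r(entire[field], central[window][field])
        rows.append({
            "comparison": label,
            "measure": field,
            "window": window,
            "r": r,
            "r2_pct": variance_explained_pct(r),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presentation-layer rounding
# ---------------------------------------------------------------------------

def _round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (table typography), not banker's rounding."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _fmt(x: float, ndigits: int) -> str:
    return f"{_round_half_away(x, ndigits):.{ndigits}f}"


def format_p(p: float) -> str:
    """p to 2 dp with a '< 0.01' floor below 0.005."""
    if p < 0.005:
        return "< 0.01"
    return _fmt(p, 2)


def format_comparison_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display rendering: 1 dp measures, 2 dp Cohen's D, '< 0.01' p floor."""
    out = pd.DataFrame({
        "Measure": table["label"],
        "Mean cases": [_fmt(v, 1) for v in table["mean_case"]],
        "SD cases": [_fmt(v, 1) for v in table["sd_case"]],
        "Mean controls": [_fmt(v, 1) for v in table["mean_control"]],
        "SD controls": [_fmt(v, 1) for v in table["sd_control"]],
        "Mean diff": [_fmt(v, 1) for v in table["mean_diff"]],
        "95% CI": [
            f"{_fmt(lo, 1)}, {_fmt(hi, 1)}"
            for lo, hi in zip(table["ci95_low"], table["ci95_high"])
        ],
        "Cohen's D": [_fmt(v, 2) for v in table["cohens_d"]],
        "P": [format_p(v) for v in table["p_value"]],
    })
    return out


def format_correlation_table(table: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "Comparison": table["comparison"],
        "Pearson correlation (r)": [_fmt(v, 2) for v in table["r"]],
        "Linear regression (r2 %)": [str(int(v)) for v in table["r2_pct"]],
    })
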