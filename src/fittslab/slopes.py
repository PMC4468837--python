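"""Component-slope decomposition of the speed-accuracy trade-off.

A unitary Fitts account predicts one MT/ID slope regardless of whether
difficulty is manipulated through movement amplitude or target width.  The
decomposition here fits, per participant and session, four amplitude-component
slopes (MT vs ID across the four amplitudes, one per fixed width) and four
width-component slopes (across the four widths, one per fixed amplitude),
on either the nominal ID or the participant-specific effective ID (ID_We)
abscissa.  Distinct amplitude- and width-component slopes are the signature of
Welford's two-slope form MT = a*log2(A) + b*log2(1/W).

Slopes are fitted on condition-mean MT (the 10-trial cell means), matching the
cell structure the omnibus ANOVAs use.  Statistics downstream always use the
mean of per-participant slopes; the slope of group-mean points is also
available for plotting-style summaries, because the two are not the same
quantity when both axes vary per participant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SLOPE_COLUMNS = ["participant", "session", "basis", "component", "fixed_level",
                 "slope_ms_per_bit", "intercept_ms", "r_squared",
                 "average_id_bits"]

AMPLITUDE = "amplitude"
WIDTH = "width"


def fit_slope(points) -> tuple[float, float, float]:
    """Ordinary least squares on (ID, MT) pairs.

    Returns ``(slope ms/bit, intercept ms, r_squared)``.  Requires >= 2 points
    with non-degenerate abscissas.  A perfect fit to constant ordinates
    reports ``r_squared = 1.0`` (zero residual).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("fit_slope needs >= 2 (id, mt) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all ID values equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        r2 = 1.0 if ss_res <= 1e-12 else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return float(slope), float(intercept), r2


def component_slopes(summaries: pd.DataFrame, basis: str = "nominal") -> pd.DataFrame:
    """Fit all component slopes for every participant x session.

    Parameters
    ----------
    summaries
        The condition-summary table (one row per participant x session x
        amplitude x width) with ``mean_mt_ms``, ``id_nominal_bits`` and
        ``id_effective_bits`` columns.
    basis
        ``"nominal"`` uses the design ID; ``"effective"`` uses the
        participant-specific ID_We abscissas.

    Each record's ``average_id_bits`` is the mean of the four *nominal*
    abscissas (the difficulty-table margin for that row/column), which serves
    as the level of the Average-ID factor in the slopes ANOVA regardless of
    basis.  Participants missing grid cells are skipped with a logged reason;
    a record whose effective abscissa is degenerate (undefined ID_We) is
    skipped likewise.
    """
    if basis not in ("nominal", "effective"):
        raise ValueError("basis must be 'nominal' or 'effective'")
    id_col = "id_nominal_bits" if basis == "nominal" else "id_effective_bits"
    amplitudes = np.sort(summaries["amplitude_mm"].unique())
    widths = np.sort(summaries["width_mm"].unique())
    n_cells = len(amplitudes) * len(widths)
    records = []
    for (participant, session), grp in summaries.groupby(
            ["participant", "session"], sort=True):
        cell = grp.set_index(["amplitude_mm", "width_mm"])
        if len(cell) < n_cells:
            logger.warning("component_slopes: %s/%s has %d of %d cells; skipped",
                           participant, session, len(cell), n_cells)
            continue
        for component, fixed_levels, moving in (
                (AMPLITUDE, widths, amplitudes), (WIDTH, amplitudes, widths)):
            for fixed in fixed_levels:
                if component == AMPLITUDE:
                    sub = cell.loc[[(a, fixed) for a in moving]]
                else:
                    sub = cell.loc[[(fixed, w) for w in moving]]
                x = sub[id_col].to_numpy()
                y = sub["mean_mt_ms"].to_numpy()
                avg_id = float(sub["id_nominal_bits"].mean())
                if np.any(~np.isfinite(x)):
                    logger.warning(
                        "component_slopes: degenerate effective ID for %s/%s "
                        "%s=%g; record skipped", participant, session,
                        component, fixed)
                    continue
                slope, intercept, r2 = fit_slope(np.column_stack([x, y]))
                records.append({
                    "participant": participant, "session": session,
                    "basis": basis, "component": component,
                    "fixed_level": float(fixed),
                    "slope_ms_per_bit": slope, "intercept_ms": intercept,
                    "r_squared": r2, "average_id_bits": avg_id,
                })
    return pd.DataFrame(records, columns=SLOPE_COLUMNS)


def summarize_slopes(slope_records: pd.DataFrame,
                     by=("basis", "component")) -> pd.DataFrame:
    """Mean-of-slopes summary with a 95 % t confidence interval.

    Slopes are first averaged within participant (across sessions and fixed
    levels), then summarized across participants, so the CI reflects
    between-participant variability of the within-participant mean slope.
    """
    by = list(by)
    per_part = (slope_records.groupby(by + ["participant"])["slope_ms_per_bit"]
                .mean().reset_index())
    rows = []
    for key, grp in per_part.groupby(by, sort=True):
        v = grp["slope_ms_per_bit"].to_numpy()
        n = v.size
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if n > 1 else np.nan
        if n > 1:
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.nan
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(by, key)) | {
            "n": n, "mean_slope_ms_per_bit": mean, "sd": sd,
            "ci95_lo": lo, "ci95_hi": hi,
        })
    return pd.DataFrame(rows)


def slope_of_means(summaries: pd.DataFrame, basis: str = "nominal") -> pd.DataFrame:
    """Group-level slope of mean points (the plotted-regression construction).

    Collapses across participants and sessions: for each component, the four
    (mean ID, mean MT) points -- widths within amplitudes or amplitudes within
    widths -- are fitted by OLS.  Kept distinct from :func:`summarize_slopes`
    because the slope of means need not equal the mean of slopes.
    """
    id_col = "id_nominal_bits" if basis == "nominal" else "id_effective_bits"
    rows = []
    for component, level_col in ((AMPLITUDE, "amplitude_mm"), (WIDTH, "width_mm")):
        pts = (summaries.groupby(level_col)[[id_col, "mean_mt_ms"]]
               .mean().dropna())
        slope, intercept, r2 = fit_slope(pts.to_numpy())
        rows.append({"basis": basis, "component": component,
                     "slope_ms_per_bit": slope, "intercept_ms": intercept,
                     "r_squared": r2})
    return pd.DataFrame(rows)
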