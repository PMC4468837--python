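"""Fitts/Welford difficulty metrics and per-condition performance summaries.

Nominal difficulty is Fitts' index ``ID = log2(2A/W)`` (bits).  The effective
variant replaces the nominal width with the width the performer actually used,
``We = 4.13 * SD(endpoints)`` -- the 95 % span of the primary-axis endpoint
distribution -- giving ``ID_We = log2(2A/We)``.  Per participant x session x
condition cells this module computes mean movement time, constant error (CE:
mean signed endpoint bias, overshoot positive), variable error (VE: sample SD
of endpoints), We and both difficulty indices, plus per-session endpoint error
rates and the accuracy-/speed-prone strategy split.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .synthetic_data import ACCURACY_PRONE, SPEED_PRONE

logger = logging.getLogger(__name__)

#: Multiplier mapping an endpoint SD to the effective target width (the 95 %
#: confidence span of a normal endpoint distribution).
WE_MULTIPLIER = 4.13

#: Error-rate cutoff separating accuracy-prone from speed-prone performers.
STRATEGY_CUTOFF = 0.05

SUMMARY_KEYS = ["participant", "session", "amplitude_mm", "width_mm"]


def index_of_difficulty(amplitude, width_like):
    """Fitts' index of difficulty ``log2(2A/W)`` in bits.

    ``width_like`` may be the nominal target width or an effective width; both
    arguments broadcast and must be strictly positive.
    """
    a = np.asarray(amplitude, dtype=float)
    w = np.asarray(width_like, dtype=float)
    if np.any(a <= 0) or np.any(w <= 0):
        raise ValueError("amplitude and width must be strictly positive")
    out = np.log2(2.0 * a / w)
    return float(out) if out.ndim == 0 else out


def effective_width(endpoints) -> float:
    """Effective target width: 4.13 x the sample SD (n-1) of endpoints.

    Returns 0.0 for a degenerate (zero-spread) endpoint set; the caller treats
    the matching effective ID as undefined.
    """
    e = np.asarray(endpoints, dtype=float)
    if e.size < 2:
        raise ValueError("effective width requires at least 2 endpoints")
    return WE_MULTIPLIER * float(np.std(e, ddof=1))


def classify_error(endpoint, amplitude, width):
    """Endpoint-error flag: miss iff ``|endpoint - A| > W/2`` (primary axis).

    The target edge counts as a hit (closed interval).
    """
    e = np.asarray(endpoint, dtype=float)
    a = np.asarray(amplitude, dtype=float)
    w = np.asarray(width, dtype=float)
    if np.any(w <= 0):
        raise ValueError("width must be strictly positive")
    out = np.abs(e - a) > w / 2.0
    return bool(out) if out.ndim == 0 else out


def classify_strategy(rates, cutoff: float = STRATEGY_CUTOFF) -> str:
    """Strategy label from per-session error rates.

    Accuracy-prone iff the rate is at or below ``cutoff`` in *every* session;
    an error rate above the cutoff in either session makes the performer
    speed-prone.
    """
    r = np.asarray(list(rates), dtype=float)
    if r.size == 0 or np.any(np.isnan(r)):
        raise ValueError("one error rate per session is required")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("error rates must lie in [0, 1]")
    return ACCURACY_PRONE if np.all(r <= cutoff) else SPEED_PRONE


def target_area_utilization(endpoint_ellipse_area: float, width: float) -> float:
    """Percent of the circular target area covered by an endpoint ellipse.

    The reference area is the circle of diameter ``width``, pi * (W/2)^2.
    """
    if width <= 0:
        raise ValueError("width must be strictly positive")
    if endpoint_ellipse_area < 0:
        raise ValueError("area must be >= 0")
    return 100.0 * endpoint_ellipse_area / (np.pi * (width / 2.0) ** 2)


def condition_summary(endpoints, mt_ms, amplitude: float, width: float) -> dict:
    """Summarize one participant x session x condition cell.

    ``ce`` = mean(endpoint - amplitude); ``ve`` = sample SD of endpoints;
    ``we`` = 4.13 * ve; ``id_effective`` is NaN when ``we`` is degenerate.
    """
    e = np.asarray(endpoints, dtype=float)
    mt = np.asarray(mt_ms, dtype=float)
    if e.size == 0:
        raise ValueError("condition cell has no valid trials")
    we = effective_width(e) if e.size >= 2 else np.nan
    return {
        "n_valid": int(e.size),
        "mean_mt_ms": float(mt.mean()),
        "ce_mm": float(np.mean(e - amplitude)),
        "ve_mm": float(np.std(e, ddof=1)) if e.size >= 2 else np.nan,
        "we_mm": we,
        "id_nominal_bits": index_of_difficulty(amplitude, width),
        "id_effective_bits": (index_of_difficulty(amplitude, we)
                              if we and we > 0 else np.nan),
    }


def condition_summaries(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-cell summaries from a reduced-measures table.

    Invalid trials are dropped (their counts logged); a cell with no valid
    trials is omitted with a warning.
    """
    valid = measures[measures["valid"].astype(bool)]
    n_dropped = len(measures) - len(valid)
    if n_dropped:
        logger.warning("condition_summaries: dropped %d invalid trials", n_dropped)
    rows = []
    for key, grp in valid.groupby(SUMMARY_KEYS, sort=True):
        participant, session, a, w = key
        rows.append(dict(zip(SUMMARY_KEYS, key))
                    | condition_summary(grp["endpoint_mm"].to_numpy(),
                                        grp["mt_ms"].to_numpy(), a, w))
    return pd.DataFrame(rows)


def participant_profiles(measures: pd.DataFrame,
                         cutoff: float = STRATEGY_CUTOFF) -> pd.DataFrame:
    """Per-session endpoint error rates and the strategy label per participant.

    Error rates are computed over valid trials of the whole session (all
    conditions pooled).  Every participant must contribute to every session
    present in the table.
    """
    valid = measures[measures["valid"].astype(bool)].copy()
    valid["error"] = classify_error(valid["endpoint_mm"], valid["amplitude_mm"],
                                    valid["width_mm"])
    rates = (valid.groupby(["participant", "session"])["error"]
                  .mean().unstack("session"))
    if rates.isna().any().any():
        missing = rates[rates.isna().any(axis=1)].index.tolist()
        raise ValueError(f"participants missing a session: {missing}")
    out = rates.copy()
    out.columns = [f"error_rate_{c}" for c in rates.columns]
    out["strategy"] = [classify_strategy(row, cutoff)
                       for row in rates.to_numpy()]
    return out.reset_index()


# ---------------------------------------------------------------------------
# Difficulty grid (design-level, participant-free)


def id_grid(amplitudes, widths) -> pd.DataFrame:
    """Nominal-ID grid with marginal means: widths as rows, amplitudes as
    columns, plus a ``mean`` margin on each axis (exact values, unrounded)."""
    amplitudes = list(amplitudes)
    widths = list(widths)
    grid = pd.DataFrame(
        [[index_of_difficulty(a, w) for a in amplitudes] for w in widths],
        index=pd.Index(widths, name="width_mm"),
        columns=pd.Index(amplitudes, name="amplitude_mm"),
    )
    grid["mean"] = grid.mean(axis=1)
    grid.loc["mean"] = grid.mean(axis=0)
    return grid


def round_half_up(x, decimals: int = 2):
    """Decimal half-up rounding (3.225 -> 3.23), as printed tables round."""
    q = Decimal(10) ** -decimals

    def _one(v) -> float:
        # round through 10 decimals first so binary noise (3.2249999...996)
        # cannot defeat the half-up rule
        return float(Decimal(repr(round(float(v), 10)))
                     .quantize(q, rounding=ROUND_HALF_UP))

    if np.ndim(x) == 0:
        return _one(x)
    return np.vectorize(_one)(np.asarray(x, dtype=float))


def format_id_grid(grid: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Presentation form of :func:`id_grid`: cells rounded half-up, margins
    recomputed as means of the rounded cells (how published difficulty tables
    are typically assembled)."""
    cells = grid.drop(index="mean", columns="mean", errors="ignore")
    out = pd.DataFrame(round_half_up(cells.to_numpy(), decimals),
                       index=cells.index, columns=cells.columns)
    out["mean"] = round_half_up(out.mean(axis=1), decimals)
    out.loc["mean"] = round_half_up(out.mean(axis=0), decimals)
    return out
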