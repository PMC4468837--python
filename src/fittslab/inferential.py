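"""Repeated-measures inference: mixed ANOVA, sphericity handling, contrasts.

The central routine, :func:`rm_anova`, fits a fully-crossed within-subject
design (any number of within factors) with an optional single between-subjects
factor that may have unequal group sizes.  It uses the classical univariate
approach: the within-cell space is rotated onto orthonormal contrast blocks
(one block per within effect), each block is analysed as a small general
linear model over subjects, and sums of squares are pooled across the block's
columns.  This reproduces the textbook mixed-model F tests while making the
sphericity machinery natural -- the Greenhouse-Geisser epsilon and Mauchly's
test both come from the pooled covariance of a block's contrast scores.

Conventions
-----------
* Type III sums of squares for designs with a between factor (unweighted
  marginal means), the standard choice when group sizes differ; the
  within-subject part is balanced, where the types coincide.
* The Greenhouse-Geisser correction is always computed and reported next to
  the uncorrected p value; ``p_headline`` switches to the corrected value
  whenever Mauchly's test rejects sphericity at alpha = 0.05 (or cannot be
  computed).
* Effect sizes are generalized eta-squared: the denominator adds every
  subject-level error SS, plus the SS of effects involving *measured* (not
  manipulated) factors -- e.g. an observed strategy grouping -- so that the
  measure stays comparable across between- and within-subject designs.
* A zero-variance error term yields an undefined F (NaN), never infinity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ANOVA_COLUMNS = ["effect", "ss_effect", "ss_error", "df_num", "df_den",
                 "ms_effect", "ms_error", "F", "p", "gg_epsilon",
                 "df_num_gg", "df_den_gg", "p_gg", "mauchly_w", "mauchly_p",
                 "sphericity_violated", "p_headline", "eta_sq_gen"]


# ---------------------------------------------------------------------------
# Orthogonal polynomial contrasts


def poly_contrast_weights(levels, max_order: int | None = None) -> np.ndarray:
    """Orthogonal polynomial contrast weights for (possibly unequally spaced)
    factor levels.

    Gram-Schmidt orthogonalization of successive powers of the centered level
    values, normalized to unit length.  Row ``i`` (0-based) holds the weights
    of the order-``i+1`` (linear, quadratic, ...) contrast; every row sums to
    zero and rows are mutually orthogonal.  For equally spaced levels the
    rows reduce to the textbook integer patterns (up to scale).
    """
    x = np.asarray(levels, dtype=float)
    k = x.size
    if k < 2 or np.unique(x).size != k:
        raise ValueError("levels must be >= 2 distinct values")
    if max_order is None:
        max_order = k - 1
    if not 1 <= max_order < k:
        raise ValueError("max_order must satisfy 1 <= max_order < n_levels")
    powers = np.vander(x - x.mean(), N=max_order + 1, increasing=True)
    q, r = np.linalg.qr(powers)
    q = q * np.sign(np.diag(r))  # leading coefficient positive
    return q[:, 1:max_order + 1].T


ORDER_NAMES = {1: "linear", 2: "quadratic", 3: "cubic"}


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal columns spanning the contrast space (sum-zero).

    Any orthonormal basis yields identical pooled SS, epsilon and Mauchly W
    (all are rotation-invariant), so Helmert-style differences are used.
    """
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0 / i
        h[i - 1, i] = -1.0
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h.T


def _type3_block(Z: np.ndarray, X: np.ndarray, xtx_inv: np.ndarray,
                 group_cols: slice | None):
    """Type III SS of intercept / group-coefficients / residual for a block
    of contrast scores ``Z`` (n x d) under the subject-level model ``X``."""
    beta = xtx_inv @ X.T @ Z                    # (p, d)
    resid = Z - X @ beta
    ss_resid = float(np.sum(resid * resid))

    def _term(idx):
        b = beta[idx, :]                        # (q, d)
        v = np.linalg.inv(xtx_inv[np.ix_(idx, idx)])
        return float(np.sum(b * (v @ b)))

    ss_int = _term([0])
    ss_grp = _term(list(range(*group_cols.indices(X.shape[1])))) \
        if group_cols is not None else None
    return ss_int, ss_grp, ss_resid, resid


def _gg_epsilon(cov: np.ndarray) -> float:
    d = cov.shape[0]
    if d < 2:
        return 1.0
    tr = np.trace(cov)
    denom = d * float(np.sum(cov * cov))
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def mauchly_test(cov: np.ndarray, df_error: int) -> tuple[float, float]:
    """Mauchly's sphericity test on an orthonormal-contrast covariance.

    Returns ``(W, p)``; ``(nan, nan)`` when the statistic is undefined (one
    contrast dimension, or too few error df to estimate the covariance).
    """
    d = cov.shape[0]
    if d < 2 or df_error < d + 1:
        return np.nan, np.nan
    sign, logdet = np.linalg.slogdet(cov)
    tr = np.trace(cov)
    if sign <= 0 or tr <= 0:
        return 0.0, 0.0
    log_w = logdet - d * np.log(tr / d)
    w = float(np.exp(log_w))
    # Box's chi-square approximation with the second-order term (the form the
    # ez-style ANOVA implementations use).
    n1 = float(df_error)
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * n1)
    chi2 = -n1 * f * log_w
    k = d + 1
    w2 = ((d + 2.0) * (d - 1.0) * (d - 2.0)
          * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
          / (288.0 * (n1 * d * f) ** 2))
    df = d * (d + 1) // 2 - 1
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w, p


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str,
             between: str | None = None, observed=(),
             alpha: float = 0.05) -> pd.DataFrame:
    """Mixed-model repeated-measures ANOVA on per-subject cell means.

    Parameters
    ----------
    data
        Long-format table; duplicate rows per subject x cell are averaged into
        cell means first.
    dv, within, subject, between
        Column names: the dependent variable, the within-subject factor(s),
        the subject identifier, and (optionally) one between-subjects factor.
    observed
        Factor names that are measured rather than manipulated (e.g. an
        observed strategy grouping); affects generalized eta-squared only.

    Returns
    -------
    DataFrame
        One row per effect (between, within mains, and all interactions) with
        SS, df, F, p, Greenhouse-Geisser epsilon and corrected p, Mauchly's
        test, and generalized eta-squared.  ``attrs`` carries ``ss_total``
        and ``ss_subjects`` for conservation checks.

    Subjects with incomplete within-cells are excluded (logged); fewer than
    two subjects per group is an error.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not within:
        raise ValueError("at least one within factor is required")
    cols = [subject] + within + ([between] if between else []) + [dv]
    df = data[cols].copy()

    levels = [np.sort(df[w].unique()) for w in within]
    wide = df.pivot_table(index=subject, columns=within, values=dv,
                          aggfunc="mean")
    if len(within) == 1:
        full_cols = pd.Index(levels[0], name=within[0])
    else:
        full_cols = pd.MultiIndex.from_product(levels, names=within)
    wide = wide.reindex(columns=full_cols)
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("rm_anova: excluding %d subject(s) with incomplete "
                       "cells: %s", len(incomplete), list(incomplete))
        wide = wide.drop(index=incomplete)

    groups = None
    if between:
        gmap = df.drop_duplicates(subject).set_index(subject)[between]
        if df.groupby(subject)[between].nunique().max() > 1:
            raise ValueError("a subject appears in more than one group")
        gmap = gmap.reindex(wide.index)
        glevels = np.sort(gmap.unique())
        counts = gmap.value_counts()
        if (counts < 2).any() or len(glevels) < 2:
            raise ValueError("each between group needs >= 2 subjects")
        groups = np.searchsorted(glevels, gmap.to_numpy())
    elif wide.shape[0] < 2:
        raise ValueError("at least 2 subjects are required")

    table = _rm_anova_cells(wide.to_numpy(dtype=float),
                            {w: list(lv) for w, lv in zip(within, levels)},
                            groups=groups, between_name=between,
                            observed=observed, alpha=alpha)
    return table


def _rm_anova_cells(Y: np.ndarray, within_levels: dict, groups=None,
                    between_name: str | None = None, observed=(),
                    alpha: float = 0.05) -> pd.DataFrame:
    """Array fast path of :func:`rm_anova`.

    ``Y`` is (n_subjects x n_cells) of cell means; cells vary with the *last*
    within factor fastest (row-major over the level products).
    """
    within = list(within_levels)
    ks = [len(within_levels[w]) for w in within]
    n, C = Y.shape
    if C != int(np.prod(ks)):
        raise ValueError("cell count does not match within levels")
    if not np.all(np.isfinite(Y)):
        raise ValueError("cell means contain non-finite values")
    observed = set([observed] if isinstance(observed, str) else observed)

    if groups is not None:
        groups = np.asarray(groups)
        glevels = np.unique(groups)
        G = glevels.size
        # sum-to-zero (effect) coding for the group factor
        X = np.ones((n, G))
        for j, g in enumerate(glevels[:-1]):
            X[:, j + 1] = np.where(groups == g, 1.0,
                                   np.where(groups == glevels[-1], -1.0, 0.0))
        group_cols = slice(1, G)
    else:
        G = 1
        X = np.ones((n, 1))
        group_cols = None
    xtx_inv = np.linalg.inv(X.T @ X)
    df_err_units = n - G

    contrasts = {w: _orthonormal_contrasts(k) for w, k in zip(within, ks)}
    unit = {w: np.full((k, 1), 1.0 / np.sqrt(k)) for w, k in zip(within, ks)}

    # Between-subject stratum: uniform average over cells, scaled orthonormally
    mats = [unit[w] for w in within]
    u_all = mats[0]
    for m in mats[1:]:
        u_all = np.kron(u_all, m)
    z0 = (Y @ u_all)[:, 0]
    ss0_int, ss0_grp, ss0_resid, _ = _type3_block(z0[:, None], X, xtx_inv,
                                                  group_cols)
    ss_total = float(np.sum((Y - Y.mean()) ** 2))
    ss_subjects = ss0_resid

    rows = []
    error_terms = {"__subjects__": (ss0_resid, df_err_units)}

    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            mats = [contrasts[w] if w in combo else unit[w] for w in within]
            M = mats[0]
            for m in mats[1:]:
                M = np.kron(M, m)
            d = M.shape[1]
            Z = Y @ M
            ss_int, ss_grp, ss_resid, resid = _type3_block(Z, X, xtx_inv,
                                                           group_cols)
            df_den = d * df_err_units
            cov = resid.T @ resid / df_err_units
            eps = _gg_epsilon(cov)
            w_stat, w_p = mauchly_test(cov, df_err_units)
            error_terms[combo] = (ss_resid, df_den)
            rows.append(_effect_row(":".join(combo), combo, ss_int, d,
                                    ss_resid, df_den, eps, w_stat, w_p, alpha))
            if groups is not None:
                name = ":".join([between_name, *combo])
                rows.append(_effect_row(name, (between_name, *combo),
                                        ss_grp, d * (G - 1), ss_resid, df_den,
                                        eps, w_stat, w_p, alpha))

    if groups is not None:
        rows.insert(0, _effect_row(between_name, (between_name,), ss0_grp,
                                   G - 1, ss0_resid, df_err_units,
                                   np.nan, np.nan, np.nan, alpha,
                                   is_between=True))

    # generalized eta-squared
    sum_err = sum(ss for ss, _ in error_terms.values())
    obs_ss = {row["effect"]: row["ss_effect"] for row in rows
              if observed and set(row["_factors"]) & observed}
    sum_obs = sum(obs_ss.values())
    for row in rows:
        ssn = row["ss_effect"]
        denom = ssn + sum_err + sum_obs - obs_ss.get(row["effect"], 0.0)
        row["eta_sq_gen"] = 0.0 if denom <= 0 else max(0.0, ssn / denom)
        del row["_factors"]

    out = pd.DataFrame(rows, columns=ANOVA_COLUMNS)
    out.attrs["ss_total"] = ss_total
    out.attrs["ss_subjects"] = ss_subjects
    out.attrs["n_subjects"] = n
    out.attrs["n_groups"] = G
    return out


def _effect_row(name, factors, ss_eff, df_num, ss_err, df_den, eps,
                mauchly_w, mauchly_p, alpha, is_between=False) -> dict:
    ms_eff = ss_eff / df_num if df_num > 0 else np.nan
    ms_err = ss_err / df_den if df_den > 0 else np.nan
    if not np.isfinite(ms_err) or ms_err <= 0:
        f_val = p = p_gg = np.nan
    else:
        f_val = ms_eff / ms_err
        p = float(stats.f.sf(f_val, df_num, df_den))
        if is_between or not np.isfinite(eps):
            p_gg = p
        else:
            p_gg = float(stats.f.sf(f_val, df_num * eps, df_den * eps))
    if is_between:
        eps_out, dfn_gg, dfd_gg = np.nan, df_num, df_den
        violated = False
    else:
        eps_out = eps
        dfn_gg, dfd_gg = df_num * eps, df_den * eps
        # No computable Mauchly test -> be conservative and correct.
        violated = bool(np.isnan(mauchly_p) or mauchly_p < alpha)
    p_headline = p_gg if violated else p
    return {
        "effect": name, "_factors": tuple(factors),
        "ss_effect": ss_eff, "ss_error": ss_err,
        "df_num": df_num, "df_den": df_den,
        "ms_effect": ms_eff, "ms_error": ms_err,
        "F": f_val, "p": p, "gg_epsilon": eps_out,
        "df_num_gg": dfn_gg, "df_den_gg": dfd_gg, "p_gg": p_gg,
        "mauchly_w": mauchly_w, "mauchly_p": mauchly_p,
        "sphericity_violated": violated, "p_headline": p_headline,
        "eta_sq_gen": np.nan,
    }


# ---------------------------------------------------------------------------
# Single-df trend tests and Bonferroni adjustment


@dataclass
class ContrastResult:
    """A single-df polynomial trend test."""

    factor: str
    order: str
    weights: np.ndarray
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq_gen: float


def trend_test(level_means, weights, factor: str = "",
               order: int | str = 1) -> ContrastResult:
    """Test one polynomial trend across within-factor levels.

    ``level_means`` is (n_subjects x k): each subject's mean at each level.
    ``weights`` come from :func:`poly_contrast_weights` over the same levels.
    The error term is the between-subject variability of the contrast scores
    themselves (df = n - 1), the sphericity-robust choice for single-df
    within-subject contrasts.
    """
    Y = np.atleast_2d(np.asarray(level_means, dtype=float))
    w = np.asarray(weights, dtype=float)
    if Y.shape[1] != w.size:
        raise ValueError("weights length must match the number of levels")
    if Y.shape[0] < 2:
        raise ValueError("trend_test needs >= 2 subjects")
    scores = Y @ w
    n = scores.size
    ss_num = n * float(scores.mean()) ** 2
    ss_err = float(((scores - scores.mean()) ** 2).sum())
    if ss_err <= 0:
        f_val = np.nan if ss_num > 0 else 0.0
        p = np.nan if ss_num > 0 else 1.0
    else:
        f_val = ss_num / (ss_err / (n - 1))
        p = float(stats.f.sf(f_val, 1, n - 1))
    denom = ss_num + ss_err
    ges = 0.0 if denom <= 0 else ss_num / denom
    order_name = ORDER_NAMES.get(order, str(order)) if isinstance(order, int) \
        else order
    return ContrastResult(factor, order_name, w, f_val, 1, n - 1, p, ges)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjusted p values: ``min(1, p * m)``.

    ``m`` defaults to the family size (the number of p values given).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Reporting


def format_anova(table: pd.DataFrame, title: str = "") -> str:
    """Human-readable ANOVA report; corrected dfs shown to one decimal."""
    lines = []
    if title:
        lines += [title, "-" * len(title)]
    for _, r in table.iterrows():
        if r["sphericity_violated"] and np.isfinite(r["gg_epsilon"]):
            dfs = f"({r['df_num_gg']:.1f}, {r['df_den_gg']:.1f})"
            p = r["p_gg"]
            tag = " [GG]"
        else:
            dfs = f"({r['df_num']:g}, {r['df_den']:g})"
            p = r["p"]
            tag = ""
        if np.isfinite(r["F"]):
            lines.append(
                f"{r['effect']:<40s} F{dfs} = {r['F']:.2f}, "
                f"p = {p:.3f}{tag}, ges = {r['eta_sq_gen']:.3f}")
        else:
            lines.append(f"{r['effect']:<40s} F not applicable "
                         "(zero-variance error term)")
    return "\n".join(lines)
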