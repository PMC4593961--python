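"""Repeated-measures condition contrasts.

Implements the univariate within-subject ANOVA for fully-crossed,
balanced designs with one to three within-subject factors, with
Mauchly's sphericity test and the Greenhouse-Geisser degrees-of-freedom
correction applied per effect when sphericity is rejected, plus Tukey
pairwise comparisons via the studentized-range distribution.

Each within-subject effect is tested against its own subject-by-effect
interaction (the standard univariate repeated-measures error term).
Sums of squares are computed by Moebius inversion over marginal means,
which is exact for balanced complete designs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2, f as f_dist, studentized_range, ttest_rel

from .exceptions import InsufficientDataError, InvalidDesignError, InvalidInputError

__all__ = ["rm_anova", "tukey_pairwise", "cell_contrast"]


def _pivot_balanced(
    table: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> tuple[np.ndarray, list[list]]:
    """Reshape a long table to a (subjects, l1, ..., lk) array.

    Requires exactly one observation per subject x cell (balanced,
    complete design).
    """
    for col in [dv, subject, *within]:
        if col not in table.columns:
            raise InvalidInputError(f"table lacks required column {col!r}")
    counts = table.groupby([subject, *within], observed=True, sort=True).size()
    if counts.empty:
        raise InvalidDesignError("empty table")
    subjects = sorted(table[subject].unique())
    levels = [sorted(table[f].unique()) for f in within]
    expected = len(subjects) * int(np.prod([len(lv) for lv in levels]))
    if len(counts) != expected or (counts != 1).any():
        raise InvalidDesignError(
            "design must be balanced and complete with exactly one observation "
            "per subject x condition cell (average repetitions first)"
        )
    wide = table.set_index([subject, *within])[dv].sort_index()
    shape = (len(subjects), *[len(lv) for lv in levels])
    return wide.to_numpy(dtype=float).reshape(shape), levels


def _effect_ss(y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Sum of squares of the factorial effect spanned by ``axes``.

    Moebius inversion: the effect estimate in each full-design cell is
    the alternating sum of marginal means over all subsets of ``axes``;
    summing its square over the full array yields the effect SS.
    """
    all_axes = tuple(range(y.ndim))
    eff = np.zeros_like(y)
    for r in range(len(axes) + 1):
        for subset in combinations(axes, r):
            mean_axes = tuple(a for a in all_axes if a not in subset)
            marg = y.mean(axis=mean_axes, keepdims=True) if mean_axes else y
            eff = eff + ((-1) ** (len(axes) - r)) * marg
    return float(np.sum(np.square(eff)))


def _orthonormal_contrasts(m: int) -> np.ndarray:
    """(m-1) x m orthonormal basis orthogonal to the unit vector."""
    return linalg.null_space(np.ones((1, m))).T


def _sphericity(y: np.ndarray, effect_axes: tuple[int, ...]) -> tuple[float, float, float]:
    """Mauchly's W, its p-value, and the Greenhouse-Geisser epsilon.

    The per-subject scores for the effect are collapsed over the
    remaining factors, transformed by the Kronecker product of
    orthonormal factor contrasts, and the covariance of the transformed
    scores is tested for proportionality to the identity.
    """
    n_subj = y.shape[0]
    other = tuple(a for a in range(1, y.ndim) if a not in effect_axes)
    collapsed = y.mean(axis=other) if other else y
    collapsed = collapsed.reshape(n_subj, -1)
    contrast = np.array([[1.0]])
    for ax in sorted(effect_axes):
        contrast = np.kron(contrast, _orthonormal_contrasts(y.shape[ax]))
    z = collapsed @ contrast.T
    k = z.shape[1]
    cov = np.cov(z, rowvar=False)
    cov = np.atleast_2d(cov)
    tr = float(np.trace(cov))
    tr2 = float(np.trace(cov @ cov))
    eps = tr**2 / (k * tr2) if tr2 > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / k, 1.0))
    # Mauchly's test needs more subjects than contrast dimensions for a
    # non-singular covariance; otherwise report W as NaN (no test).
    det = float(np.linalg.det(cov))
    if n_subj - 1 < k or det <= 0 or tr <= 0:
        return float("nan"), float("nan"), eps
    w = det / (tr / k) ** k
    # chi-square approximation with the second-order term (as in ezANOVA)
    d = 1.0 - (2 * k**2 + k + 2) / (6.0 * k * (n_subj - 1))
    w2 = (
        (k + 2)
        * (k - 1)
        * (k - 2)
        * (2 * k**3 + 6 * k**2 + 3 * (k + 1) + 2)
        / (288.0 * ((n_subj - 1) * k * d) ** 2)
    )
    stat = -(n_subj - 1) * d * np.log(w)
    dof = k * (k + 1) / 2.0 - 1.0
    p1 = float(chi2.sf(stat, dof))
    p2 = float(chi2.sf(stat, dof + 4))
    p = p1 + w2 * (p2 - p1)
    return float(w), p, eps


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    alpha: float = 0.05,
    correction: str = "auto",
) -> pd.DataFrame:
    """Within-subject ANOVA over a balanced subjects x conditions table.

    Parameters
    ----------
    table
        Long-format table with one row per subject x condition cell.
    dv, subject, within
        Column names of the response, the subject id, and the one to
        three within-subject factors.
    alpha
        Significance level of Mauchly's test used to trigger the
        Greenhouse-Geisser correction.
    correction
        ``"auto"`` (correct when Mauchly's test is significant,
        default), ``"always"``, or ``"never"``.

    Returns
    -------
    DataFrame
        One row per main effect and interaction with columns
        ``effect, F, df1, df2, eps, mauchly_W, p_sphericity, p_unc, p,
        gg_applied``.  ``df1``/``df2`` are the uncorrected degrees of
        freedom; when ``gg_applied`` is true, ``p`` is evaluated at
        ``eps * df1`` and ``eps * df2``.
    """
    if not 1 <= len(within) <= 3:
        raise InvalidInputError("between one and three within-subject factors are supported")
    if correction not in ("auto", "always", "never"):
        raise InvalidInputError(f"unknown correction policy {correction!r}")
    y, levels = _pivot_balanced(table, dv, subject, within)
    n_subj = y.shape[0]
    if n_subj < 2:
        raise InsufficientDataError("repeated-measures ANOVA needs at least two subjects")
    for name, lv in zip(within, levels):
        if len(lv) < 2:
            raise InvalidDesignError(f"factor {name!r} has fewer than two levels")

    rows = []
    factor_axes = list(range(1, y.ndim))
    for r in range(1, len(factor_axes) + 1):
        for axes in combinations(factor_axes, r):
            names = [within[a - 1] for a in axes]
            ss_effect = _effect_ss(y, axes)
            ss_error = _effect_ss(y, (0, *axes))
            df1 = int(np.prod([y.shape[a] - 1 for a in axes]))
            df2 = (n_subj - 1) * df1
            ms_effect = ss_effect / df1
            ms_error = ss_error / df2
            if ss_effect == 0.0:
                f_val = 0.0
            elif ms_error == 0.0:
                f_val = float("inf")
            else:
                f_val = ms_effect / ms_error
            p_unc = float(f_dist.sf(f_val, df1, df2)) if np.isfinite(f_val) else 0.0
            if df1 > 1:
                w, p_spher, eps = _sphericity(y, axes)
            else:
                w, p_spher, eps = float("nan"), float("nan"), 1.0
            apply_gg = correction == "always" or (
                correction == "auto" and np.isfinite(p_spher) and p_spher < alpha
            )
            apply_gg = apply_gg and df1 > 1
            if apply_gg and np.isfinite(f_val):
                p_val = float(f_dist.sf(f_val, eps * df1, eps * df2))
            else:
                p_val = p_unc
            rows.append(
                {
                    "effect": ":".join(names),
                    "F": f_val,
                    "df1": df1,
                    "df2": df2,
                    "eps": eps,
                    "mauchly_W": w,
                    "p_sphericity": p_spher,
                    "p_unc": p_unc,
                    "p": p_val,
                    "gg_applied": bool(apply_gg),
                }
            )
    return pd.DataFrame(rows)


def tukey_pairwise(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    factor: str,
) -> pd.DataFrame:
    """All pairwise level comparisons with Tukey's correction.

    Data are first collapsed to per-subject level means (averaging over
    any other factors); the error term is the subject x factor
    interaction mean square of the resulting one-way repeated-measures
    design, and adjusted p-values come from the studentized-range
    distribution.

    Returns
    -------
    DataFrame
        Columns ``level_a, level_b, mean_diff, se, q, p_adj``.
    """
    for col in (dv, subject, factor):
        if col not in table.columns:
            raise InvalidInputError(f"table lacks required column {col!r}")
    x = table.groupby([subject, factor], observed=True, sort=True)[dv].mean().unstack(factor)
    if x.isna().any().any():
        raise InvalidDesignError("every subject must have every level of the factor")
    levels = list(x.columns)
    n_levels = len(levels)
    if n_levels < 2:
        raise InvalidInputError(f"factor {factor!r} is degenerate (fewer than two levels)")
    n_subj = x.shape[0]
    if n_subj < 2:
        raise InsufficientDataError("pairwise comparisons need at least two subjects")
    y = x.to_numpy(dtype=float)
    ss_error = _effect_ss(y, (0, 1))
    df_error = (n_subj - 1) * (n_levels - 1)
    ms_error = ss_error / df_error
    se_mean = np.sqrt(ms_error / n_subj)
    means = y.mean(axis=0)
    rows = []
    for i, j in combinations(range(n_levels), 2):
        diff = means[i] - means[j]
        if se_mean > 0:
            q = abs(diff) / se_mean
            p_adj = float(studentized_range.sf(q, n_levels, df_error))
        else:
            q = float("inf") if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "mean_diff": float(diff),
                "se": float(np.sqrt(2.0) * se_mean),
                "q": float(q),
                "p_adj": min(p_adj, 1.0),
            }
        )
    return pd.DataFrame(rows)


def cell_contrast(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    cell_a: dict,
    cell_b: dict,
) -> dict:
    """Paired contrast between two arbitrary condition cells.

    Each cell is selected by a ``{column: value}`` mapping; values are
    averaged per subject within each cell and compared with a paired
    t-test.  This is a generic simple-effects facility for follow-up
    questions the omnibus table does not answer directly.
    """

    def _select(spec: dict) -> pd.Series:
        mask = pd.Series(True, index=table.index)
        for col, val in spec.items():
            if col not in table.columns:
                raise InvalidInputError(f"table lacks column {col!r}")
            mask &= table[col] == val
        sel = table[mask].groupby(subject, observed=True, sort=True)[dv].mean()
        if sel.empty:
            raise InvalidInputError(f"no rows match cell {spec!r}")
        return sel

    a, b = _select(cell_a), _select(cell_b)
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise InsufficientDataError("paired contrast needs at least two common subjects")
    res = ttest_rel(a.loc[common], b.loc[common])
    return {
        "mean_diff": float((a.loc[common] - b.loc[common]).mean()),
        "t": float(res.statistic),
        "df": int(len(common) - 1),
        "p": float(res.pvalue),
        "n": int(len(common)),
    }
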