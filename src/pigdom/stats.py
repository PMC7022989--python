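"""Statistical panel relating hierarchy indices to dyadic behavior:
index inter-correlations, partial correlations, multiple regression of
the six log-transformed behavior indicators on each index, and the sex
contrast on time to social stability.

Conventions: I&SI enters as integer rank (1 = most dominant), so its
correlations with the cardinal ratings are negative; |r| is reported
alongside the signed coefficient.  Raw p-values are reported with no
multiple-testing correction, judged at 0.05 (significant) and 0.1
(tendency).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "index_correlations",
    "partial_correlation",
    "multiple_regression",
    "sex_contrast",
    "SexContrastResult",
    "BEHAVIOR_COVARIATES",
]

#: log-transformed dyadic indicators used as regression covariates
BEHAVIOR_COVARIATES = ["lgDAA", "lgDSO", "lgDBB", "lgFAA", "lgFSO", "lgFBB"]


def index_correlations(index_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between hierarchy indices.

    ``index_table`` holds one column per index (e.g. ``isi_rank``,
    ``elo``, ``glicko``) over the pooled animals.  Returns columns
    index_a, index_b, rho, abs_rho, p_value.
    """
    rows = []
    for a, b in combinations(index_table.columns, 2):
        rho, p = stats.spearmanr(index_table[a], index_table[b])
        rows.append(
            {"index_a": a, "index_b": b, "rho": rho, "abs_rho": abs(rho),
             "p_value": p}
        )
    return pd.DataFrame(rows, columns=["index_a", "index_b", "rho", "abs_rho", "p_value"])


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    Z: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for Z.

    Both variables are projected on [1, Z] by least squares and the
    residuals correlated; with an empty covariate set this reduces to the
    plain Pearson correlation.  The p-value comes from the t distribution
    with n - k - 2 degrees of freedom (k covariates).

    Raises on a singular covariate matrix, naming the collinear columns;
    returns (nan, nan) when either residual vector is (numerically) zero,
    e.g. when y is itself a linear combination of the covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if Z is None or (hasattr(Z, "shape") and np.size(Z) == 0):
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        names = list(Z.columns) if isinstance(Z, pd.DataFrame) else None
        Zm = np.column_stack([np.ones(n), np.asarray(Z, dtype=float)])
        k = Zm.shape[1] - 1
        if np.linalg.matrix_rank(Zm) < Zm.shape[1]:
            raise ValueError(
                "singular covariate matrix"
                + (f" (columns: {names})" if names else "")
            )
        coef_x, *_ = np.linalg.lstsq(Zm, x, rcond=None)
        coef_y, *_ = np.linalg.lstsq(Zm, y, rcond=None)
        rx, ry = x - Zm @ coef_x, y - Zm @ coef_y
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if np.linalg.norm(rx) < 1e-10 * scale or np.linalg.norm(ry) < 1e-10 * scale:
        return float("nan"), float("nan")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r = max(-1.0, min(1.0, r))
    dof = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(p)


def multiple_regression(
    summary: pd.DataFrame,
    response: str,
    covariates: Sequence[str] = tuple(BEHAVIOR_COVARIATES),
) -> pd.DataFrame:
    """OLS of a hierarchy index on the log dyadic behavior indicators.

    ``summary`` must contain the response column and the covariate
    columns; incomplete cases are dropped.  Returns one row per covariate
    with the unstandardized coefficient B, its SE, t and p, plus the
    intercept row, with ``n`` attached in ``DataFrame.attrs``.
    """
    cols = [response, *covariates]
    data = summary[cols].dropna()
    n = len(data)
    if n <= len(covariates) + 1:
        raise ValueError(
            f"n = {n} too small to fit {len(covariates)} covariates"
        )
    X = sm.add_constant(data[list(covariates)])
    fit = sm.OLS(data[response], X).fit()
    out = pd.DataFrame(
        {"B": fit.params, "SE": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    out.index.name = "covariate"
    out.attrs["n"] = n
    out.attrs["response"] = response
    return out


@dataclass(frozen=True)
class SexContrastResult:
    """Adjusted (covariate-standardised) sex means of stability time."""

    mean_female: float
    se_female: float
    mean_barrow: float
    se_barrow: float
    diff: float          # barrow - female
    se_diff: float
    p_value: float
    n: int


def _sex_design(data: pd.DataFrame, with_covariates: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data)), (data["sex"] == "barrow").astype(float).to_numpy()]
    names = ["intercept", "sex_barrow"]
    if with_covariates:
        cols.append(data["parity"].astype(float).to_numpy())
        names.append("parity")
        cols.append(data["initial_bw_kg"].astype(float).to_numpy())
        names.append("initial_bw_kg")
        cols.append(cols[1] * cols[3])
        names.append("sex_barrow:initial_bw_kg")
        sires = sorted(data["sire_id"].unique())[1:]  # first level is reference
        for s in sires:
            cols.append((data["sire_id"] == s).astype(float).to_numpy())
            names.append(f"sire[{s}]")
    return np.column_stack(cols), names


def sex_contrast(
    stability: pd.DataFrame, with_covariates: bool = True
) -> SexContrastResult:
    """Sex contrast on time to social stability via fixed-effects OLS.

    The model regresses stability hours on sex, parity, sire, initial
    body weight and the sex x body-weight interaction (all fixed
    effects); ``with_covariates=False`` fits sex alone, which reduces the
    contrast to a pooled two-sample t test.  Adjusted sex means are
    g-computation averages — every animal's prediction with sex forced to
    each level, averaged — with delta-method standard errors, and the
    p-value tests their difference.
    """
    required = {"stability_h", "sex"}
    if with_covariates:
        required |= {"parity", "sire_id", "initial_bw_kg"}
    missing = required - set(stability.columns)
    if missing:
        raise ValueError(f"stability table lacks column(s) {sorted(missing)}")
    data = stability.dropna(subset=sorted(required)).copy()
    sexes = set(data["sex"])
    if sexes != {"female", "barrow"}:
        raise ValueError("sex contrast needs both sexes present")
    X, names = _sex_design(data, with_covariates)
    y = data["stability_h"].astype(float).to_numpy()
    fit = sm.OLS(y, X).fit()
    cov = fit.cov_params()

    def level_row(sex: str) -> np.ndarray:
        forced = data.copy()
        forced["sex"] = sex
        Xf, _ = _sex_design(forced, with_covariates)
        return Xf.mean(axis=0)

    l_f, l_b = level_row("female"), level_row("barrow")
    mean_f = float(l_f @ fit.params)
    mean_b = float(l_b @ fit.params)
    se_f = float(np.sqrt(l_f @ cov @ l_f))
    se_b = float(np.sqrt(l_b @ cov @ l_b))
    l_d = l_b - l_f
    diff = float(l_d @ fit.params)
    se_d = float(np.sqrt(l_d @ cov @ l_d))
    if se_d > 0:
        p = float(2.0 * stats.t.sf(abs(diff / se_d), fit.df_resid))
    else:  # degenerate zero-residual fit: no basis for a test
        p = float("nan")
    return SexContrastResult(
        mean_female=mean_f, se_female=se_f,
        mean_barrow=mean_b, se_barrow=se_b,
        diff=diff, se_diff=se_d, p_value=p, n=len(data),
    )
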