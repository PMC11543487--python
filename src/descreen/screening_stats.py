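"""Tie-corrected Spearman correlation screening and QSAR input selection.

Screening tables mix monotone but nonlinear relationships (viscosity vs
water content, stability vs viscosity), so rank correlation is the
appropriate screen. The estimator is Pearson's r on average (mid-) ranks,
which handles the many tied viscosities/densities correctly; significance
uses the two-sided t approximation t = rho*sqrt((n-2)/(1-rho^2)) with no
multiple-testing correction. Variables significantly correlated with a
modelling target become that target's QSAR inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

__all__ = ["CorrelationMatrix", "spearman_matrix", "select_inputs"]


@dataclass
class CorrelationMatrix:
    """Spearman rho, p-values and significance flags for named variables."""

    variables: list[str]
    rho: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    n: pd.DataFrame          # pairwise-complete sample sizes
    alpha: float

    def pair(self, a: str, b: str) -> float:
        return float(self.rho.loc[a, b])


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """rho, two-sided p and n for one pairwise-complete pair."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        return math.nan, math.nan, n
    xr = rankdata(x[ok], method="average")
    yr = rankdata(y[ok], method="average")
    sx, sy = xr.std(), yr.std()
    if sx == 0 or sy == 0:
        return math.nan, math.nan, n
    rho = float(np.mean((xr - xr.mean()) * (yr - yr.mean())) / (sx * sy))
    rho = max(min(rho, 1.0), -1.0)
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(t_dist.sf(abs(t_stat), df=n - 2))
    return rho, p, n


def spearman_matrix(table: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """Tie-corrected Spearman correlation matrix with significance flags.

    Missing cells are handled pairwise-complete; constant columns yield NaN
    for their pairs with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    num = table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    if not cols:
        raise ValueError("no numeric columns")
    k = len(cols)
    rho = np.eye(k)
    pv = np.zeros((k, k))
    nn = np.full((k, k), len(num))
    for i in range(k):
        nn[i, i] = int(np.isfinite(num[cols[i]].to_numpy()).sum())
        for j in range(i + 1, k):
            r, p, n = _spearman_pair(num[cols[i]].to_numpy(float), num[cols[j]].to_numpy(float))
            if math.isnan(r):
                warnings.warn(
                    f"rho undefined for pair ({cols[i]}, {cols[j]}): "
                    "constant column or too few complete rows",
                    stacklevel=2,
                )
            rho[i, j] = rho[j, i] = r
            pv[i, j] = pv[j, i] = p
            nn[i, j] = nn[j, i] = n
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pv, index=cols, columns=cols)
    sig = (p_df < alpha) & np.isfinite(rho_df)
    np.fill_diagonal(sig.values, False)
    return CorrelationMatrix(
        variables=cols,
        rho=rho_df,
        p_values=p_df,
        significant=sig,
        n=pd.DataFrame(nn, index=cols, columns=cols),
        alpha=alpha,
    )


def select_inputs(matrix: CorrelationMatrix, target: str) -> list[str]:
    """Variables whose correlation with ``target`` is significant at the
    matrix's alpha, in the table's column order."""
    if target not in matrix.variables:
        raise KeyError(f"unknown target variable {target!r}")
    return [
        v
        for v in matrix.variables
        if v != target and bool(matrix.significant.loc[target, v])
    ]
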