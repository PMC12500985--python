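"""Pearson correlation matrices with two-tailed significance stars.

p-values use the exact t reference distribution,
``t = r·√((n−2)/(1−r²))`` with ``df = n−2`` — appropriate for the small
panels this package targets.  Pairs involving a constant variable get an
undefined (NaN) correlation and are flagged rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = ["CorrelationResult", "pearson_matrix"]

STAR_THRESHOLDS = ((0.01, "**"), (0.05, "*"))


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int
    undefined: list[str]  # constant variables whose pairs are undefined

    def annotated(self, decimals: int = 3) -> pd.DataFrame:
        """Lower-triangle display matrix: '0.548**' style strings."""
        vars_ = list(self.r.columns)
        out = pd.DataFrame("", index=vars_, columns=vars_)
        for i, a in enumerate(vars_):
            for j, b in enumerate(vars_):
                if j > i:
                    continue
                val = self.r.loc[a, b]
                if np.isnan(val):
                    out.loc[a, b] = "nan"
                else:
                    out.loc[a, b] = f"{val:.{decimals}f}{self.stars.loc[a, b]}"
        return out

    def to_csv(self, path: str | Path, decimals: int = 3) -> None:
        self.annotated(decimals).to_csv(path, index_label="Trait")


def _star(p: float) -> str:
    if np.isnan(p):
        return ""
    for thr, mark in STAR_THRESHOLDS:
        if p < thr:
            return mark
    return ""


def pearson_matrix(X: pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson r, two-tailed p and star annotations."""
    arr = X.to_numpy(dtype=float)
    n, p_vars = arr.shape
    if n < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {n}")
    names = [str(c) for c in X.columns]

    sd = arr.std(axis=0, ddof=1)
    undefined = [names[i] for i in np.flatnonzero(sd == 0)]

    centered = arr - arr.mean(axis=0)
    cov = centered.T @ centered
    denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    r = np.clip(r, -1.0, 1.0)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))

    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    pmat = 2.0 * stats.t.sf(np.abs(t), df=df)
    pmat = np.where(np.abs(r) >= 1.0, 0.0, pmat)  # exact fits: t -> inf
    pmat = np.where(np.isnan(r), np.nan, pmat)
    np.fill_diagonal(pmat, np.where(sd == 0, np.nan, 0.0))

    r_df = pd.DataFrame(r, index=names, columns=names)
    p_df = pd.DataFrame(pmat, index=names, columns=names)
    stars = p_df.map(_star)
    stars.values[np.diag_indices(p_vars)] = ""
    return CorrelationResult(r_df, p_df, stars, n, undefined)
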