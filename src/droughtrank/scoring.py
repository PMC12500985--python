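"""Eigenvalue weights, composite F score, D values and genotype ranking.

The comprehensive score of a genotype is
``D = Σ_j μ(F_j) · W_j``
where μ is the positive-direction membership transform of each retained
component-score column across genotypes (a higher component score always
counts toward resistance) and W_j is the eigenvalue-proportion weight.

Two weight denominators exist in the wild and are both supported:
``total_variance`` divides λ_j by the total variance p (the full eigenvalue
count), ``extracted_sum`` divides by the sum of the retained eigenvalues so
the weights add to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .membership import membership_transform

__all__ = ["ScoreTable", "component_weights", "composite_f", "d_values"]

WEIGHT_DENOMINATORS = ("total_variance", "extracted_sum")


def component_weights(
    eigenvalues: Sequence[float] | np.ndarray,
    m: int,
    denominator: str = "total_variance",
    *,
    p: int | None = None,
) -> np.ndarray:
    """Weights W_1..W_m from an eigenvalue vector.

    ``eigenvalues`` should be the full descending spectrum; ``p`` defaults to
    its length (the number of indices for correlation-matrix PCA).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.ndim != 1 or not 1 <= m <= lam.size:
        raise ParameterError(
            f"m must be in [1, {lam.size}] for a 1-d eigenvalue vector, got {m}"
        )
    if np.any(lam < 0):
        raise ParameterError("eigenvalues must be non-negative")
    if denominator not in WEIGHT_DENOMINATORS:
        raise ParameterError(
            f"denominator must be one of {WEIGHT_DENOMINATORS}, got {denominator!r}"
        )
    if denominator == "total_variance":
        denom = float(p if p is not None else lam.size)
    else:
        denom = float(lam[:m].sum())
    if denom == 0:
        raise DegenerateInputError("zero weight denominator")
    return lam[:m] / denom


def composite_f(
    scores: pd.DataFrame | np.ndarray,
    eigenvalues: Sequence[float] | np.ndarray,
) -> np.ndarray | pd.Series:
    """Eigenvalue-weighted mean of component scores:
    ``F = Σ λ_j F_j / Σ λ_j``."""
    lam = np.asarray(eigenvalues, dtype=float)
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != lam.size:
        raise ParameterError(
            f"scores shape {arr.shape} does not conform to {lam.size} eigenvalues"
        )
    total = lam.sum()
    if total == 0:
        raise DegenerateInputError("eigenvalues sum to zero")
    f = arr @ lam / total
    if isinstance(scores, pd.DataFrame):
        return pd.Series(f, index=scores.index, name="F")
    return f


@dataclass
class ScoreTable:
    """Per-genotype component scores, memberships, D values and ranks."""

    frame: pd.DataFrame  # columns F1..Fm, mu1..mum, D, rank; genotype index
    weights: np.ndarray
    tied: bool = False  # True when identical D values were rank-broken by order

    @property
    def m(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> pd.Series:
        return self.frame["D"]

    @property
    def rank(self) -> pd.Series:
        return self.frame["rank"]

    def ordered(self) -> pd.DataFrame:
        return self.frame.sort_values("rank")

    def to_csv(self, path: str | Path, *, decimals: int | None = 3) -> None:
        """Write the table plus a trailing weights row.

        ``decimals=None`` writes full precision.
        """
        df = self.frame.copy()
        if decimals is not None:
            float_cols = [c for c in df.columns if c != "rank"]
            df[float_cols] = df[float_cols].round(decimals)
        footer = {c: "" for c in df.columns}
        for j, w in enumerate(self.weights):
            footer[f"mu{j+1}"] = round(float(w), 3) if decimals else float(w)
        footer_row = pd.DataFrame([footer], index=pd.Index(["Weights"], name=df.index.name))
        pd.concat([df, footer_row]).to_csv(path, index_label="genotype")


def d_values(
    scores: pd.DataFrame,
    weights: Sequence[float] | np.ndarray,
    *,
    on_degenerate: str = "error",
) -> ScoreTable:
    """Membership-transform each component-score column and weight-sum to D.

    Ranks are 1 = highest D; exact ties keep genotype input order and set the
    ``tied`` flag on the result.
    """
    w = np.asarray(weights, dtype=float)
    arr = scores.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != w.size:
        raise ParameterError(
            f"scores shape {arr.shape} does not conform to {w.size} weights"
        )
    if arr.shape[0] < 2:
        raise ParameterError("need at least 2 genotypes")
    if np.any(w < 0) or w.sum() == 0:
        raise ParameterError("weights must be non-negative and not all zero")

    mu = np.column_stack(
        [
            membership_transform(
                arr[:, j],
                "positive",
                index_name=str(scores.columns[j]),
                on_degenerate=on_degenerate,
            ).values
            for j in range(w.size)
        ]
    )
    d = mu @ w
    order = np.argsort(-d, kind="stable")
    rank = np.empty(len(d), dtype=int)
    rank[order] = np.arange(1, len(d) + 1)
    tied = bool(len(np.unique(d)) < len(d))

    frame = pd.DataFrame(index=scores.index)
    for j in range(w.size):
        frame[f"F{j+1}"] = arr[:, j]
    for j in range(w.size):
        frame[f"mu{j+1}"] = mu[:, j]
    frame["D"] = d
    frame["rank"] = rank
    return ScoreTable(frame, w.copy(), tied)
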