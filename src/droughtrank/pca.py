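"""PCA by eigen-decomposition of the correlation matrix.

Columns are standardized to mean 0, sample SD 1 (the ``ZX`` values); the
symmetric eigen-solver runs on the correlation matrix, components are ordered
by descending eigenvalue (ties broken by original column order) and signs are
fixed so each component's largest-magnitude coefficient is positive.  Both
coefficient conventions used by mainstream stats packages are supported:

``eigenvector``
    raw unit-norm eigenvectors; component scores then have variance λ_j.
``loadings``
    eigenvector · √λ (the "component matrix" of SPSS-style output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "PCAResult",
    "fit_pca",
    "component_scores",
    "retain_components",
    "spectrum_result",
]

CONVENTIONS = ("loadings", "eigenvector")
RETENTION_RULES = ("fixed_m", "kaiser", "cumulative_threshold")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending, length p
    eigenvectors: np.ndarray  # p × p, unit-norm sign-fixed columns
    mean_: np.ndarray
    sd_: np.ndarray  # sample SD (ddof=1) used for ZX standardization
    index_names: list[str]
    n_samples: int

    @property
    def p(self) -> int:
        return len(self.eigenvalues)

    @property
    def loadings(self) -> np.ndarray:
        return self.eigenvectors * np.sqrt(self.eigenvalues)

    @property
    def contribution(self) -> np.ndarray:
        """Per-component contribution rate, % of total variance p."""
        return 100.0 * self.eigenvalues / self.p

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.contribution)

    def coefficients(self, convention: str = "loadings") -> np.ndarray:
        if convention not in CONVENTIONS:
            raise ParameterError(
                f"convention must be one of {CONVENTIONS}, got {convention!r}"
            )
        return self.loadings if convention == "loadings" else self.eigenvectors

    def standardize(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Map raw values onto the fitted ZX scale."""
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != self.p:
            raise ParameterError(
                f"expected {self.p} columns, got {arr.shape[1]}"
            )
        return (arr - self.mean_) / self.sd_

    def to_dict(self) -> dict:
        coef = pd.DataFrame(
            self.loadings,
            index=self.index_names,
            columns=[f"PC{j+1}" for j in range(self.p)],
        )
        return {
            "n_samples": self.n_samples,
            "indices": self.index_names,
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "contribution_rate_pct": [float(v) for v in self.contribution],
            "cumulative_contribution_pct": [float(v) for v in self.cumulative],
            "loadings": coef.round(6).to_dict(orient="index"),
            "eigenvectors": pd.DataFrame(
                self.eigenvectors, index=self.index_names, columns=coef.columns
            ).round(6).to_dict(orient="index"),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|coefficient| entry is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(
    X: pd.DataFrame | np.ndarray,
    index_names: Sequence[str] | None = None,
) -> PCAResult:
    """Correlation-matrix PCA of a genotype × index matrix."""
    if isinstance(X, pd.DataFrame):
        if index_names is None:
            index_names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if index_names is None:
            index_names = [f"X{i+1}" for i in range(arr.shape[1])]
    if arr.ndim != 2:
        raise ParameterError(f"expected a 2-d matrix, got shape {arr.shape}")
    n, p = arr.shape
    if n < 2:
        raise ParameterError(f"need at least 2 rows, got {n}")
    if p < 2:
        raise ParameterError(f"need at least 2 columns, got {p}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("input contains non-finite values")

    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise DegenerateInputError(
            f"constant column(s): {[index_names[i] for i in constant]}"
        )
    Z = (arr - mean) / sd
    corr = (Z.T @ Z) / (n - 1)

    lam, vec = np.linalg.eigh(corr)  # ascending
    lam = np.clip(lam[::-1], 0.0, None)
    vec = vec[:, ::-1]
    # eigh returns ascending order; reversal keeps original column order for
    # exactly tied eigenvalues in reversed-ascending position — restore a
    # stable descending order explicitly
    order = np.argsort(-lam, kind="stable")
    lam = lam[order]
    vec = _fix_signs(vec[:, order])

    return PCAResult(
        eigenvalues=lam,
        eigenvectors=vec,
        mean_=mean,
        sd_=sd,
        index_names=list(index_names),
        n_samples=n,
    )


def component_scores(
    X: pd.DataFrame | np.ndarray,
    result: PCAResult,
    m: int | None = None,
    *,
    convention: str = "eigenvector",
) -> pd.DataFrame:
    """Per-genotype component scores ``F_j = Σ_i a_ij · ZX_i``.

    With the ``eigenvector`` convention (default) score column j has sample
    variance λ_j; the ``loadings`` convention rescales each column by √λ_j.
    """
    if m is None:
        m = result.p
    if not 1 <= m <= result.p:
        raise ParameterError(f"m must be in [1, {result.p}], got {m}")
    rows = X.index if isinstance(X, pd.DataFrame) else None
    Z = result.standardize(X)
    coef = result.coefficients(convention)[:, :m]
    scores = Z @ coef
    return pd.DataFrame(
        scores, index=rows, columns=[f"F{j+1}" for j in range(m)]
    )


def spectrum_result(eigenvalues: Sequence[float] | np.ndarray) -> PCAResult:
    """Wrap a bare (e.g. published) eigenvalue spectrum as a PCAResult.

    Coefficients are identity placeholders; only eigenvalue-derived
    quantities (contribution rates, retention rules, weights) are meaningful.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.ndim != 1 or lam.size < 1:
        raise ParameterError("expected a 1-d eigenvalue vector")
    p = lam.size
    return PCAResult(
        eigenvalues=lam,
        eigenvectors=np.eye(p),
        mean_=np.zeros(p),
        sd_=np.ones(p),
        index_names=[f"X{i+1}" for i in range(p)],
        n_samples=0,
    )


def retain_components(
    result: "PCAResult | np.ndarray | Sequence[float]",
    rule: str = "fixed_m",
    *,
    m: int = 3,
    threshold: float | None = None,
) -> int:
    """Number of components to keep under a named retention rule."""
    if not isinstance(result, PCAResult):
        result = spectrum_result(result)
    if rule not in RETENTION_RULES:
        raise ParameterError(f"rule must be one of {RETENTION_RULES}, got {rule!r}")
    if rule == "fixed_m":
        if not 1 <= m <= result.p:
            raise ParameterError(f"fixed m must be in [1, {result.p}], got {m}")
        return m
    if rule == "kaiser":
        return max(1, int(np.sum(result.eigenvalues > 1.0)))
    if threshold is None or not 0 < threshold <= 100:
        raise ParameterError(
            f"cumulative_threshold needs a threshold in (0, 100], got {threshold}"
        )
    cum = result.cumulative
    # smallest m whose cumulative contribution reaches the threshold; the
    # last cumulative value is 100 so a solution always exists up to fp slack
    reached = np.flatnonzero(cum >= threshold - 1e-9)
    return int(reached[0]) + 1 if reached.size else result.p
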