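"""Control-vs-treatment response statistics per genotype and index.

Covers the signed percent change, the drought coefficient
(treatment/control ratio of cell means) and a classical paired two-tailed
t-test on replicate differences with "a"/"b" significance letters (same
letter = not significantly different at α = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError
from .trait_data import TraitMatrix

__all__ = [
    "percent_change",
    "drought_coefficient",
    "paired_t_test",
    "TTestResult",
    "response_table",
]

ALPHA = 0.05


def percent_change(control: float, treatment: float) -> float:
    """Signed percent change ``100·(treatment − control)/control``."""
    if control == 0:
        raise DomainError("percent change undefined for control mean 0")
    return 100.0 * (treatment - control) / control


def drought_coefficient(control: float, treatment: float) -> float:
    """Treatment/control ratio of a trait mean (unitless)."""
    if control == 0:
        raise DomainError("drought coefficient undefined for control mean 0")
    return treatment / control


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    significant: bool

    @property
    def letters(self) -> tuple[str, str]:
        """(control, treatment) display letters; same letter = no difference."""
        return ("a", "b") if self.significant else ("a", "a")


def paired_t_test(
    control: Sequence[float] | np.ndarray,
    treatment: Sequence[float] | np.ndarray,
) -> TTestResult:
    """Two-tailed paired t-test on replicate differences.

    Replicates pair by position (replicate-id order upstream).  A zero-variance
    nonzero-mean difference vector is the infinite-t limit: t = ±inf, p = 0,
    reported with a warning.
    """
    c = np.asarray(control, dtype=float)
    t_arr = np.asarray(treatment, dtype=float)
    if c.shape != t_arr.shape or c.ndim != 1:
        raise InsufficientDataError(
            f"replicate vectors must be equal-length 1-d, got {c.shape} vs {t_arr.shape}"
        )
    n = c.size
    if n < 2:
        raise InsufficientDataError(f"paired t-test needs n >= 2 replicates, got {n}")
    d = t_arr - c
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if md == 0:
            return TTestResult(0.0, 1.0, False)
        warnings.warn(
            "zero variance of paired differences with nonzero mean: "
            "p reported at the 0 limit",
            stacklevel=2,
        )
        return TTestResult(np.inf if md > 0 else -np.inf, 0.0, True)
    t_stat = md / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    return TTestResult(float(t_stat), float(p), bool(p < ALPHA))


def response_table(
    tm: TraitMatrix,
    *,
    fdr: bool = False,
) -> pd.DataFrame:
    """One row per (genotype, index): means, % change, coefficient, paired t.

    ``fdr=True`` appends Benjamini–Hochberg adjusted p-values across all
    rows (off by default — the plain per-pair test matches the conventional
    table presentation).
    """
    rows = []
    for g in tm.genotypes:
        for ix in tm.indices:
            ctrl, trt = tm.replicate_vectors(g, ix)
            cm, tmn = ctrl.mean(), trt.mean()
            rec = {
                "genotype": g,
                "index": ix,
                "control_mean": cm,
                "treatment_mean": tmn,
                "percent_change": percent_change(cm, tmn) if cm != 0 else np.nan,
                "drought_coefficient": drought_coefficient(cm, tmn)
                if cm != 0
                else np.nan,
            }
            if len(ctrl) >= 2 and len(ctrl) == len(trt):
                res = paired_t_test(ctrl, trt)
                rec.update(t=res.t, p=res.p, significant=res.significant)
            else:
                rec.update(t=np.nan, p=np.nan, significant=False)
            rows.append(rec)
    out = pd.DataFrame(rows)
    if fdr:
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
        out["significant_adj"] = out["p_adj"] < ALPHA
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    ps = p[mask]
    n = ps.size
    if n == 0:
        return out
    order = np.argsort(ps)
    ranked = ps[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.clip(adj, 0, 1)
    out[mask] = res
    return out
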