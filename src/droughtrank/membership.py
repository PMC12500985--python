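"""Fuzzy membership (min–max) transformation of index vectors.

For an index that counts toward resistance the transform is
``(x − min)/(max − min)``; for one that counts against it the complement
``1 − (x − min)/(max − min)`` is used, so that 1 always means "best" and 0
"worst".  The transform is invariant under positive affine rescaling of the
raw values, which makes everything downstream unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateRangeError, ParameterError
from .trait_data import IndexSpec

__all__ = ["MembershipVector", "membership_transform", "membership_matrix"]


@dataclass(frozen=True)
class MembershipVector:
    """Result of one membership transform: values in [0, 1] plus provenance."""

    values: np.ndarray
    direction: str
    index_name: str | None = None

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i):
        return self.values[i]


def membership_transform(
    x: Sequence[float] | np.ndarray,
    direction: str = "positive",
    *,
    index_name: str | None = None,
    on_degenerate: str = "error",
) -> MembershipVector:
    """Min–max membership of ``x`` with the given direction.

    on_degenerate
        What to do when max == min: ``"error"`` (default) raises
        :class:`DegenerateRangeError`; ``"half"`` returns all 0.5.
    """
    if direction not in ("positive", "negative"):
        raise ParameterError(f"direction must be 'positive' or 'negative', got {direction!r}")
    if on_degenerate not in ("error", "half"):
        raise ParameterError(f"on_degenerate must be 'error' or 'half', got {on_degenerate!r}")
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"expected a 1-d vector, got shape {arr.shape}")
    if arr.size < 2:
        raise ParameterError("membership transform needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("membership transform requires finite values")

    lo, hi = arr.min(), arr.max()
    if hi == lo:
        if on_degenerate == "error":
            name = f" for index {index_name!r}" if index_name else ""
            raise DegenerateRangeError(
                f"degenerate range{name}: all values equal {lo}"
            )
        mu = np.full_like(arr, 0.5)
    else:
        mu = (arr - lo) / (hi - lo)
        if direction == "negative":
            mu = 1.0 - mu
    return MembershipVector(mu, direction, index_name)


def membership_matrix(
    X: pd.DataFrame,
    specs: Mapping[str, IndexSpec],
    *,
    on_degenerate: str = "error",
) -> pd.DataFrame:
    """Column-wise membership transform of a genotype × index frame.

    Directions come from ``specs``; columns missing from the spec default to
    positive direction only if a spec entry exists — otherwise this raises,
    because silently guessing a direction would corrupt the scoring.
    """
    out = {}
    for col in X.columns:
        if col not in specs:
            raise ParameterError(f"no direction defined for index {col!r}")
        out[col] = membership_transform(
            X[col].to_numpy(),
            specs[col].direction,
            index_name=col,
            on_degenerate=on_degenerate,
        ).values
    return pd.DataFrame(out, index=X.index)
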