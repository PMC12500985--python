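"""Bundled reference data: a published 25-genotype daylily drought screen.

The bundle carries the printed summary statistics of the screen — per-pigment
control/treatment means, the 13-component eigenvalue spectrum, the retained
component scores (F columns) and the published membership/D/rank evaluation —
so the scoring stages can be exercised and regression-tested against known
output without any download.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["Daylily25", "load_daylily25"]

_PKG = "droughtrank.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


@dataclass
class Daylily25:
    eigenvalues: np.ndarray  # full descending spectrum, length 13
    component_scores: pd.DataFrame  # genotype-indexed F1..F3
    evaluation: pd.DataFrame  # genotype-indexed mu1..mu3, D, rank (published)
    pigment_means: pd.DataFrame  # tidy: genotype,index,condition,mean,sd

    @property
    def genotypes(self) -> list[str]:
        return list(self.component_scores.index)


def load_daylily25() -> Daylily25:
    eig = _read("daylily25_eigenvalues.csv")["eigenvalue"].to_numpy(dtype=float)
    scores = _read("daylily25_component_scores.csv").set_index("genotype")
    evaluation = _read("daylily25_evaluation.csv").set_index("genotype")
    pigments = _read("daylily25_pigments.csv")
    return Daylily25(eig, scores, evaluation, pigments)
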