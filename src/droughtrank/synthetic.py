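"""Synthetic genotype panels with planted resistance structure.

Each genotype carries a latent resistance score in [0, 1] drawn around its
group centre (three groups: high / moderate / low).  Every index responds to
treatment with a multiplier that interpolates *linearly in the latent score*
between a worst-case and a best-case effect, so in the noise-free limit the
drought coefficient of every index is an exact affine function of the latent
score and the full pipeline must recover the planted order.

Noise is multiplicative (CV-based): trait SDs in real panels scale roughly
with their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .trait_data import CONDITIONS, IndexSpec, DEFAULT_INDEX_SPECS, TraitMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_panel"]

GROUP_NAMES = ("high", "moderate", "low")

#: Baseline control-condition means for the 13 default indices.
DEFAULT_BASELINES: dict[str, float] = {
    "PH": 35.0, "CW": 45.0, "LL": 38.0, "LW": 1.4, "LA": 38.0,
    "Chl": 1.1, "Chl_a": 0.8, "Chl_b": 0.29, "Chl_a_b": 2.9, "Car": 0.5,
    "RWC": 85.0, "EL": 25.0, "MDA": 8.0,
}

#: Treatment effect (signed fraction of baseline) at latent resistance 1
#: and 0 respectively: (effect_best, effect_worst).
DEFAULT_EFFECTS: dict[str, tuple[float, float]] = {
    "PH": (-0.01, -0.25),
    "CW": (-0.01, -0.20),
    "LL": (-0.02, -0.25),
    "LW": (-0.02, -0.30),
    "LA": (-0.03, -0.35),
    "Chl": (0.40, -0.15),
    "Chl_a": (0.40, -0.15),
    "Chl_b": (0.45, -0.20),
    "Chl_a_b": (0.08, -0.02),
    "Car": (0.30, -0.05),
    "RWC": (-0.02, -0.20),
    "EL": (0.05, 0.90),
    "MDA": (0.10, 1.00),
}


@dataclass
class SyntheticConfig:
    seed: int
    n_genotypes: int = 25
    group_proportions: tuple[float, float, float] = (0.24, 0.28, 0.48)
    group_centers: tuple[float, float, float] = (0.9, 0.55, 0.2)
    genotype_jitter: float = 0.03
    baseline_cv: float = 0.08
    noise_cv: float = 0.02
    replicates: int = 3
    index_specs: Mapping[str, IndexSpec] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_SPECS)
    )
    baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )

    def __post_init__(self):
        props = np.asarray(self.group_proportions, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"group proportions must be non-negative and sum to 1, got {tuple(props)}"
            )
        if self.replicates < 1:
            raise ConfigError(f"replicate count must be >= 1, got {self.replicates}")
        if min(self.noise_cv, self.baseline_cv, self.genotype_jitter) < 0:
            raise ConfigError("noise CV / jitter values must be >= 0")
        if self.n_genotypes < 2:
            raise ConfigError(f"need at least 2 genotypes, got {self.n_genotypes}")
        for name, spec in self.index_specs.items():
            if name not in self.baselines or name not in self.effects:
                raise ConfigError(f"index {name!r} lacks a baseline or effect entry")
            if self.baselines[name] <= 0:
                raise ConfigError(f"index {name!r}: baseline must be > 0")
            e_best, e_worst = self.effects[name]
            # effects must respect direction: losing resistance means larger
            # increases for injury indices and larger decreases otherwise
            if spec.direction == "negative" and not e_worst > e_best:
                raise ConfigError(
                    f"index {name!r} is negative-direction but the worst-case "
                    f"effect ({e_worst}) does not exceed the best-case ({e_best})"
                )
            if spec.direction == "positive" and not e_worst < e_best:
                raise ConfigError(
                    f"index {name!r} is positive-direction but the worst-case "
                    f"effect ({e_worst}) is not below the best-case ({e_best})"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "index_specs" in raw:
            raw["index_specs"] = {
                k: IndexSpec(k, **v) for k, v in raw["index_specs"].items()
            }
        if "effects" in raw:
            raw["effects"] = {k: tuple(v) for k, v in raw["effects"].items()}
        for key in ("group_proportions", "group_centers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    genotypes: list[str]
    group: list[str]  # one of GROUP_NAMES per genotype
    latent: np.ndarray  # planted resistance score in [0, 1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"genotype": self.genotypes, "group": self.group, "latent": self.latent}
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path, index=False)


def _group_counts(props: np.ndarray, G: int) -> np.ndarray:
    """Largest-remainder apportionment of G genotypes over the groups."""
    raw = props * G
    counts = np.floor(raw).astype(int)
    rem = G - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def treatment_multiplier(cfg: SyntheticConfig, index: str, latent: float) -> float:
    """1 + effect at the given latent resistance (linear interpolation)."""
    e_best, e_worst = cfg.effects[index]
    return 1.0 + e_worst + (e_best - e_worst) * latent


def generate_panel(cfg: SyntheticConfig) -> tuple[TraitMatrix, SyntheticTruth]:
    """Simulate a replicated control/treatment panel; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genotypes
    counts = _group_counts(np.asarray(cfg.group_proportions, dtype=float), G)
    genotypes = [f"S{i+1}" for i in range(G)]

    centers = np.repeat(np.asarray(cfg.group_centers, dtype=float), counts)
    latent = np.clip(centers + cfg.genotype_jitter * rng.standard_normal(G), 0.0, 1.0)
    # relabel groups by latent rank so labels always respect the score order
    order = np.argsort(-latent, kind="stable")
    group = np.empty(G, dtype=object)
    start = 0
    for name, cnt in zip(GROUP_NAMES, counts):
        group[order[start:start + cnt]] = name
        start += cnt

    indices = list(cfg.index_specs)
    records = []
    for gi, g in enumerate(genotypes):
        for ix in indices:
            base = cfg.baselines[ix] * float(
                np.exp(cfg.baseline_cv * rng.standard_normal())
            )
            mult = treatment_multiplier(cfg, ix, float(latent[gi]))
            for cond in CONDITIONS:
                level = base if cond == "control" else base * mult
                for rep in range(1, cfg.replicates + 1):
                    noise = 1.0 + cfg.noise_cv * float(rng.standard_normal())
                    records.append((g, ix, cond, rep, level * noise))

    tidy = pd.DataFrame(
        records, columns=["genotype", "index", "condition", "replicate", "value"]
    )
    tm = TraitMatrix.from_tidy(tidy, spec=cfg.index_specs)
    truth = SyntheticTruth(genotypes, list(group), latent)
    return tm, truth
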