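"""End-to-end orchestration: tidy panel → response → membership → PCA →
F/D scores → groups → correlation, with a manifest for reproducibility.

Every run writes the same artifact set into ``outdir``:

================  ====================================================
response.csv      per-(genotype, index) response statistics
membership.csv    membership matrix fed to PCA
pca.json          eigenvalues, contribution rates, coefficient matrix
scores.csv        F/μ/D/rank table rounded for display
scores_full.csv   same table at full precision
labels.csv        cluster group per genotype
dendrogram.nwk    Newick dendrogram, rescaled heights
correlation.csv   index × index Pearson matrix with stars
manifest.json     config echo + SHA-256 config hash + package version
pipeline.log      stage-level log
================  ====================================================

Identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_genotypes
from .correlation import pearson_matrix
from .errors import ConfigError, DroughtRankError, PipelineError
from .membership import membership_matrix
from .pca import component_scores, fit_pca, retain_components
from .response import response_table
from .scoring import component_weights, composite_f, d_values
from .synthetic import SyntheticConfig, generate_panel
from .trait_data import (
    DEFAULT_INDEX_SPECS,
    read_index_spec,
    read_trait_table,
    write_trait_table,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

PCA_INPUT_MODES = ("drought_coefficient", "treatment_mean", "percent_change")
CLUSTER_INPUTS = ("component_scores", "composite_f", "d_value")


@dataclass
class PipelineConfig:
    outdir: str
    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    index_spec_path: str | None = None
    pca_input: str = "drought_coefficient"
    coefficient_convention: str = "eigenvector"
    retention_rule: str = "fixed_m"
    retention_m: int = 3
    retention_threshold: float | None = None
    weight_denominator: str = "total_variance"
    linkage: str = "complete"
    cluster_input: str = "component_scores"
    cut_k: int | None = 3
    cut_rescaled_height: float | None = None
    membership_degenerate: str = "error"
    score_decimals: int = 3
    percent_decimals: int = 2

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_csv or synthetic must be set")
        if self.pca_input not in PCA_INPUT_MODES:
            raise ConfigError(
                f"pca_input must be one of {PCA_INPUT_MODES}, got {self.pca_input!r}"
            )
        if self.cluster_input not in CLUSTER_INPUTS:
            raise ConfigError(
                f"cluster_input must be one of {CLUSTER_INPUTS}, got {self.cluster_input!r}"
            )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            syn = d["synthetic"]
            syn["index_specs"] = {
                k: {"direction": v.direction, "units": v.units}
                for k, v in self.synthetic.index_specs.items()
            }
            syn["effects"] = {k: list(v) for k, v in self.synthetic.effects.items()}
            syn["group_proportions"] = list(self.synthetic.group_proportions)
            syn["group_centers"] = list(self.synthetic.group_centers)
            syn["baselines"] = dict(self.synthetic.baselines)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        cfg_syn = None
        if syn is not None:
            syn = dict(syn)
            if "index_specs" in syn:
                from .trait_data import IndexSpec

                syn["index_specs"] = {
                    k: IndexSpec(k, **v) for k, v in syn["index_specs"].items()
                }
            if "effects" in syn:
                syn["effects"] = {k: tuple(v) for k, v in syn["effects"].items()}
            for key in ("group_proportions", "group_centers"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            cfg_syn = SyntheticConfig(**syn)
        return cls(synthetic=cfg_syn, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    artifacts: dict[str, Path]
    score_table: "pd.DataFrame"
    labels: "pd.DataFrame"
    m: int
    weights: np.ndarray


def _stage(log: logging.Logger, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                log.info("stage %s: done", name)
                return False
            if isinstance(exc, PipelineError):
                return False
            log.error("stage %s: %s", name, exc)
            if isinstance(exc, DroughtRankError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log = logging.getLogger("droughtrank.pipeline")
    log.setLevel(logging.INFO)
    log.handlers = [logging.FileHandler(outdir / "pipeline.log", mode="w")]
    log.handlers[0].setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    artifacts["log"] = outdir / "pipeline.log"

    with _stage(log, "load"):
        if cfg.index_spec_path:
            specs = read_index_spec(cfg.index_spec_path)
        elif cfg.synthetic is not None:
            specs = dict(cfg.synthetic.index_specs)
        else:
            specs = dict(DEFAULT_INDEX_SPECS)
        if cfg.synthetic is not None:
            tm, truth = generate_panel(cfg.synthetic)
            write_trait_table(tm, outdir / "panel.csv")
            truth.to_csv(outdir / "truth.csv")
            artifacts["panel"] = outdir / "panel.csv"
            artifacts["truth"] = outdir / "truth.csv"
        else:
            tm = read_trait_table(cfg.input_csv, spec=specs)
        log.info("loaded %d genotypes × %d indices", len(tm.genotypes), len(tm.indices))

    with _stage(log, "respond"):
        resp = response_table(tm)
        out = resp.copy()
        for col in ("percent_change",):
            out[col] = out[col].round(cfg.percent_decimals)
        out.to_csv(outdir / "response.csv", index=False)
        artifacts["response"] = outdir / "response.csv"

    with _stage(log, "membership"):
        means_c = tm.mean_matrix("control")
        means_t = tm.mean_matrix("treatment")
        if cfg.pca_input == "treatment_mean":
            raw = means_t
        elif cfg.pca_input == "drought_coefficient":
            raw = means_t / means_c
        else:
            raw = 100.0 * (means_t - means_c) / means_c
        mu = membership_matrix(raw, specs, on_degenerate=cfg.membership_degenerate)
        mu.to_csv(outdir / "membership.csv", index_label="genotype")
        artifacts["membership"] = outdir / "membership.csv"

    with _stage(log, "pca"):
        pca = fit_pca(mu)
        pca.to_json(outdir / "pca.json")
        artifacts["pca"] = outdir / "pca.json"
        m = retain_components(
            pca,
            cfg.retention_rule,
            m=cfg.retention_m,
            threshold=cfg.retention_threshold,
        )
        log.info("retained m=%d components", m)

    with _stage(log, "score"):
        scores = component_scores(mu, pca, m, convention=cfg.coefficient_convention)
        weights = component_weights(
            pca.eigenvalues, m, denominator=cfg.weight_denominator
        )
        table = d_values(scores, weights, on_degenerate=cfg.membership_degenerate)
        table.frame.insert(m, "F", composite_f(scores, pca.eigenvalues[:m]))
        table.to_csv(outdir / "scores.csv", decimals=cfg.score_decimals)
        table.to_csv(outdir / "scores_full.csv", decimals=None)
        artifacts["scores"] = outdir / "scores.csv"
        artifacts["scores_full"] = outdir / "scores_full.csv"

    with _stage(log, "classify"):
        if cfg.cluster_input == "component_scores":
            feats = scores
        elif cfg.cluster_input == "composite_f":
            feats = table.frame[["F"]]
        else:
            feats = table.frame[["D"]]
        grouping = cluster_genotypes(
            feats,
            tm.genotypes,
            linkage=cfg.linkage,
            k=cfg.cut_k,
            rescaled_height=cfg.cut_rescaled_height,
        )
        labels = grouping.labels_frame()
        labels.to_csv(outdir / "labels.csv", index=False)
        grouping.to_newick(outdir / "dendrogram.nwk")
        artifacts["labels"] = outdir / "labels.csv"
        artifacts["dendrogram"] = outdir / "dendrogram.nwk"
        log.info("cut into k=%d groups", grouping.k)

    with _stage(log, "correlate"):
        corr = pearson_matrix(mu)
        corr.to_csv(outdir / "correlation.csv")
        artifacts["correlation"] = outdir / "correlation.csv"

    with _stage(log, "manifest"):
        manifest = {
            "version": __version__,
            "config_sha256": cfg.config_hash(),
            "config": cfg.to_dict(),
            "n_genotypes": len(tm.genotypes),
            "n_indices": len(tm.indices),
            "retained_components": m,
            "weights": [float(w) for w in weights],
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        artifacts["manifest"] = outdir / "manifest.json"

    for h in log.handlers:
        h.close()
    log.handlers = []

    return PipelineResult(outdir, artifacts, table.frame, labels, m, weights)
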