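"""Genotype × trait panel data model, tidy CSV I/O and validation.

The universal input of the pipeline is a *tidy* table with one row per
measured value::

    genotype,index,condition,replicate,value
    S1,PH,control,1,40.4

``TraitMatrix`` wraps that table, enforces a fully crossed
(genotype × index × condition) design with no missing cells, and provides
aggregation to per-cell means.  Genotype and index display order is
first-appearance order in the source and is preserved by every operation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, IntegrityError, ParseError, SpecError

CONDITIONS = ("control", "treatment")

TIDY_COLUMNS = ("genotype", "index", "condition", "replicate", "value")


@dataclass(frozen=True)
class IndexSpec:
    """Per-index metadata.

    direction
        ``"positive"`` if larger values indicate stronger resistance,
        ``"negative"`` otherwise (inverted during membership transforms).
    """

    name: str
    direction: str = "positive"
    units: str = ""

    def __post_init__(self):
        if self.direction not in ("positive", "negative"):
            raise SpecError(
                f"index {self.name!r}: direction must be 'positive' or "
                f"'negative', got {self.direction!r}"
            )


#: Default spec for the 13 standard growth/physiology indices.  Electrolyte
#: leakage and MDA rise with stress injury and therefore count against
#: resistance; every other index counts toward it.
DEFAULT_INDEX_SPECS: dict[str, IndexSpec] = {
    name: IndexSpec(name, direction, units)
    for name, direction, units in [
        ("PH", "positive", "cm"),
        ("CW", "positive", "cm"),
        ("LL", "positive", "cm"),
        ("LW", "positive", "cm"),
        ("LA", "positive", "cm2"),
        ("Chl", "positive", "mg/g FW"),
        ("Chl_a", "positive", "mg/g FW"),
        ("Chl_b", "positive", "mg/g FW"),
        ("Chl_a_b", "positive", ""),
        ("Car", "positive", "mg/g FW"),
        ("RWC", "positive", "%"),
        ("EL", "negative", "%"),
        ("MDA", "negative", "umol/g FW"),
    ]
}


def read_index_spec(path: str | Path) -> dict[str, IndexSpec]:
    """Read a YAML mapping ``index -> {direction, units}``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise FormatError(f"{path}: expected a mapping of index -> spec")
    specs = {}
    for name, entry in raw.items():
        entry = entry or {}
        specs[str(name)] = IndexSpec(
            str(name),
            direction=entry.get("direction", "positive"),
            units=entry.get("units", ""),
        )
    return specs


def write_index_spec(specs: Mapping[str, IndexSpec], path: str | Path) -> None:
    payload = {
        s.name: {"direction": s.direction, "units": s.units} for s in specs.values()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _first_appearance(values: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class TraitMatrix:
    """A validated tidy genotype × index × condition × replicate table."""

    data: pd.DataFrame
    genotypes: list[str] = field(default_factory=list)
    indices: list[str] = field(default_factory=list)

    @classmethod
    def from_tidy(
        cls,
        df: pd.DataFrame,
        spec: Mapping[str, IndexSpec] | None = None,
    ) -> "TraitMatrix":
        missing = [c for c in TIDY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(TIDY_COLUMNS)].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["index"] = df["index"].astype(str)
        df["condition"] = df["condition"].astype(str)

        bad_cond = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise FormatError(
                f"unknown condition(s) {bad_cond}; expected {list(CONDITIONS)}"
            )

        def _parse(v):
            # python float() is round-trip exact; pandas' fast parser is not
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan

        values = df["value"].map(_parse)
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric or non-finite value {df['value'].iloc[row]!r} "
                f"at data row {row + 1}"
            )
        df["value"] = values.astype(float)
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
        if df["replicate"].isna().any():
            row = int(df.index[df["replicate"].isna()][0])
            raise ParseError(f"non-numeric replicate id at data row {row + 1}")
        df["replicate"] = df["replicate"].astype(int)

        dup = df.duplicated(subset=["genotype", "index", "condition", "replicate"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["genotype", "index", "condition", "replicate"]]
            raise IntegrityError(
                "duplicate key (genotype={genotype!r}, index={index!r}, "
                "condition={condition!r}, replicate={replicate})".format(**key)
            )

        if spec is not None:
            unknown = sorted(set(df["index"]) - set(spec))
            if unknown:
                raise SpecError(
                    f"index(es) {unknown} present in data but absent from spec"
                )

        genotypes = _first_appearance(df["genotype"])
        indices = _first_appearance(df["index"])

        # fully crossed design: every (genotype, index, condition) cell present
        cells = df.groupby(["genotype", "index", "condition"], sort=False).size()
        expected = len(genotypes) * len(indices) * len(CONDITIONS)
        if len(cells) != expected:
            have = set(cells.index)
            for g in genotypes:
                for ix in indices:
                    for c in CONDITIONS:
                        if (g, ix, c) not in have:
                            raise IntegrityError(
                                f"missing cell (genotype={g!r}, index={ix!r}, "
                                f"condition={c!r})"
                            )

        return cls(df.reset_index(drop=True), genotypes, indices)

    # ------------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitMatrix):
            return NotImplemented
        if self.genotypes != other.genotypes or self.indices != other.indices:
            return False
        key = ["genotype", "index", "condition", "replicate"]
        a = self.data.sort_values(key).reset_index(drop=True)
        b = other.data.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    @property
    def n_replicates(self) -> int:
        return int(self.data.groupby(["genotype", "index", "condition"]).size().max())

    def cell_means(self) -> pd.DataFrame:
        """Mean, sample SD (ddof=1, 0 for singleton cells) and n per cell."""
        grouped = self.data.groupby(["genotype", "index", "condition"], sort=False)[
            "value"
        ]
        out = grouped.agg(mean="mean", sd="std", n="size").reset_index()
        out["sd"] = out["sd"].fillna(0.0)
        return out

    def mean_matrix(self, condition: str) -> pd.DataFrame:
        """Genotype × index matrix of cell means for one condition."""
        if condition not in CONDITIONS:
            raise FormatError(f"unknown condition {condition!r}")
        means = self.cell_means()
        sub = means[means["condition"] == condition]
        wide = sub.pivot(index="genotype", columns="index", values="mean")
        return wide.reindex(index=self.genotypes, columns=self.indices)

    def replicate_vectors(
        self, genotype: str, index: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """(control, treatment) replicate values ordered by replicate id."""
        sel = self.data[
            (self.data["genotype"] == genotype) & (self.data["index"] == index)
        ].sort_values("replicate")
        ctrl = sel.loc[sel["condition"] == "control", "value"].to_numpy()
        trt = sel.loc[sel["condition"] == "treatment", "value"].to_numpy()
        return ctrl, trt


def read_trait_table(
    path: str | Path | io.TextIOBase,
    spec: Mapping[str, IndexSpec] | None = None,
) -> TraitMatrix:
    """Read and validate a tidy trait CSV.

    Row order in the file does not affect the resulting matrix beyond the
    first-appearance display order of genotypes and indices.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise FormatError(str(exc)) from exc
    return TraitMatrix.from_tidy(df, spec=spec)


def write_trait_table(tm: TraitMatrix, path: str | Path) -> None:
    """Write the tidy table; floats use shortest round-trip representation."""
    df = tm.data.copy()
    df["value"] = df["value"].map(repr)
    df.to_csv(path, index=False)


def read_wide_means(
    path: str | Path,
    spec: Mapping[str, IndexSpec] | None = None,
) -> TraitMatrix:
    """Convenience reader for a wide means table.

    Expected header: ``genotype`` plus one ``<index>_<condition>`` column per
    index and condition (e.g. ``PH_control,PH_treatment``).  Normalized to a
    single-replicate tidy table internally.
    """
    df = pd.read_csv(path)
    if "genotype" not in df.columns:
        raise FormatError("missing column(s): genotype")
    records = []
    for col in df.columns:
        if col == "genotype":
            continue
        name, sep, cond = col.rpartition("_")
        if not sep or cond not in CONDITIONS:
            raise FormatError(
                f"column {col!r} is not of the form <index>_<condition>"
            )
        for g, v in zip(df["genotype"].astype(str), df[col]):
            records.append((g, name, cond, 1, v))
    tidy = pd.DataFrame(records, columns=TIDY_COLUMNS)
    return TraitMatrix.from_tidy(tidy, spec=spec)


def means_to_trait_matrix(
    means: pd.DataFrame,
    spec: Mapping[str, IndexSpec] | None = None,
) -> TraitMatrix:
    """Build a 1-replicate TraitMatrix from a tidy means table.

    ``means`` needs columns genotype, index, condition and mean (or value).
    """
    df = means.copy()
    if "mean" in df.columns and "value" not in df.columns:
        df = df.rename(columns={"mean": "value"})
    df["replicate"] = 1
    return TraitMatrix.from_tidy(df[list(TIDY_COLUMNS)], spec=spec)
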