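"""Closed-form leaf physiology assay calculators.

Each calculator implements the published bench formula verbatim; unit
conventions (volumes in mL, the ×1000 factor in the MDA formula) follow the
printed protocols, so reported magnitudes depend on honouring them.
Spectrophotometric coefficients (``E``) are explicit parameters — no hidden
per-pigment table is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DomainError

__all__ = [
    "MdaReading",
    "RwcReading",
    "PigmentReading",
    "mda_content",
    "rwc_percent",
    "pigment_concentration",
    "el_percent",
    "batch_compute",
]


@dataclass(frozen=True)
class MdaReading:
    """TBA-assay absorbances plus extract volume (mL) and tissue mass (g)."""

    A450: float
    A532: float
    A600: float
    V: float
    W: float

    def __post_init__(self):
        if min(self.A450, self.A532, self.A600) < 0:
            warnings.warn("negative absorbance reading", stacklevel=3)
        if self.V <= 0:
            raise DomainError(f"supernatant volume V must be > 0, got {self.V}")
        if self.W <= 0:
            raise DomainError(f"fresh tissue mass W must be > 0, got {self.W}")


@dataclass(frozen=True)
class RwcReading:
    """Fresh, turgid and dry leaf weights (g)."""

    Wf: float
    Wt: float
    Wd: float

    def __post_init__(self):
        if not (self.Wt >= self.Wf >= self.Wd > 0):
            warnings.warn(
                f"expected Wt >= Wf >= Wd > 0, got Wf={self.Wf}, Wt={self.Wt}, "
                f"Wd={self.Wd}",
                stacklevel=3,
            )


@dataclass(frozen=True)
class PigmentReading:
    """Absorbance, extract volume (mL), absorption coefficient, path length (cm)."""

    A: float
    V: float
    E: float
    l: float  # noqa: E741 - conventional symbol for path length

    def __post_init__(self):
        if self.E <= 0:
            raise DomainError(f"absorption coefficient E must be > 0, got {self.E}")
        if self.l <= 0:
            raise DomainError(f"path length l must be > 0, got {self.l}")
        if self.V <= 0:
            raise DomainError(f"extract volume V must be > 0, got {self.V}")


def mda_content(r: MdaReading) -> float:
    """Malondialdehyde content, µmol per g fresh weight.

    ``[6.452·(A532 − A600) − 0.559·A450] · (V/W) · 1000`` with V in mL.
    """
    return (6.452 * (r.A532 - r.A600) - 0.559 * r.A450) * (r.V / r.W) * 1000.0


def rwc_percent(r: RwcReading) -> float:
    """Leaf relative water content, %: ``100·(Wf − Wd)/(Wt − Wd)``."""
    if r.Wt == r.Wd:
        raise DomainError("Wt equals Wd: zero denominator in RWC")
    return 100.0 * (r.Wf - r.Wd) / (r.Wt - r.Wd)


def pigment_concentration(r: PigmentReading) -> float:
    """Pigment concentration, g/L: ``(A·V·1000)/(E·l)``."""
    return (r.A * r.V * 1000.0) / (r.E * r.l)


def el_percent(
    c_initial: float,
    c_total: float,
    *,
    c_blank: float = 0.0,
) -> float:
    """Electrolyte leakage, %, by the conductivity-ratio method.

    Default is the plain ratio ``100·C_initial/C_total``; passing ``c_blank``
    switches to the blank-corrected form
    ``100·(C_initial − C_blank)/(C_total − C_blank)``.
    """
    denom = c_total - c_blank
    if denom == 0:
        raise DomainError("zero denominator: C_total equals the blank")
    if c_total <= 0:
        raise DomainError(f"C_total must be > 0, got {c_total}")
    if c_initial > c_total:
        warnings.warn(
            f"C_initial ({c_initial}) exceeds C_total ({c_total})", stacklevel=2
        )
    return 100.0 * (c_initial - c_blank) / denom


# ----------------------------------------------------------------------
# batch CSV mode

_BATCH_SCHEMAS = {
    "mda": (("A450", "A532", "A600", "V", "W"), "MDA"),
    "rwc": (("Wf", "Wt", "Wd"), "RWC"),
    "pigment": (("A", "V", "E", "l"), "concentration"),
    "el": (("C_initial", "C_total"), "EL"),
}


def _compute_row(kind: str, row: pd.Series) -> float:
    if kind == "mda":
        return mda_content(MdaReading(row.A450, row.A532, row.A600, row.V, row.W))
    if kind == "rwc":
        return rwc_percent(RwcReading(row.Wf, row.Wt, row.Wd))
    if kind == "pigment":
        return pigment_concentration(PigmentReading(row.A, row.V, row.E, row.l))
    return el_percent(row.C_initial, row.C_total)


def batch_compute(kind: str, readings: pd.DataFrame) -> pd.DataFrame:
    """Apply one assay formula to a CSV-shaped table of readings.

    Returns the input with the computed index appended as the last column.
    """
    if kind not in _BATCH_SCHEMAS:
        raise DomainError(
            f"unknown assay kind {kind!r}; expected one of {sorted(_BATCH_SCHEMAS)}"
        )
    columns, out_name = _BATCH_SCHEMAS[kind]
    missing = [c for c in columns if c not in readings.columns]
    if missing:
        raise DomainError(f"assay {kind!r}: missing column(s) {missing}")
    out = readings.copy()
    out[out_name] = [_compute_row(kind, row) for row in readings.itertuples()]
    return out


def batch_compute_csv(kind: str, in_path: str | Path, out_path: str | Path) -> None:
    batch_compute(kind, pd.read_csv(in_path)).to_csv(out_path, index=False)
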