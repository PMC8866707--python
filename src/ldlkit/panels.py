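"""Lipid panel records and cohort tables.

A cohort is a plain :class:`pandas.DataFrame` with one row per participant
and at least the columns ``tc``, ``hdl`` and ``tg`` (all mg/dL).  A column
``ldl_measured`` holds the directly measured LDL-C where available, and
``non_hdl`` (``tc - hdl``) is derived on demand.  Scalar work goes through
:class:`LipidPanel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("tc", "hdl", "tg")

__all__ = [
    "LipidPanel",
    "PanelValidationError",
    "REQUIRED_COLUMNS",
    "validate_cohort",
    "with_non_hdl",
    "read_cohort",
    "write_cohort",
]


class PanelValidationError(ValueError):
    """A lipid panel or cohort failed validation; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclass(frozen=True)
class LipidPanel:
    """One participant's fasting lipid panel in mg/dL."""

    tc: float
    hdl: float
    tg: float
    ldl_measured: float | None = None

    @property
    def non_hdl(self) -> float:
        return self.tc - self.hdl

    def validate(self) -> "LipidPanel":
        if not np.isfinite(self.tc) or self.tc <= 0:
            raise PanelValidationError("tc", f"total cholesterol must be positive, got {self.tc}")
        if not np.isfinite(self.hdl) or self.hdl <= 0:
            raise PanelValidationError("hdl", f"HDL-C must be positive, got {self.hdl}")
        if not np.isfinite(self.tg) or self.tg < 0:
            raise PanelValidationError("tg", f"triglycerides must be non-negative, got {self.tg}")
        if self.hdl >= self.tc:
            raise PanelValidationError("hdl", f"HDL-C ({self.hdl}) must be below total cholesterol ({self.tc})")
        return self


def _check(name: str, ok: np.ndarray) -> None:
    if not bool(np.all(ok)):
        bad = int(np.argmax(~np.asarray(ok)))
        raise PanelValidationError(name, f"invalid value at row {bad}")


def validate_cohort(df: pd.DataFrame, require_measured: bool = False) -> pd.DataFrame:
    """Validate a cohort table; raises :class:`PanelValidationError` naming the field."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PanelValidationError(col, "required column missing")
    tc = df["tc"].to_numpy(dtype=float)
    hdl = df["hdl"].to_numpy(dtype=float)
    tg = df["tg"].to_numpy(dtype=float)
    _check("tc", np.isfinite(tc) & (tc > 0))
    _check("hdl", np.isfinite(hdl) & (hdl > 0))
    _check("tg", np.isfinite(tg) & (tg >= 0))
    _check("hdl", hdl < tc)
    if require_measured:
        if "ldl_measured" not in df.columns:
            raise PanelValidationError("ldl_measured", "required column missing")
        meas = df["ldl_measured"].to_numpy(dtype=float)
        _check("ldl_measured", np.isfinite(meas))
    return df


def with_non_hdl(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the derived ``non_hdl`` column (tc - hdl)."""
    out = df.copy()
    out["non_hdl"] = out["tc"] - out["hdl"]
    return out


def read_cohort(path, validate: bool = True) -> pd.DataFrame:
    """Read a delimited-text cohort (comma default, empty fields = missing)."""
    df = pd.read_csv(path)
    if validate:
        validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def panels_to_frame(panels: Iterable[LipidPanel]) -> pd.DataFrame:
    rows = [
        {"tc": p.tc, "hdl": p.hdl, "tg": p.tg, "ldl_measured": p.ldl_measured}
        for p in panels
    ]
    return pd.DataFrame(rows)
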