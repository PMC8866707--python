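"""Closed-form LDL-C estimators and the adjustable-factor strata table.

Three estimators from the standard fasting lipid panel (all mg/dL):

* Friedewald: ``LDL = TC - HDL - TG/5`` — a fixed 5:1 TG:VLDL-C ratio,
  flagged out-of-validity at TG >= 400 mg/dL.
* Martin adjustable-factor: ``LDL = TC - HDL - TG/f`` where ``f`` is a
  strata-specific median VLDL-C:TG divisor read from a 2-D table indexed
  by TG and non-HDL-C (180 cells by default).
* NIH/Sampson: a bivariate polynomial developed for low LDL-C and
  hypertriglyceridemia.

The table itself can be re-derived from any cohort with directly measured
LDL-C via :class:`AdjustableFactorModel` / :func:`derive_strata_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import LipidPanel, PanelValidationError, validate_cohort

logger = logging.getLogger(__name__)

FRIEDEWALD_TG_LIMIT = 400.0  # mg/dL; estimate still computed, only flagged

__all__ = [
    "friedewald",
    "sampson_nih",
    "martin_adjustable",
    "StrataTable",
    "AdjustableFactorModel",
    "AdjustableFactorResults",
    "derive_strata_table",
    "default_tg_edges",
    "default_nonhdl_edges",
    "FRIEDEWALD_TG_LIMIT",
]


def _unpack(panel):
    """Return validated (tc, hdl, tg, scalar?) arrays from a panel or cohort."""
    if isinstance(panel, LipidPanel):
        panel.validate()
        return (
            np.asarray(panel.tc, dtype=float),
            np.asarray(panel.hdl, dtype=float),
            np.asarray(panel.tg, dtype=float),
            True,
        )
    if isinstance(panel, pd.DataFrame):
        validate_cohort(panel)
        return (
            panel["tc"].to_numpy(dtype=float),
            panel["hdl"].to_numpy(dtype=float),
            panel["tg"].to_numpy(dtype=float),
            False,
        )
    raise TypeError(f"expected LipidPanel or cohort DataFrame, got {type(panel).__name__}")


def _wrap(values: np.ndarray, scalar: bool):
    return float(values) if scalar else values


def friedewald(panel, return_flag: bool = False):
    """Friedewald estimate ``tc - hdl - tg/5``.

    With ``return_flag=True`` also returns a boolean validity flag that is
    False where TG >= 400 mg/dL (the estimate is still computed so that
    whole-range comparisons can include those records).
    """
    tc, hdl, tg, scalar = _unpack(panel)
    est = tc - hdl - tg / 5.0
    if not return_flag:
        return _wrap(est, scalar)
    valid = tg < FRIEDEWALD_TG_LIMIT
    return _wrap(est, scalar), (bool(valid) if scalar else valid)


def sampson_nih(panel):
    """NIH/Sampson estimate.

    ``TC/0.948 - HDL/0.971 - (TG/8.56 + TG*nonHDL/2140 - TG^2/16100) - 9.44``
    with ``nonHDL = TC - HDL``.
    """
    tc, hdl, tg, scalar = _unpack(panel)
    non_hdl = tc - hdl
    est = (
        tc / 0.948
        - hdl / 0.971
        - (tg / 8.56 + tg * non_hdl / 2140.0 - tg**2 / 16100.0)
        - 9.44
    )
    return _wrap(est, scalar)


def default_tg_edges() -> np.ndarray:
    """Interior TG breakpoints giving 30 strata: [0,30), [30,45), ... [450,inf)."""
    return np.arange(30.0, 465.0, 15.0)  # 29 interior edges -> 30 strata


def default_nonhdl_edges() -> np.ndarray:
    """Interior non-HDL-C breakpoints giving 6 strata."""
    return np.array([100.0, 130.0, 160.0, 190.0, 220.0])


@dataclass(frozen=True)
class StrataTable:
    """2-D grid of adjustable VLDL-C:TG divisors indexed by (TG, non-HDL) strata.

    ``tg_edges`` / ``nonhdl_edges`` are ascending *interior* breakpoints;
    strata are left-closed right-open, and values outside every stratum are
    clamped to the nearest edge stratum.  The default geometry is 30 TG x 6
    non-HDL strata = 180 cells.
    """

    tg_edges: np.ndarray
    nonhdl_edges: np.ndarray
    factors: np.ndarray  # shape (n_tg_strata, n_nonhdl_strata)

    def __post_init__(self):
        tg_e = np.asarray(self.tg_edges, dtype=float)
        nh_e = np.asarray(self.nonhdl_edges, dtype=float)
        fac = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "tg_edges", tg_e)
        object.__setattr__(self, "nonhdl_edges", nh_e)
        object.__setattr__(self, "factors", fac)
        if fac.ndim != 2 or fac.shape != (len(tg_e) + 1, len(nh_e) + 1):
            raise ValueError(
                f"factor matrix shape {fac.shape} does not match strata "
                f"({len(tg_e) + 1} x {len(nh_e) + 1})"
            )
        if np.any(np.diff(tg_e) <= 0) or np.any(np.diff(nh_e) <= 0):
            raise ValueError("strata edges must be strictly ascending")
        if not np.all(np.isfinite(fac)) or np.any(fac <= 0):
            raise ValueError("all adjustable factors must be positive and finite")

    @property
    def cell_count(self) -> int:
        return int(self.factors.size)

    @classmethod
    def uniform(cls, factor: float, tg_edges=None, nonhdl_edges=None) -> "StrataTable":
        """A table with the same divisor in every cell (factor 5 == Friedewald)."""
        tg_e = default_tg_edges() if tg_edges is None else np.asarray(tg_edges, float)
        nh_e = default_nonhdl_edges() if nonhdl_edges is None else np.asarray(nonhdl_edges, float)
        return cls(tg_e, nh_e, np.full((len(tg_e) + 1, len(nh_e) + 1), float(factor)))

    def cell_index(self, tg, non_hdl):
        """Left-closed right-open lookup; out-of-range values clamp to edge strata."""
        i = np.searchsorted(self.tg_edges, np.asarray(tg, float), side="right")
        j = np.searchsorted(self.nonhdl_edges, np.asarray(non_hdl, float), side="right")
        return i, j

    def lookup(self, tg, non_hdl):
        i, j = self.cell_index(tg, non_hdl)
        return self.factors[i, j]

    # -- plain-text serialization: two edge lines then the factor matrix ----
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tg_edges," + ",".join(repr(float(x)) for x in self.tg_edges) + "\n")
            fh.write("nonhdl_edges," + ",".join(repr(float(x)) for x in self.nonhdl_edges) + "\n")
            for row in self.factors:
                fh.write(",".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_file(cls, path) -> "StrataTable":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if len(lines) < 3 or not lines[0].startswith("tg_edges,") or not lines[1].startswith("nonhdl_edges,"):
            raise ValueError(f"{path}: not a strata table file")
        tg_e = np.array([float(x) for x in lines[0].split(",")[1:]])
        nh_e = np.array([float(x) for x in lines[1].split(",")[1:]])
        fac = np.array([[float(x) for x in ln.split(",")] for ln in lines[2:]])
        return cls(tg_e, nh_e, fac)


def martin_adjustable(panel, table: StrataTable):
    """Martin-style estimate ``tc - hdl - tg / factor[cell(tg, non_hdl)]``."""
    if table.cell_count < 1:
        raise ValueError("strata table must have at least one cell")
    tc, hdl, tg, scalar = _unpack(panel)
    factor = table.lookup(tg, tc - hdl)
    return _wrap(tc - hdl - tg / factor, scalar)


@dataclass
class AdjustableFactorResults:
    """Fitted strata table plus derivation diagnostics."""

    table: StrataTable
    n_used: int
    n_dropped_nonpositive_vldl: int
    n_filled_cells: int
    cell_counts: np.ndarray = field(repr=False)

    def predict(self, panel):
        return martin_adjustable(panel, self.table)

    def summary(self) -> str:
        t = self.table
        return (
            f"Adjustable-factor strata table: {t.factors.shape[0]} TG x "
            f"{t.factors.shape[1]} non-HDL strata = {t.cell_count} cells\n"
            f"records used: {self.n_used} "
            f"(dropped {self.n_dropped_nonpositive_vldl} with non-positive implied VLDL-C)\n"
            f"empty cells filled from neighbours: {self.n_filled_cells}\n"
            f"factor range: {t.factors.min():.3f} - {t.factors.max():.3f}"
        )


class AdjustableFactorModel:
    """Derive a Martin-style adjustable-factor table from measured-LDL data.

    Each cell's divisor is the median of ``tg / (tc - hdl - ldl_measured)``
    over the records falling in that (TG, non-HDL) stratum; records whose
    implied VLDL-C is non-positive are dropped.  Empty cells are filled from
    the nearest non-empty cell along the TG row first, then down columns.
    """

    def __init__(self, cohort: pd.DataFrame, tg_edges=None, nonhdl_edges=None):
        self.cohort = validate_cohort(cohort, require_measured=True)
        self.tg_edges = default_tg_edges() if tg_edges is None else np.asarray(tg_edges, float)
        self.nonhdl_edges = (
            default_nonhdl_edges() if nonhdl_edges is None else np.asarray(nonhdl_edges, float)
        )

    def fit(self) -> AdjustableFactorResults:
        df = self.cohort
        tc = df["tc"].to_numpy(float)
        hdl = df["hdl"].to_numpy(float)
        tg = df["tg"].to_numpy(float)
        vldl = tc - hdl - df["ldl_measured"].to_numpy(float)
        keep = vldl > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("derive_strata_table: dropped %d records with non-positive implied VLDL-C", n_dropped)
        if not keep.any():
            raise ValueError("no records with positive implied VLDL-C; cannot derive table")
        ratio = tg[keep] / vldl[keep]
        shape = (len(self.tg_edges) + 1, len(self.nonhdl_edges) + 1)
        i = np.searchsorted(self.tg_edges, tg[keep], side="right")
        j = np.searchsorted(self.nonhdl_edges, (tc - hdl)[keep], side="right")
        factors = np.full(shape, np.nan)
        counts = np.zeros(shape, dtype=int)
        flat = i * shape[1] + j
        order = np.argsort(flat, kind="stable")
        flat_sorted = flat[order]
        ratio_sorted = ratio[order]
        starts = np.searchsorted(flat_sorted, np.arange(shape[0] * shape[1]))
        ends = np.searchsorted(flat_sorted, np.arange(shape[0] * shape[1]), side="right")
        for cell in range(shape[0] * shape[1]):
            if ends[cell] > starts[cell]:
                ci, cj = divmod(cell, shape[1])
                factors[ci, cj] = np.median(ratio_sorted[starts[cell]:ends[cell]])
                counts[ci, cj] = ends[cell] - starts[cell]
        if np.all(np.isnan(factors)):
            raise ValueError("all strata cells empty")
        n_filled = self._fill_empty(factors)
        if np.any(factors <= 0):
            raise ValueError("derived a non-positive median factor; data inconsistent with tg/vldl > 0")
        table = StrataTable(self.tg_edges, self.nonhdl_edges, factors)
        return AdjustableFactorResults(
            table=table,
            n_used=int(keep.sum()),
            n_dropped_nonpositive_vldl=n_dropped,
            n_filled_cells=n_filled,
            cell_counts=counts,
        )

    @staticmethod
    def _fill_empty(factors: np.ndarray) -> int:
        """Fill NaN cells from nearest non-empty cell, row-first then column."""
        n_filled = int(np.isnan(factors).sum())
        n_rows, n_cols = factors.shape
        # pass 1: within each TG row, nearest filled column (ties -> lower index)
        filled_row = factors.copy()
        for r in range(n_rows):
            cols = np.where(~np.isnan(factors[r]))[0]
            if len(cols) == 0:
                continue
            for c in range(n_cols):
                if np.isnan(filled_row[r, c]):
                    nearest = cols[np.argmin(np.abs(cols - c))]
                    filled_row[r, c] = factors[r, nearest]
                    logger.debug("filled empty cell (%d,%d) from (%d,%d)", r, c, r, nearest)
        # pass 2: remaining fully-empty rows take the nearest filled row
        rows = np.where(~np.isnan(filled_row).any(axis=1))[0]
        for r in range(n_rows):
            if np.isnan(filled_row[r]).any():
                nearest = rows[np.argmin(np.abs(rows - r))]
                filled_row[r] = filled_row[nearest]
                logger.debug("filled empty row %d from row %d", r, nearest)
        factors[:] = filled_row
        if n_filled:
            logger.info("derive_strata_table: filled %d empty cells from neighbours", n_filled)
        return n_filled


def derive_strata_table(cohort: pd.DataFrame, tg_edges=None, nonhdl_edges=None) -> StrataTable:
    """Functional wrapper around :class:`AdjustableFactorModel`."""
    return AdjustableFactorModel(cohort, tg_edges, nonhdl_edges).fit().table
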