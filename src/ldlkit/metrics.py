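"""Clinical method-comparison metrics.

Four accuracy indices for an estimator against directly measured LDL-C:

* bias — mean of (estimate - measured) with a one-sample t-test against 0;
* RMSE — root mean squared error;
* Pn — fraction of records whose estimate falls within +/- n% of the
  measured value (band closed at the boundary);
* concordance — within each clinical category of measured LDL-C, the
  fraction of records whose estimate lands in the same category.

Plus grouped RMSE over arbitrary strata (TG bins, non-HDL bins, risk
vigintiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryScheme",
    "MetricReport",
    "LDL_SCHEME",
    "TG_SCHEME",
    "NONHDL_SCHEME",
    "bias_stats",
    "rmse",
    "pn_accuracy",
    "concordance",
    "grouped_rmse",
    "evaluate_estimates",
]


@dataclass(frozen=True)
class CategoryScheme:
    """Named ascending breakpoints defining left-closed right-open bins.

    ``breakpoints=[100, 130]`` gives three bins: <100, [100,130), >=130.
    """

    name: str
    breakpoints: tuple

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if len(bp) == 0 or np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be non-empty and strictly increasing")

    @property
    def labels(self) -> list:
        bp = self.breakpoints
        labs = [f"<{bp[0]:g}"]
        labs += [f"[{a:g},{b:g})" for a, b in zip(bp[:-1], bp[1:])]
        labs.append(f">={bp[-1]:g}")
        return labs

    def assign(self, values) -> np.ndarray:
        """Bin index per value (0 .. len(breakpoints))."""
        return np.searchsorted(self.breakpoints, np.asarray(values, float), side="right")


# clinical LDL-C guideline categories (mg/dL); five self-consistent bins
LDL_SCHEME = CategoryScheme("ldl", (100, 130, 160, 190))
# default 50 mg/dL-wide grouping schemes for TG / non-HDL stratified reports
TG_SCHEME = CategoryScheme("tg", (50, 100, 150, 200, 250, 300, 350, 400))
NONHDL_SCHEME = CategoryScheme("non_hdl", (40, 90, 140, 190, 240))


def _paired(estimates, measured, min_n=1):
    est = np.asarray(estimates, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.shape != meas.shape or est.ndim != 1:
        raise ValueError("estimates and measured must be equal-length 1-D vectors")
    if len(est) < min_n:
        raise ValueError(f"need at least {min_n} paired records, got {len(est)}")
    return est, meas


def bias_stats(estimates, measured):
    """Mean error (estimate - measured), one-sample t vs 0, and two-sided p."""
    est, meas = _paired(estimates, measured, min_n=2)
    err = est - meas
    mean = float(err.mean())
    sd = float(err.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.0, 1.0
        return mean, float(np.sign(mean) * np.inf), 0.0
    t, p = stats.ttest_1samp(err, 0.0)
    return mean, float(t), float(p)


def rmse(estimates, measured) -> float:
    """Root mean squared error, mg/dL."""
    est, meas = _paired(estimates, measured, min_n=1)
    return float(np.sqrt(np.mean((est - meas) ** 2)))


def pn_accuracy(estimates, measured, n_percent) -> float:
    """Fraction of records with |estimate - measured| <= (n/100) * measured.

    The tolerance band is closed (boundary counts as inside); every measured
    value must be positive for the relative band to make sense.
    """
    est, meas = _paired(estimates, measured, min_n=1)
    if np.any(meas <= 0):
        raise ValueError("pn_accuracy requires all measured values > 0")
    band = (n_percent / 100.0) * meas
    return float(np.mean(np.abs(est - meas) <= band))


def concordance(estimates, measured, scheme: CategoryScheme = LDL_SCHEME) -> dict:
    """Per-category classification agreement.

    For each category c of *measured* values: |{measured in c and estimate
    in c}| / |{measured in c}|.  Categories with no measured records are
    reported as NaN (undefined, distinct from 0).  The ``"overall"`` entry
    is the plain fraction of records whose estimate lands in the same
    category as its measurement.
    """
    est, meas = _paired(estimates, measured, min_n=1)
    est_cat = scheme.assign(est)
    meas_cat = scheme.assign(meas)
    agree = est_cat == meas_cat
    out: dict = {}
    for k, label in enumerate(scheme.labels):
        in_cat = meas_cat == k
        n_cat = int(in_cat.sum())
        out[label] = float(agree[in_cat].sum() / n_cat) if n_cat else float("nan")
    out["overall"] = float(agree.mean())
    return out


def grouped_rmse(estimates, measured, group_labels) -> pd.DataFrame:
    """RMSE within each group; returns a (group, n, rmse) table ordered by label.

    Empty groups are omitted (pandas drops them; a log line records the fact
    when the label set is categorical with unobserved levels).
    """
    est, meas = _paired(estimates, measured, min_n=1)
    labels = np.asarray(group_labels)
    if len(labels) != len(est):
        raise ValueError("group labels must align with the paired vectors")
    df = pd.DataFrame({"group": labels, "sq": (est - meas) ** 2})
    agg = df.groupby("group", observed=True, sort=True)["sq"].agg(["size", "mean"]).reset_index()
    agg["rmse"] = np.sqrt(agg["mean"])
    out = agg[["group", "size", "rmse"]].rename(columns={"size": "n"})
    return out.reset_index(drop=True)


@dataclass
class MetricReport:
    """All four accuracy indices for one estimator on one dataset."""

    method_name: str
    n: int
    bias_mean: float
    bias_t: float
    bias_p: float
    rmse: float
    p10: float
    p15: float
    p20: float
    concordance: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "method": self.method_name,
            "n": self.n,
            "bias_mean": self.bias_mean,
            "bias_t": self.bias_t,
            "bias_p": self.bias_p,
            "rmse": self.rmse,
            "p10": self.p10,
            "p15": self.p15,
            "p20": self.p20,
        }
        for label, value in self.concordance.items():
            row[f"concordance_{label}"] = value
        return row


def evaluate_estimates(method_name, estimates, measured, scheme: CategoryScheme = LDL_SCHEME) -> MetricReport:
    """Compute the full MetricReport for one estimator on one dataset."""
    est, meas = _paired(estimates, measured, min_n=2)
    bias_mean, bias_t, bias_p = bias_stats(est, meas)
    return MetricReport(
        method_name=method_name,
        n=len(est),
        bias_mean=bias_mean,
        bias_t=bias_t,
        bias_p=bias_p,
        rmse=rmse(est, meas),
        p10=pn_accuracy(est, meas, 10),
        p15=pn_accuracy(est, meas, 15),
        p20=pn_accuracy(est, meas, 20),
        concordance=concordance(est, meas, scheme),
    )


def reports_to_frame(reports) -> pd.DataFrame:
    """Stable-column table of MetricReports (one row per method)."""
    rows = [r.to_row() for r in reports]
    return pd.DataFrame(rows)
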