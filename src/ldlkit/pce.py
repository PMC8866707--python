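"""Pooled-cohort-equation 10-year ASCVD risk and quantile stratification.

Risk is computed from a pluggable coefficient file (sex-specific term
lists with declared transforms) so revised-PCE coefficient sets can be
swapped in without code changes.  The packaged default coefficient set is
SYNTHETIC and marked NOT-CLINICAL: it has plausible signs and magnitudes
for structural and monotonicity validation only.

Risk uses total and HDL cholesterol, never an estimated LDL, so risk
strata are independent of the estimator under evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

ALLOWED_TRANSFORMS = ("identity", "log", "square", "product")
SEXES = ("female", "male")

COVARIATE_RANGES = {"age": (20.0, 79.0)}  # default plausibility window, years

__all__ = [
    "PceCoefficients",
    "CoefficientError",
    "load_coefficients",
    "pce_risk",
    "vigintile_bins",
    "ALLOWED_TRANSFORMS",
]


class CoefficientError(ValueError):
    """A coefficient file failed schema validation."""


@dataclass(frozen=True)
class PceTerm:
    variables: tuple
    transform: str
    coefficient: float

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for v in self.variables:
            if v not in df.columns:
                raise CoefficientError(f"missing covariate column '{v}'")
            cols.append(df[v].to_numpy(dtype=float))
        if self.transform == "identity":
            value = cols[0]
        elif self.transform == "log":
            if np.any(cols[0] <= 0):
                raise CoefficientError(f"log transform of non-positive '{self.variables[0]}'")
            value = np.log(cols[0])
        elif self.transform == "square":
            value = cols[0] ** 2
        elif self.transform == "product":
            value = cols[0] * cols[1]
        else:  # unreachable after validation
            raise CoefficientError(f"unknown transform '{self.transform}'")
        return self.coefficient * value


@dataclass(frozen=True)
class PceCoefficients:
    """Sex-specific linear-predictor terms plus the model-form link."""

    model_form: str  # "revised-logistic" | "original-cox-style"
    intercepts: dict  # sex -> float
    terms: dict  # sex -> tuple of PceTerm
    name: str = "unnamed"

    @classmethod
    def from_dict(cls, raw: dict, name: str = "unnamed") -> "PceCoefficients":
        if not isinstance(raw, dict):
            raise CoefficientError("coefficient file must be a mapping")
        form = raw.get("model_form")
        if form not in ("revised-logistic", "original-cox-style"):
            raise CoefficientError(f"model_form must be revised-logistic or original-cox-style, got {form!r}")
        sexes = raw.get("sexes")
        if not isinstance(sexes, dict) or set(sexes) != set(SEXES):
            raise CoefficientError(f"coefficient file must define exactly the sexes {SEXES}")
        intercepts, terms = {}, {}
        for sex, block in sexes.items():
            try:
                intercepts[sex] = float(block["intercept"])
            except (KeyError, TypeError, ValueError) as exc:
                raise CoefficientError(f"{sex}: missing or non-numeric intercept") from exc
            parsed = []
            for i, t in enumerate(block.get("terms", [])):
                transform = t.get("transform")
                if transform not in ALLOWED_TRANSFORMS:
                    raise CoefficientError(
                        f"{sex} term {i}: transform {transform!r} not in {ALLOWED_TRANSFORMS}"
                    )
                variables = tuple(t.get("variables", []))
                need = 2 if transform == "product" else 1
                if len(variables) != need:
                    raise CoefficientError(
                        f"{sex} term {i}: transform '{transform}' needs {need} variable(s)"
                    )
                try:
                    coef = float(t["coefficient"])
                except (KeyError, TypeError, ValueError) as exc:
                    raise CoefficientError(f"{sex} term {i}: missing or non-numeric coefficient") from exc
                parsed.append(PceTerm(variables, transform, coef))
            terms[sex] = tuple(parsed)
        return cls(model_form=form, intercepts=intercepts, terms=terms, name=name)


def load_coefficients(path=None) -> PceCoefficients:
    """Load and validate a coefficient file; default is the packaged synthetic set."""
    if path is None:
        text = resources.files("ldlkit.data").joinpath("pce_synthetic_placeholder.yaml").read_text()
        name = "pce_synthetic_placeholder"
    else:
        with open(path) as fh:
            text = fh.read()
        name = str(path)
    return PceCoefficients.from_dict(yaml.safe_load(text), name=name)


def _linear_predictor(df: pd.DataFrame, coefs: PceCoefficients) -> np.ndarray:
    sex = df["sex"].astype(str).str.lower().to_numpy()
    unknown = set(np.unique(sex)) - set(SEXES)
    if unknown:
        raise CoefficientError(f"unknown sex values {sorted(unknown)}; expected {SEXES}")
    lp = np.empty(len(df), dtype=float)
    for s in SEXES:
        mask = sex == s
        if not mask.any():
            continue
        sub = df.loc[mask]
        val = np.full(mask.sum(), coefs.intercepts[s])
        for term in coefs.terms[s]:
            val = val + term.evaluate(sub)
        lp[mask] = val
    return lp


def pce_risk(profiles: pd.DataFrame, coefs: PceCoefficients) -> np.ndarray:
    """10-year ASCVD risk per row, in [0, 1].

    Requires complete covariates (age, sex, sbp, bp_treated, diabetes,
    smoker, tc, hdl as used by the coefficient file's terms).  Both model
    forms map the sex-specific linear predictor through the inverse logit;
    for a Cox-style set the result is interpretable only comparatively.
    """
    required = {"sex"}
    for s in SEXES:
        for term in coefs.terms[s]:
            required.update(term.variables)
    missing = sorted(required - set(profiles.columns))
    if missing:
        raise CoefficientError(f"missing covariate column(s): {missing}")
    for col, (lo, hi) in COVARIATE_RANGES.items():
        if col in profiles.columns:
            v = profiles[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(v)):
                raise CoefficientError(f"covariate '{col}' has missing values")
    lp = _linear_predictor(profiles, coefs)
    with np.errstate(over="ignore"):
        risk = 1.0 / (1.0 + np.exp(-lp))
    return risk


def vigintile_bins(risks, n_bins: int = 20) -> np.ndarray:
    """Equal-frequency risk bins, labels 1..n_bins (1 = lowest risk).

    Ties are broken by stable record order; bin sizes differ by at most one,
    with the larger bins first.
    """
    risks = np.asarray(risks, dtype=float)
    n = len(risks)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} records for {n_bins} bins; got {n} (use fewer bins)")
    order = np.argsort(risks, kind="stable")
    labels = np.empty(n, dtype=int)
    base, extra = divmod(n, n_bins)
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        labels[order[start:start + size]] = b + 1
        start += size
    return labels
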