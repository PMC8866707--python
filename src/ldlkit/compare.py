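"""End-to-end estimator comparison on synthetic cohorts.

``ComparisonStudy(config).fit()`` reproduces the full study flow:

1. generate a derivation-population cohort, apply the exclusion sequence,
   and split it 70/30 into derivation and internal validation sets;
2. derive a Martin-style adjustable-factor strata table from the
   derivation set;
3. run the pyramid-MLP architecture search (k-fold CV per depth class on
   the derivation set, tournament final on the internal validation set);
4. only then generate the external-population cohort and evaluate all
   four estimators (Friedewald, NIH/Sampson, Martin table, MLP) on the
   internal and external sets: bias/t, RMSE, P10-P20, concordance, plus
   grouped RMSE by TG, non-HDL and ASCVD-risk vigintile.

The report bundle is a pure function of the configuration: identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import equations, metrics, pce
from .dnn import DnnConfig, DnnLdlModel
from .simulate import (
    CohortParams,
    FactorModel,
    apply_exclusions,
    generate_cohort,
    external_params,
    split_cohort,
)


def _normalize_overrides(overrides: dict) -> dict:
    """YAML-loaded overrides carry factor_model as a plain mapping."""
    out = dict(overrides)
    fm = out.get("factor_model")
    if isinstance(fm, dict):
        out["factor_model"] = FactorModel(**fm)
    return out

logger = logging.getLogger(__name__)

METHODS = ("friedewald", "sampson_nih", "martin", "dnn")

__all__ = ["RunConfig", "ComparisonStudy", "ComparisonResults", "run_comparison"]


@dataclass(frozen=True)
class RunConfig:
    """Everything the comparison pipeline needs; round-trips through YAML."""

    seed: int = 1
    n_cohort: int = 50_000
    n_external: int = 20_000
    split_fractions: tuple = (0.7, 0.3)
    dnn: DnnConfig = field(
        default_factory=lambda: DnnConfig(per_depth_caps={6: 10, 4: 20, 2: 30})
    )
    cohort_overrides: dict = field(default_factory=dict)
    external_overrides: dict = field(default_factory=dict)
    risk_vigintiles: int = 20
    pce_path: str | None = None  # None -> packaged synthetic placeholder
    use_pce: bool = True

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["split_fractions"] = list(self.split_fractions)
        raw["dnn"] = asdict(self.dnn)
        for key in ("depth_classes", "node_grid", "features"):
            raw["dnn"][key] = list(raw["dnn"][key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dnn_raw = raw.pop("dnn", {})
        for key in ("depth_classes", "node_grid", "features"):
            if key in dnn_raw:
                dnn_raw[key] = tuple(dnn_raw[key])
        if dnn_raw.get("per_depth_caps"):
            dnn_raw["per_depth_caps"] = {int(k): int(v) for k, v in dnn_raw["per_depth_caps"].items()}
        raw["split_fractions"] = tuple(raw.get("split_fractions", (0.7, 0.3)))
        return cls(dnn=DnnConfig(**dnn_raw), **raw)

    def config_hash(self) -> str:
        raw = asdict(self)
        return hashlib.sha256(json.dumps(raw, sort_keys=True, default=list).encode()).hexdigest()[:16]


@dataclass
class ComparisonResults:
    """Report bundle of one comparison run."""

    config: RunConfig
    strata_results: equations.AdjustableFactorResults
    dnn_results: object
    reports: dict  # dataset name -> list[MetricReport]
    grouped: dict  # table name -> DataFrame
    manifest: dict
    stage_log: list

    def summary(self) -> str:
        lines = [
            f"Estimator comparison (config {self.manifest['config_hash']}, seed {self.config.seed})",
            f"derivation n={self.manifest['n_derivation']}, internal n={self.manifest['n_internal']}, "
            f"external n={self.manifest['n_external']}",
            f"selected MLP architecture: {self.dnn_results.final.candidate.widths}",
        ]
        for dataset, reports in self.reports.items():
            lines.append(f"\n{dataset} validation set:")
            frame = metrics.reports_to_frame(reports)
            cols = ["method", "n", "bias_mean", "bias_t", "rmse", "p10", "p15", "p20", "concordance_overall"]
            lines.append(frame[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
        return "\n".join(lines)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for dataset, reports in self.reports.items():
            metrics.reports_to_frame(reports).to_csv(out / f"metrics_{dataset}.csv", index=False)
        for name, table in self.grouped.items():
            table.to_csv(out / f"{name}.csv", index=False)
        self.strata_results.table.to_file(out / "strata_table.csv")
        self.dnn_results.final.save(out / "dnn_model.json")
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")


class ComparisonStudy:
    """Model object for the full synthetic-cohort estimator comparison."""

    def __init__(self, config: RunConfig = RunConfig()):
        self.config = config
        self._stage_log: list = []

    def _stage(self, name: str, **info) -> None:
        entry = {"stage": name, **info}
        self._stage_log.append(entry)
        logger.info("stage %s: %s", name, info)

    def fit(self) -> ComparisonResults:
        cfg = self.config
        seed = cfg.seed

        self._stage("simulate", n=cfg.n_cohort, seed=seed)
        cohort = generate_cohort(
            CohortParams(n=cfg.n_cohort, seed=seed, **_normalize_overrides(cfg.cohort_overrides))
        )

        retained, counts = apply_exclusions(cohort)
        self._stage(
            "exclude",
            n_in=counts.n_input,
            removed=[counts.removed_demographics, counts.removed_lifestyle, counts.removed_laboratory],
            n_out=counts.n_retained,
        )

        derivation, internal = split_cohort(retained, cfg.split_fractions, seed=seed + 1)
        self._stage("split", n_derivation=len(derivation), n_internal=len(internal))

        self._stage("derive_table", n=len(derivation))
        strata_results = equations.AdjustableFactorModel(derivation).fit()

        self._stage("train_dnn", candidates="pyramid", seed=seed + 2)
        dnn_results = DnnLdlModel(derivation, internal, cfg.dnn).fit(seed=seed + 2)

        # the external cohort is generated only now, after all fitting is done
        self._stage("simulate_external", n=cfg.n_external, seed=seed + 3)
        external = generate_cohort(
            external_params(cfg.n_external, seed + 3, **_normalize_overrides(cfg.external_overrides))
        )

        self._stage("evaluate")
        reports, grouped = {}, {}
        for dataset, df in (("internal", internal), ("external", external)):
            measured = df["ldl_measured"].to_numpy(float)
            estimates = self._estimates(df, strata_results, dnn_results)
            reports[dataset] = [
                metrics.evaluate_estimates(name, est, measured) for name, est in estimates.items()
            ]
            for scheme, col in ((metrics.TG_SCHEME, "tg"), (metrics.NONHDL_SCHEME, "non_hdl")):
                labels = np.asarray(scheme.labels)[scheme.assign(df[col])]
                grouped[f"rmse_by_{scheme.name}_{dataset}"] = self._grouped_table(
                    estimates, measured, labels, group_name=scheme.name
                )
        risk_note = None
        if cfg.use_pce:
            coefs = pce.load_coefficients(cfg.pce_path)
            risks = pce.pce_risk(external, coefs)
            bins = pce.vigintile_bins(risks, cfg.risk_vigintiles)
            estimates = self._estimates(external, strata_results, dnn_results)
            grouped["rmse_by_risk_vigintile_external"] = self._grouped_table(
                estimates, external["ldl_measured"].to_numpy(float), bins, group_name="vigintile"
            )
        else:
            risk_note = "risk-stratified table skipped: no PCE coefficients configured"
            logger.warning(risk_note)

        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_cohort": counts.n_input,
            "n_retained": counts.n_retained,
            "n_derivation": len(derivation),
            "n_internal": len(internal),
            "n_external": len(external),
            "selected_widths": list(dnn_results.final.candidate.widths),
            "stages": [s["stage"] for s in self._stage_log],
        }
        if risk_note:
            manifest["risk_note"] = risk_note
        return ComparisonResults(
            config=cfg,
            strata_results=strata_results,
            dnn_results=dnn_results,
            reports=reports,
            grouped=grouped,
            manifest=manifest,
            stage_log=self._stage_log,
        )

    @staticmethod
    def _estimates(df, strata_results, dnn_results) -> dict:
        return {
            "friedewald": equations.friedewald(df),
            "sampson_nih": equations.sampson_nih(df),
            "martin": equations.martin_adjustable(df, strata_results.table),
            "dnn": dnn_results.predict(df),
        }

    @staticmethod
    def _grouped_table(estimates, measured, labels, group_name="group") -> pd.DataFrame:
        parts = []
        for name, est in estimates.items():
            t = metrics.grouped_rmse(est, measured, labels)
            t.insert(0, "method", name)
            parts.append(t)
        out = pd.concat(parts, ignore_index=True).rename(columns={"group": group_name})
        return out


def run_comparison(config: RunConfig = RunConfig()) -> ComparisonResults:
    """Functional wrapper: run the full comparison and return the results."""
    return ComparisonStudy(config).fit()
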