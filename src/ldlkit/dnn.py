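"""Pyramid-MLP LDL-C estimator with cross-validated tournament selection.

The search space is the set of fully connected "pyramid" architectures:
hidden-layer width sequences that never increase with depth, drawn from a
node grid (default {10, 20, 30}) at each of the configured depth classes
(default 2, 4 and 6 hidden layers).  Selection is two-stage:

1. *Per-depth round*: every candidate of a depth class is scored by k-fold
   (default 10) cross-validated mean squared error on the derivation set,
   with the same seed-driven fold partition for all candidates; the
   lowest-MSE candidate of each depth advances.
2. *Tournament final*: each depth winner is refitted on the full
   derivation set and scored on the internal validation set; the lowest
   validation MSE wins, ties broken toward fewer parameters, then fewer
   layers.

Training is a standard regression MLP: rectifier hidden units, a single
linear output, mean-squared-error loss minimised by Adam with mini-batches
and early stopping on a 10% inner holdout of the training partition.
Feature and target standardisation are learned on the training partition
only.  Prediction runs our own forward pass from the stored weights, so a
saved and reloaded model predicts bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .panels import PanelValidationError

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = ("tc", "hdl", "tg")

__all__ = [
    "DnnCandidate",
    "DnnConfig",
    "TrainedEstimator",
    "enumerate_candidates",
    "crossval_select",
    "tournament_final",
    "fit_predict",
    "DnnLdlModel",
    "DnnLdlResults",
]


@dataclass(frozen=True, order=True)
class DnnCandidate:
    """A hidden-layer width sequence obeying the pyramid (non-increasing) constraint."""

    widths: tuple

    def __post_init__(self):
        w = tuple(int(x) for x in self.widths)
        object.__setattr__(self, "widths", w)
        if len(w) == 0 or any(x <= 0 for x in w):
            raise ValueError("widths must be a non-empty sequence of positive ints")
        if any(a < b for a, b in zip(w, w[1:])):
            raise ValueError(f"pyramid constraint violated: widths {w} must be non-increasing")

    @property
    def depth(self) -> int:
        return len(self.widths)

    def n_parameters(self, n_features: int) -> int:
        dims = (n_features, *self.widths, 1)
        return sum(a * b + b for a, b in zip(dims, dims[1:]))


@dataclass(frozen=True)
class DnnConfig:
    """Search-space and training configuration."""

    depth_classes: tuple = (2, 4, 6)
    node_grid: tuple = (10, 20, 30)
    per_depth_caps: dict | None = None  # e.g. {6: 10, 4: 20, 2: 30}
    k_folds: int = 10
    features: tuple = DEFAULT_FEATURES
    max_epochs: int = 60
    final_max_epochs: int = 200
    early_stop_patience: int = 8
    batch_size: int = 512
    learning_rate: float = 1e-3
    alpha: float = 1e-4  # L2 penalty

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def enumerate_candidates(depth_classes, node_grid=None, per_depth_caps=None) -> list:
    """All pyramid width sequences for each depth class, deduplicated.

    Order is deterministic: by depth, then ascending tuple order.  With
    ``per_depth_caps`` the grid for a depth class is restricted to widths
    at or below that depth's cap (the per-depth reading of the candidate
    grid); otherwise one shared grid is used for every depth.
    """
    grid = tuple(sorted(set(int(g) for g in (node_grid or ()))))
    if not grid:
        raise ValueError("node grid must be non-empty")
    depths = sorted(set(int(d) for d in depth_classes))
    if not depths:
        raise ValueError("depth class set must be non-empty")
    out = []
    for d in depths:
        g = grid
        if per_depth_caps and d in per_depth_caps:
            g = tuple(x for x in grid if x <= per_depth_caps[d])
            if not g:
                raise ValueError(f"per-depth cap {per_depth_caps[d]} excludes every grid width")
        # non-increasing sequences of length d == multisets of the grid
        seqs = {tuple(sorted(c, reverse=True)) for c in combinations_with_replacement(g, d)}
        out.extend(DnnCandidate(w) for w in sorted(seqs))
    return out


@dataclass
class TrainedEstimator:
    """A fitted pyramid MLP with its standardisation, ready to predict."""

    candidate: DnnCandidate
    input_features: tuple
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    coefs: list  # per-layer weight matrices
    intercepts: list  # per-layer bias vectors
    training_seed: int
    cv_mse: float | None = None

    def _design(self, panels: pd.DataFrame) -> np.ndarray:
        for feat in self.input_features:
            if feat not in panels.columns:
                raise PanelValidationError(feat, "required model feature missing from cohort")
        return panels.loc[:, list(self.input_features)].to_numpy(dtype=float)

    def predict(self, panels: pd.DataFrame) -> np.ndarray:
        """Deterministic forward pass: standardise, relu layers, linear output."""
        h = (self._design(panels) - self.x_center) / self.x_scale
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        out = h @ self.coefs[-1] + self.intercepts[-1]
        return out.ravel() * self.y_scale + self.y_center

    def n_parameters(self) -> int:
        return self.candidate.n_parameters(len(self.input_features))

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "widths": list(self.candidate.widths),
            "input_features": list(self.input_features),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center,
            "y_scale": self.y_scale,
            "coefs": [W.tolist() for W in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "training_seed": self.training_seed,
            "cv_mse": self.cv_mse,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedEstimator":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            candidate=DnnCandidate(tuple(payload["widths"])),
            input_features=tuple(payload["input_features"]),
            x_center=np.array(payload["x_center"], dtype=float),
            x_scale=np.array(payload["x_scale"], dtype=float),
            y_center=float(payload["y_center"]),
            y_scale=float(payload["y_scale"]),
            coefs=[np.array(W, dtype=float) for W in payload["coefs"]],
            intercepts=[np.array(b, dtype=float) for b in payload["intercepts"]],
            training_seed=int(payload["training_seed"]),
            cv_mse=payload["cv_mse"],
        )


def _design_matrix(cohort: pd.DataFrame, features) -> tuple[np.ndarray, np.ndarray]:
    for feat in features:
        if feat not in cohort.columns:
            raise PanelValidationError(feat, "required model feature missing from cohort")
    if "ldl_measured" not in cohort.columns:
        raise PanelValidationError("ldl_measured", "training requires measured LDL")
    X = cohort.loc[:, list(features)].to_numpy(dtype=float)
    y = cohort["ldl_measured"].to_numpy(dtype=float)
    return X, y


def _fit_mlp(
    X: np.ndarray,
    y: np.ndarray,
    candidate: DnnCandidate,
    seed: int,
    cfg: DnnConfig,
    max_epochs: int | None = None,
) -> TrainedEstimator:
    """Fit one architecture; standardisation learned on this partition only."""
    x_center = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_center = float(y.mean())
    y_scale = float(y.std()) or 1.0
    if y.std() == 0:
        logger.warning("degenerate target (zero variance); fitting a constant-capable model anyway")
    Xs = (X - x_center) / x_scale
    ys = (y - y_center) / y_scale
    mlp = MLPRegressor(
        hidden_layer_sizes=candidate.widths,
        activation="relu",
        solver="adam",
        alpha=cfg.alpha,
        batch_size=min(cfg.batch_size, len(X)),
        learning_rate_init=cfg.learning_rate,
        max_iter=max_epochs or cfg.max_epochs,
        shuffle=True,
        random_state=seed,
        early_stopping=len(X) >= 50,
        validation_fraction=0.1,
        n_iter_no_change=cfg.early_stop_patience,
        tol=1e-5,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at the epoch cap are expected
        mlp.fit(Xs, ys)
    return TrainedEstimator(
        candidate=candidate,
        input_features=tuple(cfg.features),
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        coefs=[np.asarray(W, dtype=float) for W in mlp.coefs_],
        intercepts=[np.asarray(b, dtype=float) for b in mlp.intercepts_],
        training_seed=seed,
        cv_mse=None,
    )


def crossval_select(
    candidates,
    derivation: pd.DataFrame,
    k: int | None = None,
    seed: int = 0,
    config: DnnConfig = DnnConfig(),
) -> tuple[dict, pd.DataFrame]:
    """k-fold CV of every candidate on the derivation set; one winner per depth.

    The fold partition is identical across candidates (same seed).  Returns
    ``(winners, table)`` where ``winners`` maps depth -> (candidate, cv_mse)
    and ``table`` lists every candidate's cv_mse.
    """
    k = k or config.k_folds
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to select from")
    X, y = _design_matrix(derivation, config.features)
    if len(X) < k:
        raise ValueError(f"derivation set of {len(X)} records cannot support {k} folds")
    if y.std() == 0:
        logger.warning("derivation target has zero variance; selection proceeds on MSE")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))
    rows = []
    for cand in candidates:
        fold_mse = []
        for f, (tr, te) in enumerate(folds):
            est = _fit_mlp(X[tr], y[tr], cand, seed=seed + f, cfg=config)
            pred = est.predict(derivation.iloc[te])
            fold_mse.append(float(np.mean((pred - y[te]) ** 2)))
        cv_mse = float(np.mean(fold_mse))
        rows.append({"widths": cand.widths, "depth": cand.depth, "cv_mse": cv_mse})
        logger.info("cv %s: mse=%.4f", cand.widths, cv_mse)
    table = pd.DataFrame(rows)
    winners: dict = {}
    n_feat = X.shape[1]
    for depth in sorted({c.depth for c in candidates}):
        sub = [(r["cv_mse"], DnnCandidate(r["widths"])) for r in rows if r["depth"] == depth]
        # argmin with ties toward fewer parameters, then enumeration order
        best = min(
            range(len(sub)),
            key=lambda i: (sub[i][0], sub[i][1].n_parameters(n_feat), i),
        )
        winners[depth] = (sub[best][1], sub[best][0])
    return winners, table


def tournament_final(
    depth_winners,
    derivation: pd.DataFrame,
    internal_validation: pd.DataFrame,
    seed: int = 0,
    config: DnnConfig = DnnConfig(),
) -> tuple[TrainedEstimator, pd.DataFrame]:
    """Refit each finalist on the full derivation set and pick the lowest
    internal-validation MSE; ties break toward fewer parameters, then fewer
    layers.  ``depth_winners`` is a list of (candidate, cv_mse) pairs (or the
    dict from :func:`crossval_select`)."""
    if isinstance(depth_winners, dict):
        finalists = [depth_winners[d] for d in sorted(depth_winners)]
    else:
        finalists = list(depth_winners)
    if not finalists:
        raise ValueError("tournament needs at least one finalist")
    if len(internal_validation) == 0:
        raise ValueError("internal validation set is empty")
    X, y = _design_matrix(derivation, config.features)
    y_val = internal_validation["ldl_measured"].to_numpy(dtype=float)
    fitted, rows = [], []
    n_feat = len(config.features)
    for cand, cv_mse in finalists:
        est = _fit_mlp(X, y, cand, seed=seed, cfg=config, max_epochs=config.final_max_epochs)
        est.cv_mse = cv_mse
        val_mse = float(np.mean((est.predict(internal_validation) - y_val) ** 2))
        fitted.append((est, val_mse))
        rows.append({"widths": cand.widths, "depth": cand.depth, "cv_mse": cv_mse, "val_mse": val_mse})
        logger.info("tournament %s: validation mse=%.4f", cand.widths, val_mse)
    best = min(
        range(len(fitted)),
        key=lambda i: (
            fitted[i][1],
            fitted[i][0].candidate.n_parameters(n_feat),
            fitted[i][0].candidate.depth,
            i,
        ),
    )
    return fitted[best][0], pd.DataFrame(rows)


def fit_predict(model: TrainedEstimator, panels: pd.DataFrame) -> np.ndarray:
    """Apply a trained estimator to a cohort (row-wise, deterministic)."""
    return model.predict(panels)


@dataclass
class DnnLdlResults:
    """Outcome of the full enumerate -> cross-validate -> tournament pipeline."""

    final: TrainedEstimator
    cv_table: pd.DataFrame
    tournament_table: pd.DataFrame
    config: DnnConfig
    seed: int

    def predict(self, panels: pd.DataFrame) -> np.ndarray:
        return self.final.predict(panels)

    def summary(self) -> str:
        w = self.final.candidate.widths
        lines = [
            f"Pyramid-MLP LDL-C estimator (features: {', '.join(self.final.input_features)})",
            f"selected architecture: {w} ({self.final.n_parameters()} parameters)",
            f"cross-validated MSE at selection: {self.final.cv_mse:.4f}",
            "tournament round (internal-validation MSE):",
        ]
        for _, row in self.tournament_table.iterrows():
            lines.append(f"  {tuple(row['widths'])}: cv={row['cv_mse']:.4f}  val={row['val_mse']:.4f}")
        return "\n".join(lines)


class DnnLdlModel:
    """Model object running the full architecture search on given partitions.

    ``DnnLdlModel(derivation, internal_validation).fit(seed)`` enumerates the
    pyramid candidates, cross-validates them per depth class on the
    derivation set, and runs the tournament final on the internal validation
    set.  The external validation set is never an input here by design.
    """

    def __init__(
        self,
        derivation: pd.DataFrame,
        internal_validation: pd.DataFrame,
        config: DnnConfig = DnnConfig(),
    ):
        self.derivation = derivation
        self.internal_validation = internal_validation
        self.config = config

    def fit(self, seed: int = 0) -> DnnLdlResults:
        cfg = self.config
        candidates = enumerate_candidates(cfg.depth_classes, cfg.node_grid, cfg.per_depth_caps)
        logger.info("enumerated %d pyramid candidates", len(candidates))
        winners, cv_table = crossval_select(candidates, self.derivation, cfg.k_folds, seed, cfg)
        final, tour_table = tournament_final(
            winners, self.derivation, self.internal_validation, seed=seed, config=cfg
        )
        return DnnLdlResults(final=final, cv_table=cv_table, tournament_table=tour_table, config=cfg, seed=seed)
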