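"""Single-response NIPALS partial least squares for sugar calibration.

One PLS model is fit per monosaccharide, regressing preprocessed spectra
(channels as predictors) on mol% of that sugar.  NIPALS extracts latent
components one at a time: each weight vector is the direction of maximum
covariance between the deflated spectra and the response residual.  With
as many components as the rank of X, PLS prediction coincides with
ordinary least squares; fewer components regularize the fit, which is why
each sugar carries its own component count.

Model quality is assessed by seeded K-fold cross-validation: per-fold
RMSEP (root mean square error of prediction on the held-out fold) and a
pooled predicted-vs-measured R^2 over all sugars, computed as the squared
Pearson correlation of the held-out pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "CVConfig",
    "CalibrationReport",
    "DEFAULT_COMPONENTS",
    "fit_pls",
    "predict_pls",
    "kfold_cv",
    "fit_sugar_models",
]

#: per-sugar latent-component counts used for the rice leaf calibration
DEFAULT_COMPONENTS = {"Ara": 8, "Gal": 7, "Glc": 11, "Xyl": 10}


@dataclass
class PLSModel:
    """Fitted single-response PLS regression for one sugar."""

    sugar: str
    n_components: int
    x_weights: np.ndarray  # components x channels
    x_loadings: np.ndarray  # components x channels
    y_loadings: np.ndarray  # per component
    coefficients: np.ndarray  # per channel
    x_mean: np.ndarray
    y_mean: float

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("x_weights", "x_loadings", "y_loadings", "coefficients", "x_mean"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            sugar=d["sugar"],
            n_components=int(d["n_components"]),
            x_weights=np.asarray(d["x_weights"], float),
            x_loadings=np.asarray(d["x_loadings"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            coefficients=np.asarray(d["coefficients"], float),
            x_mean=np.asarray(d["x_mean"], float),
            y_mean=float(d["y_mean"]),
        )


@dataclass
class CVConfig:
    """K-fold cross-validation settings (seeded random partition)."""

    K: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")


@dataclass
class CalibrationReport:
    """Cross-validated calibration summary across sugars."""

    per_sugar_rmsep: dict[str, float]  # mean RMSEP over folds, mol%
    per_sugar_components: dict[str, int]
    per_sugar_r2: dict[str, float]
    pooled_pairs: pd.DataFrame  # columns: sugar, sample_index, predicted, measured
    pooled_r2: float  # squared Pearson correlation, held-out pairs
    pooled_r2_regression: float = 0.0
    dropped_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_sugar_rmsep": {k: float(v) for k, v in self.per_sugar_rmsep.items()},
            "per_sugar_components": dict(self.per_sugar_components),
            "per_sugar_r2": {k: float(v) for k, v in self.per_sugar_r2.items()},
            "pooled_r2": float(self.pooled_r2),
            "pooled_r2_regression": float(self.pooled_r2_regression),
            "n_pooled_pairs": int(len(self.pooled_pairs)),
            "dropped_samples": list(self.dropped_samples),
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
        self.pooled_pairs.to_csv(path.with_suffix(".pairs.csv"), index=False, float_format="%.17g")


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int, sugar: str = "y") -> PLSModel:
    """Fit a single-response PLS model by NIPALS.

    Columns of X and y are centered internally; centering terms are stored
    on the model so prediction is self-contained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"{n} spectra but {y.size} responses")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} invalid for {n} samples x {p} channels"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((n_components, p))
    P = np.zeros((n_components, p))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            # residual X carries no covariance with y; stop deflating
            W, P, q = W[: a], P[: a], q[: a]
            n_components = a
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-14:
            W, P, q = W[: a], P[: a], q[: a]
            n_components = a
            break
        P[a] = (Xd.T @ t) / tt
        q[a] = float(yd @ t) / tt
        W[a] = w
        Xd = Xd - np.outer(t, P[a])
        yd = yd - q[a] * t
    if n_components == 0:
        raise ValueError("no usable PLS component (X uncorrelated with y)")
    # regression vector: b = W^T (P W^T)^-1 q   (rows of W, P are components)
    R = np.linalg.solve(P @ W.T, q)
    coefficients = W.T @ R
    return PLSModel(
        sugar=sugar,
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coefficients,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def predict_pls(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict mol% for spectra on the model's grid and preprocessing.

    Predictions are reported raw; negative mol% triggers a warning but is
    not clipped (clipping would silently bias percent differences).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"spectra have {X.shape[1]} channels, model expects {model.x_mean.size}"
        )
    yhat = (X - model.x_mean) @ model.coefficients + model.y_mean
    if np.any(yhat < 0):
        warnings.warn(
            f"{int(np.sum(yhat < 0))} negative predicted mol% value(s) for "
            f"{model.sugar}; reported unclipped",
            stacklevel=2,
        )
    return yhat


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    cv: CVConfig | None = None,
    sugar: str = "y",
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded K-fold cross-validation.

    Returns (per-fold RMSEP, pooled held-out predictions in original
    sample order).  Each sample is held out exactly once; the model (with
    its centering) is refit on the remaining folds.
    """
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if cv.K > n:
        raise ValueError(f"K={cv.K} folds exceed {n} samples")
    rng = np.random.default_rng(cv.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv.K)
    rmsep = np.empty(cv.K)
    pooled = np.empty(n)
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        if train_idx.size < 2:
            raise ValueError(f"fold {k} leaves {train_idx.size} training samples")
        model = fit_pls(X[train_idx], y[train_idx], n_components, sugar=sugar)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict_pls(model, X[test_idx])
        pooled[test_idx] = pred
        rmsep[k] = float(np.sqrt(np.mean((pred - y[test_idx]) ** 2)))
    return rmsep, pooled


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def fit_sugar_models(
    X: np.ndarray,
    composition: pd.DataFrame,
    components_map: dict[str, int] | None = None,
    cv: CVConfig | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[dict[str, PLSModel], CalibrationReport]:
    """Fit one PLS model per sugar and cross-validate the calibration.

    ``composition`` is indexed by sample id (or aligned row-wise when
    ``sample_ids`` is None) with one mol% column per sugar.  The report
    pools held-out (predicted, measured) pairs across sugars; the headline
    R^2 is the squared Pearson correlation of that pooled scatter.
    """
    components_map = dict(components_map or DEFAULT_COMPONENTS)
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in composition.index]
        if missing:
            raise ValueError(f"composition table missing samples: {missing}")
        composition = composition.loc[sample_ids]
    if len(composition) != X.shape[0]:
        raise ValueError("composition rows do not match spectra rows")
    missing_cols = [s for s in components_map if s not in composition.columns]
    if missing_cols:
        raise ValueError(f"composition table missing sugar columns: {missing_cols}")

    models: dict[str, PLSModel] = {}
    rmsep_by_sugar: dict[str, float] = {}
    r2_by_sugar: dict[str, float] = {}
    frames = []
    for sugar, k in components_map.items():
        y = composition[sugar].to_numpy(dtype=float)
        models[sugar] = fit_pls(X, y, k, sugar=sugar)
        fold_rmsep, pooled = kfold_cv(X, y, k, cv=cv, sugar=sugar)
        rmsep_by_sugar[sugar] = float(fold_rmsep.mean())
        r2_by_sugar[sugar] = _pearson_r2(pooled, y)
        frames.append(
            pd.DataFrame(
                {
                    "sugar": sugar,
                    "sample_index": np.arange(X.shape[0]),
                    "predicted": pooled,
                    "measured": y,
                }
            )
        )
    pairs = pd.concat(frames, ignore_index=True)
    pred = pairs["predicted"].to_numpy()
    meas = pairs["measured"].to_numpy()
    pooled_r2 = _pearson_r2(pred, meas)
    ss_res = float(np.sum((meas - pred) ** 2))
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    report = CalibrationReport(
        per_sugar_rmsep=rmsep_by_sugar,
        per_sugar_components={s: models[s].n_components for s in models},
        per_sugar_r2=r2_by_sugar,
        pooled_pairs=pairs,
        pooled_r2=pooled_r2,
        pooled_r2_regression=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
    )
    return models, report
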