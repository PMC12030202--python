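"""Random-forest inversion of NNI from vegetation indices.

A shallow random-forest regressor (100 trees; maximum depth, minimum
samples split and minimum samples leaf all 2) maps the selected
vegetation indices of a plot to its nitrogen nutrition index.  Data are
split 70/30 into training and testing sets, stratified by growth stage,
and the fit is judged by RMSE, R^2, a relative-error accuracy and the
through-origin slope k of predicted vs measured values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

__all__ = [
    "InversionModelSpec",
    "EvalMetrics",
    "split_dataset",
    "train_model",
    "predict_nni",
    "evaluate_model",
    "NNIInversion",
    "InversionResults",
]


@dataclass(frozen=True)
class InversionModelSpec:
    """Hyperparameters of the NNI inversion forest.

    The very shallow depth (2) is deliberate: with a handful of strongly
    collinear indices as features, deep trees add variance without
    signal.  Override ``max_depth`` for richer feature sets.
    """

    n_trees: int = 100
    max_depth: int = 2
    min_samples_split: int = 2
    min_samples_leaf: int = 2
    features: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "max_depth", "min_samples_split", "min_samples_leaf"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    def to_estimator(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_samples_split=max(self.min_samples_split, 2),
            min_samples_leaf=self.min_samples_leaf,
            random_state=int(self.seed) % (2**31),
        )


@dataclass(frozen=True)
class EvalMetrics:
    r2: float
    rmse: float
    accuracy: float  # 1 - mean relative error
    k: float  # through-origin slope of predicted vs measured
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def split_dataset(
    records: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_col: str | None = "stage",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split, stratified by growth stage.

    Deterministic for a fixed seed.  ``train_fraction=1.0`` returns an
    empty test set with a warning.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to split")
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must lie in (0, 1]")
    if train_fraction == 1.0:
        warnings.warn("train_fraction 1.0: empty test set", stacklevel=2)
        return records.copy(), records.iloc[0:0].copy()
    strat = records[stratify_col] if stratify_col and stratify_col in records else None
    train, test = train_test_split(
        records,
        train_size=train_fraction,
        random_state=int(seed) % (2**31),
        stratify=strat,
        shuffle=True,
    )
    return train, test


def train_model(train: pd.DataFrame, spec: InversionModelSpec, target: str = "nni"):
    """Fit the random forest on the spec's feature columns.

    Rejects records with missing features (undefined-index markers must
    be resolved upstream).
    """
    if not spec.features:
        raise ValueError("spec.features must name at least one index column")
    missing = [f for f in spec.features if f not in train.columns]
    if missing:
        raise ValueError(f"training table lacks feature columns: {missing}")
    X = train[list(spec.features)].to_numpy(dtype=float)
    bad = [f for f, col in zip(spec.features, X.T) if np.isnan(col).any()]
    if bad:
        raise ValueError(f"features contain undefined values (NaN): {bad}")
    y = train[target].to_numpy(dtype=float)
    model = spec.to_estimator()
    model.fit(X, y)
    return model


def predict_nni(model, records: pd.DataFrame, features) -> pd.DataFrame:
    """Attach predicted NNI to the records (stage/cultivar labels kept)."""
    X = records[list(features)].to_numpy(dtype=float)
    out = records.copy()
    out["nni_pred"] = model.predict(X)
    return out


def evaluate_model(predicted, measured) -> EvalMetrics:
    """RMSE, R^2 (1 - SSE/SST), relative-error accuracy and slope k.

    accuracy = 1 - mean(|pred - meas| / meas); k is the least-squares
    slope of predicted on measured through the origin, so k close to 1
    indicates an unbiased 1:1 fit.
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.size == 0:
        raise ValueError("predicted and measured must be equal-length, non-empty")
    resid = p - m
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else (1.0 if rmse == 0 else -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        accuracy = 1.0 - float(np.mean(np.abs(resid) / np.abs(m)))
    k = float(np.sum(p * m) / np.sum(m**2))
    return EvalMetrics(r2=r2, rmse=rmse, accuracy=accuracy, k=k, n=int(p.size))


class NNIInversion:
    """NNI inversion model: vegetation indices -> NNI via random forest.

    Parameters
    ----------
    data : per-plot table with the feature columns, a target column and
        (optionally) ``stage``/``cultivar`` labels.
    features : index columns used as predictors.
    target : name of the measured-NNI column (default ``"nni"``).
    """

    def __init__(self, data: pd.DataFrame, features, target: str = "nni"):
        self.data = data.reset_index(drop=True)
        self.features = tuple(features)
        self.target = target
        if target not in self.data.columns:
            raise ValueError(f"target column {target!r} missing")

    def fit(
        self,
        spec: InversionModelSpec | None = None,
        train_fraction: float = 0.7,
        seed: int = 0,
    ) -> "InversionResults":
        spec = spec or InversionModelSpec(features=self.features, seed=seed)
        if not spec.features:
            spec = InversionModelSpec(**{**asdict(spec), "features": self.features})
        train, test = split_dataset(self.data, train_fraction, seed=seed)
        model = train_model(train, spec, target=self.target)
        return InversionResults(self, spec, model, train, test)


class InversionResults:
    """Fitted forest plus train/test predictions and metrics."""

    def __init__(self, parent, spec, model, train, test):
        self.model_spec = spec
        self.estimator = model
        self.features = spec.features
        self.target = parent.target
        self.train = predict_nni(model, train, spec.features)
        self.test = predict_nni(model, test, spec.features) if len(test) else test.copy()
        self.train_metrics = evaluate_model(self.train["nni_pred"], self.train[parent.target])
        self.test_metrics = (
            evaluate_model(self.test["nni_pred"], self.test[parent.target])
            if len(test)
            else None
        )

    def predict(self, records: pd.DataFrame) -> pd.DataFrame:
        return predict_nni(self.estimator, records, self.features)

    def metrics_by_stage(self, which: str = "test") -> pd.DataFrame:
        """Evaluation metrics per growth stage (and cultivar, if present)."""
        table = self.test if which == "test" else self.train
        keys = [c for c in ("stage", "cultivar") if c in table.columns]
        rows = []
        for key, sub in table.groupby(keys, observed=True) if keys else [((), table)]:
            m = evaluate_model(sub["nni_pred"], sub[self.target])
            row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
            rows.append({**row, **m.as_dict()})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "NNI inversion (random forest)",
            "=" * 46,
            f"features: {', '.join(self.features)}",
            f"trees={self.model_spec.n_trees} depth={self.model_spec.max_depth} "
            f"min_split={self.model_spec.min_samples_split} min_leaf={self.model_spec.min_samples_leaf}",
            f"train n={self.train_metrics.n}: R2={self.train_metrics.r2:.3f} "
            f"RMSE={self.train_metrics.rmse:.4f} acc={self.train_metrics.accuracy:.3f} "
            f"k={self.train_metrics.k:.3f}",
        ]
        if self.test_metrics is not None:
            lines.append(
                f"test  n={self.test_metrics.n}: R2={self.test_metrics.r2:.3f} "
                f"RMSE={self.test_metrics.rmse:.4f} acc={self.test_metrics.accuracy:.3f} "
                f"k={self.test_metrics.k:.3f}"
            )
        return "\n".join(lines)

    def save_report(self, path) -> None:
        report = {
            "spec": {**asdict(self.model_spec), "features": list(self.features)},
            "train": self.train_metrics.as_dict(),
            "test": self.test_metrics.as_dict() if self.test_metrics else None,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
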