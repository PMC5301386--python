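"""Soft-voting ensemble: Gaussian naive Bayes + random forest.

Two classifiers with complementary failure modes are trained on the same
standardized matrix -- a Gaussian naive Bayes and a 100-tree random forest --
and combined by averaging their predicted class probabilities (soft voting
with equal weights).  The vote output is therefore always bracketed by the
two member outputs.  A probability at or above 0.5 is called an epitope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler

FORMAT_VERSION = 1


@dataclass
class EnsembleModel:
    """Fitted standardizer + GNB + RF pair with the voting rule."""

    scaler: StandardScaler
    gnb: GaussianNB
    rf: RandomForestClassifier
    seed: int
    columns: list[str] = field(default_factory=list)
    vote_weights: tuple[float, float] = (0.5, 0.5)
    decision_threshold: float = 0.5

    @property
    def n_features(self) -> int:
        return self.scaler.n_features_in_


def train(
    X: np.ndarray, y: np.ndarray, seed: int = 0, columns: list[str] | None = None
) -> EnsembleModel:
    """Fit the standardizer and both members on identical rows.

    Requires two classes and finite values; the random forest uses 100 trees
    with the library defaults of unlimited depth, sqrt(p) features per split
    and bootstrap sampling, pinned by ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("training requires both classes")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    gnb = GaussianNB().fit(Xs, y)
    rf = RandomForestClassifier(
        n_estimators=100, random_state=seed, n_jobs=1
    ).fit(Xs, y)
    return EnsembleModel(
        scaler=scaler, gnb=gnb, rf=rf, seed=seed, columns=list(columns or [])
    )


def _check_shape(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects {model.n_features}"
        )
    return X


def member_proba(model: EnsembleModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class probability of each member separately."""
    Xs = model.scaler.transform(_check_shape(model, X))
    pos = list(model.gnb.classes_).index(1)
    return model.gnb.predict_proba(Xs)[:, pos], model.rf.predict_proba(Xs)[:, pos]


def predict_proba(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Soft-vote epitope probability: (p_GNB + p_RF) / 2, exactly."""
    p_gnb, p_rf = member_proba(model, X)
    w1, w2 = model.vote_weights
    return (w1 * p_gnb + w2 * p_rf) / (w1 + w2)


def predict_labels(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """0/1 epitope call; probability equal to the threshold counts positive."""
    return (predict_proba(model, X) >= model.decision_threshold).astype(int)


def save(model: EnsembleModel, path: str | Path, extra: dict | None = None) -> None:
    """Persist the model (self-describing, versioned)."""
    payload = {
        "format_version": FORMAT_VERSION,
        "model": model,
        "rf_params": model.rf.get_params(),
        "extra": extra or {},
    }
    joblib.dump(payload, path)


def load(path: str | Path) -> tuple[EnsembleModel, dict]:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {version!r}")
    return payload["model"], payload.get("extra", {})
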