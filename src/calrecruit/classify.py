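"""Supervised selection of neuronal-activity traces.

A small, auditable feature vector is computed per normalized trace and an
AdaBoost ensemble of depth-1 decision stumps is trained on manually labeled
examples; the resulting labels can be refined and the classifier retrained,
mirroring the iterative curation workflow of calcium-imaging analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .core import NORMALIZED, Trace
from .errors import LengthError, ReferenceError_, SchemaError, StageError, TrainingError
from .synthetic import NEURONAL

FEATURE_NAMES = (
    "std",
    "skewness",
    "kurtosis",
    "max_amplitude",
    "n_excursions",
    "autocorr_1s",
    "band_power_ratio",
)

#: excursion-counting threshold in percent dF/F (half a transient amplitude)
EXCURSION_THRESHOLD_PCT = 0.5
#: split between "slow" and "fast" band power, Hz
BAND_SPLIT_HZ = 0.5

_FORMAT_VERSION = 1


def extract_features(trace: Trace, excursion_threshold: float = EXCURSION_THRESHOLD_PCT) -> dict[str, float]:
    """Deterministic per-trace feature vector (on the normalized trace).

    Requires at least 2 s of data (for the 1 s-lag autocorrelation and the
    spectral split). Excursions are upward crossings of the threshold.
    """
    if trace.stage != NORMALIZED:
        raise StageError(f"features are computed on normalized traces, got {trace.stage!r}")
    v = trace.values
    fr = trace.frame_rate_hz
    min_len = int(np.ceil(2.0 * fr))
    if v.size < min_len:
        raise LengthError(f"trace {trace.roi_id} has {v.size} frames; need >= {min_len}")
    above = v >= excursion_threshold
    n_exc = int(above[0]) + int(np.sum(above[1:] & ~above[:-1]))
    lag = max(int(round(fr)), 1)
    a, b = v[:-lag], v[lag:]
    if np.std(a) > 0 and np.std(b) > 0:
        autocorr = float(np.corrcoef(a, b)[0, 1])
    else:
        autocorr = 0.0
    freqs, power = signal.periodogram(v, fs=fr)
    low = float(power[(freqs > 0) & (freqs <= BAND_SPLIT_HZ)].sum())
    high = float(power[freqs > BAND_SPLIT_HZ].sum())
    eps = 1e-12
    return {
        "std": float(np.std(v)),
        "skewness": float(stats.skew(v)) if np.std(v) > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(v)) if np.std(v) > 0 else 0.0,
        "max_amplitude": float(np.max(v)) if np.max(v) > 0 else 0.0,
        "n_excursions": float(n_exc),
        "autocorr_1s": autocorr,
        "band_power_ratio": (low + eps) / (high + eps),
    }


def features_table(traces: Sequence[Trace], **kwargs) -> pd.DataFrame:
    """Feature matrix indexed by roi_id, columns in ``FEATURE_NAMES`` order."""
    rows = {tr.roi_id: extract_features(tr, **kwargs) for tr in traces}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "roi_id"
    return df


@dataclass
class TraceClassifier:
    """Trained AdaBoost trace classifier plus its training metadata."""

    model: AdaBoostClassifier
    feature_names: tuple[str, ...]
    training_accuracy: float
    n_rounds: int
    seed: int

    def save(self, path) -> None:
        joblib.dump({"format_version": _FORMAT_VERSION, "classifier": self}, path)

    @staticmethod
    def load(path) -> "TraceClassifier":
        payload = joblib.load(path)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise SchemaError(f"unsupported classifier file version: {payload.get('format_version')}")
        return payload["classifier"]


def _check_features(features: pd.DataFrame, expected: Sequence[str]) -> np.ndarray:
    if list(features.columns) != list(expected):
        raise SchemaError(
            f"feature columns {list(features.columns)} do not match {list(expected)}"
        )
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise SchemaError("features contain non-finite values")
    return X


def train_classifier(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    n_rounds: int = 50,
    seed: int = 0,
) -> TraceClassifier:
    """AdaBoost over depth-1 decision stumps, deterministic given ``seed``.

    ``labels`` must have columns ``roi_id`` and ``label`` with both classes
    present. Class imbalance is handled by weighting samples inversely to
    class frequency.
    """
    X = _check_features(features, FEATURE_NAMES)
    lab = labels.set_index("roi_id")["label"].reindex(features.index)
    if lab.isna().any():
        missing = list(features.index[lab.isna()])[:5]
        raise SchemaError(f"labels missing for roi_ids {missing}")
    y = lab.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError(f"training set contains a single class: {classes.tolist()}")
    weight_of = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    sample_weight = np.asarray([weight_of[c] for c in y])
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1),
        n_estimators=int(n_rounds),
        random_state=int(seed),
    )
    model.fit(X, y, sample_weight=sample_weight)
    acc = float(np.mean(model.predict(X) == y))
    return TraceClassifier(model, tuple(FEATURE_NAMES), acc, int(n_rounds), int(seed))


def classify_traces(clf: TraceClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Predicted labels, one row per trace (columns roi_id, label, source)."""
    if features.empty:
        return pd.DataFrame(columns=["roi_id", "label", "source"])
    X = _check_features(features, clf.feature_names)
    pred = clf.model.predict(X)
    return pd.DataFrame(
        {"roi_id": features.index.to_numpy(), "label": pred, "source": "predicted"}
    )


def refine_training_set(
    labels: pd.DataFrame,
    corrections: pd.DataFrame,
    round_counter: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Apply manual corrections to a label table, keeping an audit trail.

    Corrections override prior labels (their source becomes ``manual``);
    unknown roi_ids raise. Returns (updated labels, audit table, new round
    counter). The audit table records roi_id, old and new label, and round.
    """
    known = set(labels["roi_id"].tolist())
    audit_rows = []
    updated = labels.copy()
    for _, row in corrections.iterrows():
        rid = row["roi_id"]
        if rid not in known:
            raise ReferenceError_(f"correction references unknown roi_id {rid}")
        mask = updated["roi_id"] == rid
        old = updated.loc[mask, "label"].iloc[0]
        updated.loc[mask, ["label", "source"]] = [row["label"], "manual"]
        audit_rows.append({"roi_id": rid, "old_label": old, "new_label": row["label"],
                           "round": round_counter + 1})
    audit = pd.DataFrame(audit_rows, columns=["roi_id", "old_label", "new_label", "round"])
    return updated, audit, round_counter + 1


def neuronal_ids(labels: pd.DataFrame) -> list[int]:
    """roi_ids labeled as the neuronal-activity class."""
    return labels.loc[labels["label"] == NEURONAL, "roi_id"].tolist()
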