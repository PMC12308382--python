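"""Boosted-tree property models on latent vectors.

The generator and predictor are trained *separately*: the VAE learns the
chemical space, then gradient-boosted regression trees (GBRT) map each
molecule's latent mean — optionally concatenated with a small solvent
descriptor — to emission energy (eV) or photoluminescence quantum yield
(PLQY). A companion classifier splits molecules into bright/dark at the
PLQY 0.25 threshold. The practical accuracy criterion for a PLQY
prediction is |error| < 0.3 * true + 0.1, i.e. a 30% relative band widened
by an absolute 0.1 floor so near-dark molecules are judged fairly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor

from .codec import MoleculeRecord, encode_one_hot
from .generator import GeneratorModel

BRIGHT_THRESHOLD = 0.25

TASKS = ("emission_ev", "plqy_regression", "plqy_class")

#: Generic polarity descriptors (dielectric constant, dipole moment in
#: debye, refractive index) for common photophysics solvents. Unknown
#: solvents featurize as zeros.
SOLVENT_TABLE: dict[str, tuple[float, float, float]] = {
    "water": (78.4, 1.85, 1.333),
    "methanol": (32.7, 1.70, 1.329),
    "ethanol": (24.5, 1.69, 1.361),
    "acetonitrile": (37.5, 3.92, 1.344),
    "dichloromethane": (8.93, 1.60, 1.424),
    "chloroform": (4.81, 1.04, 1.446),
    "toluene": (2.38, 0.36, 1.497),
    "hexane": (1.88, 0.00, 1.375),
    "dmso": (46.7, 3.96, 1.479),
    "thf": (7.58, 1.75, 1.407),
}

SOLVENT_DESCRIPTOR_LEN = 3


def solvent_descriptor(
    solvent_id: str, table: dict | None = None
) -> np.ndarray:
    """Descriptor for a solvent; zeros (with a warning) when unknown."""
    table = SOLVENT_TABLE if table is None else table
    if not solvent_id:
        return np.zeros(SOLVENT_DESCRIPTOR_LEN)
    key = solvent_id.strip().lower()
    if key not in table:
        warnings.warn(f"unknown solvent {solvent_id!r}; using zero descriptor")
        return np.zeros(SOLVENT_DESCRIPTOR_LEN)
    return np.asarray(table[key], dtype=float)


def featurize(
    model: GeneratorModel,
    record: MoleculeRecord | str,
    solvent_table: dict | None = None,
) -> np.ndarray:
    """Latent-mean features: encoder mean (no sampling) + solvent part."""
    mu = model.encode_mean(record)
    sid = record.solvent_id if isinstance(record, MoleculeRecord) else ""
    return np.concatenate([mu, solvent_descriptor(sid, solvent_table)])


def featurize_onehot(
    model: GeneratorModel,
    record: MoleculeRecord | str,
    solvent_table: dict | None = None,
) -> np.ndarray:
    """Alternative featurizer: the flattened one-hot matrix + solvent part."""
    x = model._to_onehot(record).ravel()
    sid = record.solvent_id if isinstance(record, MoleculeRecord) else ""
    return np.concatenate([x, solvent_descriptor(sid, solvent_table)])


def featurize_batch(model, records, featurizer=featurize) -> np.ndarray:
    return np.stack([featurizer(model, r) for r in records])


# ---------------------------------------------------------------------------
# Criterion and threshold
# ---------------------------------------------------------------------------


def plqy_prediction_accurate(true_plqy: float, predicted_plqy: float) -> bool:
    """Practical accuracy: |error| strictly below 30% of true plus 0.1."""
    if not (0.0 <= true_plqy <= 1.0):
        raise ValueError(f"true PLQY {true_plqy} outside [0, 1]")
    return abs(predicted_plqy - true_plqy) < 0.3 * true_plqy + 0.1


def classify_brightness(
    plqy_value: float, threshold: float = BRIGHT_THRESHOLD
) -> str:
    """Bright/dark dichotomy; the boundary value counts as bright."""
    if not (0.0 <= plqy_value <= 1.0):
        raise ValueError(f"PLQY {plqy_value} outside [0, 1]")
    return "bright" if plqy_value >= threshold else "dark"


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictorConfig:
    rounds: int = 500
    depth: int = 5
    lr: float = 0.05
    subsample: float = 0.8
    seed: int = 0


@dataclass
class PropertyModel:
    """A trained boosted-tree model for one task."""

    task: str
    estimator: object
    feature_len: int
    config: PredictorConfig

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.feature_len:
            raise ValueError(
                f"feature length {X.shape[1]} != trained length "
                f"{self.feature_len}")
        pred = self.estimator.predict(X)
        if self.task == "plqy_regression":
            pred = np.clip(pred, 0.0, 1.0)
        return pred

    def save(self, path: str | Path) -> None:
        import joblib

        path = Path(path)
        joblib.dump(self.estimator, path)
        meta = {
            "task": self.task,
            "feature_len": self.feature_len,
            "config": self.config.__dict__,
            "format_version": 1,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PropertyModel":
        import joblib

        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            task=meta["task"],
            estimator=joblib.load(path),
            feature_len=meta["feature_len"],
            config=PredictorConfig(**meta["config"]),
        )


def train_property_model(
    features: np.ndarray,
    targets: Sequence,
    task: str,
    config: PredictorConfig = PredictorConfig(),
) -> PropertyModel:
    """Fit a GBRT model; deterministic per ``config.seed``.

    ``task`` selects regression (emission_ev, plqy_regression) or the
    bright/dark classifier (plqy_class, labels "bright"/"dark").
    """
    if task not in TASKS:
        raise ValueError(f"unknown task: {task!r}")
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) != len(targets):
        raise ValueError("features must be 2-D with one row per target")
    if len(targets) < 10:
        raise ValueError("need at least 10 training examples")
    y = np.asarray(targets)
    if task == "plqy_class":
        if set(np.unique(y)) - {"bright", "dark"}:
            raise ValueError("class targets must be 'bright' or 'dark'")
        if len(np.unique(y)) < 2:
            raise ValueError("zero-variance target")
        est = GradientBoostingClassifier(
            n_estimators=config.rounds, max_depth=config.depth,
            learning_rate=config.lr, subsample=config.subsample,
            random_state=config.seed)
    else:
        y = y.astype(float)
        if task == "plqy_regression" and (y.min() < 0 or y.max() > 1):
            raise ValueError("PLQY targets must lie in [0, 1]")
        if np.std(y) == 0:
            raise ValueError("zero-variance target")
        est = GradientBoostingRegressor(
            n_estimators=config.rounds, max_depth=config.depth,
            learning_rate=config.lr, subsample=config.subsample,
            random_state=config.seed)
    est.fit(X, y)
    return PropertyModel(task=task, estimator=est, feature_len=X.shape[1],
                         config=config)


@dataclass(frozen=True)
class EvalReport:
    """Held-out metrics; fields that do not apply to the task are None."""

    mae: float | None
    pearson_r: float | None  # None marks undefined (constant inputs)
    plqy_accuracy_fraction: float | None
    class_accuracy: float | None
    n: int


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def evaluate(
    model: PropertyModel, features: np.ndarray, targets: Sequence
) -> EvalReport:
    """MAE, Pearson r, PLQY-criterion fraction, and/or class accuracy."""
    if len(targets) == 0:
        raise ValueError("empty evaluation set")
    preds = model.predict(features)
    y = np.asarray(targets)
    if model.task == "plqy_class":
        return EvalReport(
            mae=None, pearson_r=None, plqy_accuracy_fraction=None,
            class_accuracy=float(np.mean(preds == y)), n=len(y))
    y = y.astype(float)
    mae = float(np.mean(np.abs(preds - y)))
    r = _safe_pearson(preds, y)
    if model.task == "plqy_regression":
        acc = float(np.mean([
            plqy_prediction_accurate(t, p) for t, p in zip(y, preds)]))
        cls = float(np.mean([
            classify_brightness(min(max(p, 0.0), 1.0)) == classify_brightness(t)
            for t, p in zip(y, preds)]))
        return EvalReport(mae=mae, pearson_r=r, plqy_accuracy_fraction=acc,
                          class_accuracy=cls, n=len(y))
    return EvalReport(mae=mae, pearson_r=r, plqy_accuracy_fraction=None,
                      class_accuracy=None, n=len(y))
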