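"""Feedforward-network calibration of acoustic features to IOP.

The map from the nine inputs (three acoustic features + six biometrics) to
the reference IOP is learned by a small fully connected network with two
tanh hidden layers and a linear output, trained by full-batch L-BFGS on the
squared error with early stopping on a validation split.  Because such
trainings land in different local minima depending on the initialisation,
many independent trials are run and the best few — ranked by how close the
validation regression slope is to 1 combined with the regression
coefficient R — are averaged into the final ensemble predictor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata

from .pipeline import FEATURE_COLUMNS

__all__ = [
    "CalibrationModel",
    "TrialMetrics",
    "TrialEnsemble",
    "split_data",
    "train_once",
    "trial_score",
    "run_trials",
    "scan_architectures",
    "predict_iop",
]

DEFAULT_ARCHITECTURE = (7, 10)
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


# ---------------------------------------------------------------------------
# data splitting
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, fractions: Sequence[float]) -> List[int]:
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    rem = raw - base
    for i in np.argsort(-rem)[: total - base.sum()]:
        base[i] += 1
    return base.tolist()


def split_data(
    dataset: pd.DataFrame,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    group_column: Optional[str] = "subject_id",
    label_column: str = "reference_iop",
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation/test split, stratified by
    reference-IOP tertile.

    Rows sharing ``group_column`` (both eyes / repeated measurements of one
    subject) are kept inside a single partition so the test set carries no
    subject-level leakage.  Within each tertile, groups are shuffled with the
    seed and allocated by largest remainder, then minimally rebalanced to the
    global target sizes.
    """
    fractions = list(fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    if len(fractions) != 3:
        raise ValueError("expected exactly three fractions (train, validation, test)")
    n = len(dataset)
    if n < 30:
        raise ValueError("dataset too small to split (need >= 10 rows per split)")

    if group_column is not None and group_column in dataset.columns:
        groups = dataset.groupby(group_column, sort=True)
        units = [
            (key, list(idx), float(sub[label_column].mean()))
            for (key, idx), (_, sub) in zip(groups.groups.items(), groups)
        ]
    else:
        units = [(i, [i], float(v)) for i, v in zip(dataset.index, dataset[label_column])]

    labels = np.array([u[2] for u in units])
    t1, t2 = np.quantile(labels, [1 / 3, 2 / 3])
    tertile = np.digitize(labels, [t1, t2])

    rng = np.random.default_rng(seed)
    assignment: Dict[int, int] = {}  # unit index -> split index
    for tv in range(3):
        members = np.flatnonzero(tertile == tv)
        members = members[rng.permutation(members.size)]
        # largest remainder with the tie-break rotated per tertile, so the
        # per-tertile roundings cancel in the global split sizes
        raw = np.asarray(fractions) * members.size
        sizes = np.floor(raw).astype(int)
        rem = raw - sizes
        order = sorted(range(3), key=lambda i: (-rem[i], (i - tv) % 3))
        for i in order[: members.size - sizes.sum()]:
            sizes[i] += 1
        pos = 0
        for split_i, size in enumerate(sizes):
            for u in members[pos : pos + size]:
                assignment[int(u)] = split_i
            pos += size

    split_rows: List[List[int]] = [[], [], []]
    for u, s in assignment.items():
        split_rows[s].extend(units[u][1])
    out = tuple(dataset.loc[sorted(rows)] for rows in split_rows)
    if any(len(part) < 10 for part in out):
        raise ValueError("dataset too small: each split needs >= 10 rows")
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """A trained network plus its input/output normalisation and metadata.

    Prediction is a pure function of the stored weights; inputs are keyed by
    feature name, so column order never matters.
    """

    layer_sizes: Tuple[int, ...]
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    feature_names: List[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    activation: str = "tanh"
    metadata: dict = field(default_factory=dict)

    def _forward(self, z: np.ndarray) -> np.ndarray:
        h = z
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = np.tanh(h)
        return h[:, 0]

    def predict(self, features: Union[pd.DataFrame, Dict[str, float]]) -> np.ndarray:
        """IOP prediction in mm Hg; warns when inputs extrapolate >5 SD."""
        if isinstance(features, dict):
            features = pd.DataFrame([features])
        x = features[self.feature_names].to_numpy(dtype=float)
        z = (x - self.x_mean) / self.x_std
        if np.any(np.abs(z) > 5.0):
            warnings.warn(
                "input beyond 5 SD of the training distribution; "
                "prediction is an extrapolation",
                stacklevel=2,
            )
        return self._forward(z) * self.y_std + self.y_mean

    def to_json(self, path) -> None:
        doc = {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "activation": self.activation,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            layer_sizes=tuple(doc["layer_sizes"]),
            weights=[np.asarray(w) for w in doc["weights"]],
            biases=[np.asarray(b) for b in doc["biases"]],
            feature_names=doc["feature_names"],
            x_mean=np.asarray(doc["x_mean"]),
            x_std=np.asarray(doc["x_std"]),
            y_mean=doc["y_mean"],
            y_std=doc["y_std"],
            activation=doc["activation"],
            metadata=doc["metadata"],
        )


def _init_params(layer_sizes: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    parts = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        parts.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=fan_in * fan_out))
        parts.append(np.zeros(fan_out))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, layer_sizes: Sequence[int]) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    weights, biases, pos = [], [], 0
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(theta[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out))
        pos += fan_in * fan_out
        biases.append(theta[pos : pos + fan_out])
        pos += fan_out
    return weights, biases


def _loss_grad(
    theta: np.ndarray,
    layer_sizes: Sequence[int],
    x: np.ndarray,
    y: np.ndarray,
    l2: float,
) -> Tuple[float, np.ndarray]:
    """Mean squared error + L2 penalty, with analytic backpropagated gradient."""
    weights, biases = _unpack(theta, layer_sizes)
    last = len(weights) - 1
    acts = [x]
    h = x
    for i, (w, b) in enumerate(zip(weights, biases)):
        h = h @ w + b
        if i < last:
            h = np.tanh(h)
        acts.append(h)
    pred = acts[-1][:, 0]
    resid = pred - y
    n = y.size
    loss = float(np.mean(resid**2)) + l2 * float(np.sum(theta**2))

    grad_w = [np.empty(0)] * len(weights)
    grad_b = [np.empty(0)] * len(weights)
    delta = (2.0 / n) * resid[:, None]
    for i in range(last, -1, -1):
        grad_w[i] = acts[i].T @ delta
        grad_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ weights[i].T) * (1.0 - acts[i] ** 2)
    flat = np.concatenate([np.r_[gw.ravel(), gb] for gw, gb in zip(grad_w, grad_b)])
    return loss, flat + 2.0 * l2 * theta


class TrainingFailure(Exception):
    """Training produced a non-finite loss; the trial is discarded."""


def train_once(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    architecture: Tuple[int, int] = DEFAULT_ARCHITECTURE,
    seed: int = 0,
    feature_columns: Optional[List[str]] = None,
    label_column: str = "reference_iop",
    max_iter: int = 400,
    l2: float = 1e-5,
) -> CalibrationModel:
    """Train one network by full-batch L-BFGS with validation early stopping.

    The two hidden layers default to the 7/10 layout; architectures outside
    5-13 neurons per hidden layer are allowed but flagged in the metadata.
    Deterministic given ``seed``.  Returns the weights with the best
    validation error seen along the optimisation path, not necessarily the
    final ones.
    """
    feature_columns = feature_columns or FEATURE_COLUMNS
    h1, h2 = architecture
    layer_sizes = (len(feature_columns), h1, h2, 1)

    x_tr = train[feature_columns].to_numpy(dtype=float)
    y_tr = train[label_column].to_numpy(dtype=float)
    x_va = validation[feature_columns].to_numpy(dtype=float)
    y_va = validation[label_column].to_numpy(dtype=float)

    x_mean, x_std = x_tr.mean(axis=0), x_tr.std(axis=0)
    x_std[x_std == 0] = 1.0
    y_mean, y_std = float(y_tr.mean()), float(y_tr.std()) or 1.0
    z_tr, z_va = (x_tr - x_mean) / x_std, (x_va - x_mean) / x_std
    u_tr, u_va = (y_tr - y_mean) / y_std, (y_va - y_mean) / y_std

    rng = np.random.default_rng(seed)
    theta0 = _init_params(layer_sizes, rng)

    best = {"val": np.inf, "theta": theta0.copy()}

    def _val_loss(theta: np.ndarray) -> float:
        w, b = _unpack(theta, layer_sizes)
        h = z_va
        for i, (wi, bi) in enumerate(zip(w, b)):
            h = h @ wi + bi
            if i < len(w) - 1:
                h = np.tanh(h)
        return float(np.mean((h[:, 0] - u_va) ** 2))

    def _callback(theta: np.ndarray) -> None:
        v = _val_loss(theta)
        if v < best["val"]:
            best["val"] = v
            best["theta"] = theta.copy()

    result = minimize(
        _loss_grad,
        theta0,
        args=(layer_sizes, z_tr, u_tr, l2),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
        callback=_callback,
    )
    if not np.all(np.isfinite(result.x)) or not np.isfinite(result.fun):
        raise TrainingFailure(f"non-finite loss in trial with seed {seed}")
    _callback(result.x)

    weights, biases = _unpack(best["theta"], layer_sizes)
    return CalibrationModel(
        layer_sizes=layer_sizes,
        weights=weights,
        biases=biases,
        feature_names=list(feature_columns),
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        metadata={
            "seed": int(seed),
            "architecture": [int(h1), int(h2)],
            "n_train": int(len(train)),
            "n_validation": int(len(validation)),
            "train_index": [int(i) for i in train.index],
            "validation_index": [int(i) for i in validation.index],
            "n_iter": int(result.nit),
            "val_mse_normalised": best["val"],
            "in_recommended_range": bool(5 <= h1 <= 13 and 5 <= h2 <= 13),
        },
    )


# ---------------------------------------------------------------------------
# trial scoring and the repeated-training ensemble
# ---------------------------------------------------------------------------

@dataclass
class TrialMetrics:
    """Validation regression of prediction on reference for one trial.

    ``slope_dev`` = |slope - 1| and ``r_deficit`` = 1 - R are the two raw
    quantities the rank-sum selection combines; lower is better in both.
    Degenerate (constant) predictions score infinitely badly.
    """

    slope: float
    r: float

    @property
    def slope_dev(self) -> float:
        return abs(self.slope - 1.0) if np.isfinite(self.slope) else np.inf

    @property
    def r_deficit(self) -> float:
        return (1.0 - self.r) if np.isfinite(self.r) else np.inf


def trial_score(
    model: CalibrationModel,
    validation: pd.DataFrame,
    label_column: str = "reference_iop",
) -> TrialMetrics:
    """Slope and R of prediction vs. reference on the validation split."""
    if len(validation) == 0:
        raise ValueError("validation split is empty")
    pred = model.predict(validation)
    ref = validation[label_column].to_numpy(dtype=float)
    if np.std(pred) < 1e-12 or np.std(ref) < 1e-12:
        return TrialMetrics(slope=np.nan, r=np.nan)
    slope, _ = np.polyfit(ref, pred, deg=1)
    r = float(np.corrcoef(ref, pred)[0, 1])
    return TrialMetrics(slope=float(slope), r=r)


@dataclass
class TrialEnsemble:
    """All trained trials, their metrics, and the selected best subset.

    The ensemble prediction is the mean of the selected models' outputs.
    ``ranking`` is a permutation of the trials by ascending rank-sum of
    (|slope-1|, 1-R) on the validation split.
    """

    models: List[CalibrationModel]
    metrics: List[TrialMetrics]
    ranking: np.ndarray
    selected: np.ndarray  # indices into models, best first
    train_index: List[int]
    validation_index: List[int]
    test_index: List[int]
    n_failures: int = 0

    @property
    def selected_models(self) -> List[CalibrationModel]:
        return [self.models[i] for i in self.selected]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        preds = np.stack([m.predict(features) for m in self.selected_models])
        return preds.mean(axis=0)

    def assert_test_isolation(self) -> None:
        """No test row may have touched training or selection."""
        test = set(self.test_index)
        for m in self.models:
            used = set(m.metadata["train_index"]) | set(m.metadata["validation_index"])
            if used & test:
                raise AssertionError("test rows leaked into training or selection")


def run_trials(
    dataset: pd.DataFrame,
    architecture: Tuple[int, int] = DEFAULT_ARCHITECTURE,
    n_trials: int = 2000,
    keep_fraction: float = 0.01,
    seed: int = 0,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    feature_columns: Optional[List[str]] = None,
    max_iter: int = 400,
) -> TrialEnsemble:
    """Repeated independent trainings + rank-sum selection of the best subset.

    All trials share one train/validation/test split (the repetition is over
    weight initialisations, which is what traps trainings in different local
    minima); ranking uses validation data only, so the test split stays
    untouched for agreement analysis.
    """
    if n_trials < 10:
        raise ValueError("n_trials must be >= 10")
    train, validation, test = split_data(dataset, fractions, seed=seed)
    seeds = np.random.SeedSequence([int(seed), 3]).generate_state(n_trials) % (2**31)
    models, metrics = [], []
    n_failures = 0
    for s in seeds:
        try:
            m = train_once(
                train,
                validation,
                architecture=architecture,
                seed=int(s),
                feature_columns=feature_columns,
                max_iter=max_iter,
            )
        except TrainingFailure:
            n_failures += 1
            continue
        models.append(m)
        metrics.append(trial_score(m, validation))
    if not models:
        raise RuntimeError("all training trials failed")

    slope_rank = rankdata([t.slope_dev for t in metrics])
    r_rank = rankdata([t.r_deficit for t in metrics])
    rank_sum = slope_rank + r_rank
    ranking = np.argsort(rank_sum, kind="stable")
    n_keep = max(1, int(round(keep_fraction * len(models))))
    return TrialEnsemble(
        models=models,
        metrics=metrics,
        ranking=ranking,
        selected=ranking[:n_keep],
        train_index=[int(i) for i in train.index],
        validation_index=[int(i) for i in validation.index],
        test_index=[int(i) for i in test.index],
        n_failures=n_failures,
    )


def scan_architectures(
    dataset: pd.DataFrame,
    neuron_range: Sequence[int] = range(5, 14),
    n_trials_per_arch: int = 10,
    seed: int = 0,
    keep_fraction: float = 0.2,
    k_p: float = 2.0,
    feature_columns: Optional[List[str]] = None,
    max_iter: int = 300,
) -> pd.DataFrame:
    """Grid scan over two-hidden-layer architectures (default 5..13 x 5..13).

    For each (h1, h2) cell: mean |slope-1| + (1-R) over its trials on the
    validation split, and the expanded uncertainty of the cell's selected
    sub-ensemble on the test split.  Returned ranked by the mean score.
    """
    from .agreement import bland_altman

    rows = []
    for h1 in neuron_range:
        for h2 in neuron_range:
            ens = run_trials(
                dataset,
                architecture=(h1, h2),
                n_trials=max(10, n_trials_per_arch),
                keep_fraction=keep_fraction,
                seed=seed,
                feature_columns=feature_columns,
                max_iter=max_iter,
            )
            score = float(
                np.mean([t.slope_dev + t.r_deficit for t in ens.metrics if np.isfinite(t.slope)])
            )
            test = dataset.loc[ens.test_index]
            pred = ens.predict(test)
            report = bland_altman(test["reference_iop"].to_numpy(), pred, k_p=k_p)
            rows.append(
                {
                    "h1": h1,
                    "h2": h2,
                    "mean_score": score,
                    "test_expanded_uncertainty": report.expanded_uncertainty,
                    "n_trials": len(ens.models),
                }
            )
    table = pd.DataFrame(rows).sort_values("mean_score", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def predict_iop(
    model: Union[CalibrationModel, TrialEnsemble],
    features: Union[pd.DataFrame, Dict[str, float]],
) -> np.ndarray:
    """IOP estimate (mm Hg) from a single model or a trial ensemble."""
    if isinstance(features, dict):
        features = pd.DataFrame([features])
    return model.predict(features)
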