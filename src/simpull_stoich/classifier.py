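"""1-D CNN step classifiers for Z-scored photobleaching traces.

Two classifiers are trained per experiment: a 2-class green model
(rejected / 1-step) that selects complexes with a single bait molecule,
and a 4-class far-red model (rejected / 1-step / 2-step / 3-and-higher)
that counts prey copies. Class imbalance is handled with inverse class
frequency weighting of the cross-entropy loss; model selection runs a
grid of architectures through a stratified 80/20 split, forwards the
top five by validation accuracy to stratified 5-fold cross-validation,
and picks the best mean CV accuracy.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._nn import Network
from .core import FARRED, classes_for, derive_seed

__all__ = [
    "ModelConfig", "LabeledTraceSet", "CvReport", "TrainedModel",
    "compute_class_weights", "stratified_split", "train", "cross_validate",
    "architecture_search", "predict", "default_demo_grid",
]


@dataclass(frozen=True)
class ModelConfig:
    """One CNN architecture + training hyperparameter configuration."""

    conv_blocks: tuple = ((9, 16), (9, 32))   # (kernel_size, n_filters)
    pool_size: int = 5
    dense_layers: tuple = (64,)
    n_classes: int = 4
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 12
    input_length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for k, f in self.conv_blocks:
            if k < 3 or k % 2 == 0:
                raise ValueError("kernel sizes must be odd and >= 3")
            if f < 1:
                raise ValueError("filter counts must be positive")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 (green) or 4 (far-red)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.pool_size < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("pool/batch/epoch settings must be positive")

    def build(self, seed: int | None = None) -> Network:
        return Network(self.input_length, self.conv_blocks, self.pool_size,
                       self.dense_layers, self.n_classes,
                       seed=self.seed if seed is None else seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_blocks"] = [list(b) for b in self.conv_blocks]
        d["dense_layers"] = list(self.dense_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
        d["dense_layers"] = tuple(d["dense_layers"])
        return cls(**d)


@dataclass
class LabeledTraceSet:
    """Fixed-length Z-scored traces with class labels for one channel."""

    traces: np.ndarray              # (n, L) z-scored
    labels: np.ndarray              # (n,) class-name strings
    channel: str = FARRED
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.traces.ndim != 2 or len(self.traces) != len(self.labels):
            raise ValueError("traces must be (n, L) with one label per trace")
        valid = set(classes_for(self.channel))
        bad = set(np.unique(self.labels)) - valid
        if bad:
            raise ValueError(f"labels {bad} not in the {self.channel} class set")

    @property
    def class_names(self) -> tuple[str, ...]:
        return classes_for(self.channel)

    @property
    def y(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lookup[l] for l in self.labels])

    @property
    def length(self) -> int:
        return self.traces.shape[1]

    def subset(self, idx) -> "LabeledTraceSet":
        rep = None if self.replicate_id is None else self.replicate_id[idx]
        return LabeledTraceSet(self.traces[idx], self.labels[idx],
                               channel=self.channel, replicate_id=rep)

    def class_counts(self) -> dict[str, int]:
        names, counts = np.unique(self.labels, return_counts=True)
        out = {c: 0 for c in self.class_names}
        out.update(dict(zip(names, counts.astype(int))))
        return out


def compute_class_weights(counts) -> np.ndarray:
    """Inverse class frequency weights ``w_c = N / (K * n_c)``.

    Satisfies ``sum(n_c * w_c) == N`` exactly; the rarest class receives
    the largest weight. ``counts`` may be a sequence or a dict (values
    are used in key order for dicts, insertion order otherwise).
    """
    if isinstance(counts, dict):
        n = np.array([counts[k] for k in counts], dtype=float)
    else:
        n = np.asarray(counts, dtype=float)
    if (n < 1).any():
        raise ValueError("every class must have at least one example")
    return n.sum() / (len(n) * n)


def stratified_split(data: LabeledTraceSet, train_frac: float = 0.8,
                     seed: int = 0) -> tuple[LabeledTraceSet, LabeledTraceSet]:
    """Stratified, randomized train/validation partition (80/20 default)."""
    counts = np.array(list(data.class_counts().values()))
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 members for a stratified split")
    idx = np.arange(len(data.labels))
    tr, va = train_test_split(idx, train_size=train_frac, random_state=seed,
                              stratify=data.labels, shuffle=True)
    return data.subset(np.sort(tr)), data.subset(np.sort(va))


@dataclass
class TrainedModel:
    """A trained CNN plus everything needed to reuse it."""

    network: Network
    config: ModelConfig
    channel: str
    class_names: tuple
    metrics: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.network.state_dict())
        meta = {"config": self.config.to_dict(), "channel": self.channel,
                "class_names": list(self.class_names),
                "metrics": self.metrics}
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        config = ModelConfig.from_dict(meta["config"])
        net = config.build()
        state = dict(np.load(directory / "weights.npz"))
        net.load_state(state)
        return cls(network=net, config=config, channel=meta["channel"],
                   class_names=tuple(meta["class_names"]),
                   metrics=meta.get("metrics", {}))

    def classify_traces(self, raw_traces: np.ndarray) -> np.ndarray:
        """Z-score raw traces, then predict class names (pipeline step)."""
        x = np.asarray(raw_traces, dtype=float)
        sd = x.std(axis=1, keepdims=True)
        degenerate = (sd == 0).ravel()
        sd[sd == 0] = 1.0
        z = (x - x.mean(axis=1, keepdims=True)) / sd
        labels, _ = predict(self, z)
        labels[degenerate] = "rejected"
        return labels


def _metrics(y_true, y_pred) -> dict:
    return {"accuracy": float(accuracy_score(y_true, y_pred)),
            "macro_f1": float(f1_score(y_true, y_pred, average="macro",
                                       zero_division=0))}


def train(data: LabeledTraceSet, config: ModelConfig,
          weights: np.ndarray | None = None,
          val_data: LabeledTraceSet | None = None,
          seed: int | None = None) -> tuple[TrainedModel, dict]:
    """Train one CNN with inverse-class-frequency-weighted cross-entropy.

    Returns the trained model and metrics (validation metrics when
    ``val_data`` is given, otherwise training-set metrics). Fully
    deterministic given data, config and seed.
    """
    seed = config.seed if seed is None else seed
    counts = data.class_counts()
    present = np.array(list(counts.values()))
    if (present > 0).sum() < 2:
        raise ValueError("training needs at least 2 classes present")
    if config.n_classes != len(data.class_names):
        raise ValueError("config.n_classes does not match the channel class set")
    if weights is None:
        # weight only over classes present; absent classes get weight 0
        weights = np.zeros(len(present))
        nz = present > 0
        weights[nz] = compute_class_weights(present[nz])
    net = config.build(seed=derive_seed(seed, "init"))
    net.fit(data.traces, data.y, np.asarray(weights, dtype=float),
            lr=config.learning_rate, batch_size=config.batch_size,
            epochs=config.max_epochs, seed=derive_seed(seed, "batches"))
    model = TrainedModel(network=net, config=config, channel=data.channel,
                         class_names=data.class_names)
    eval_set = val_data if val_data is not None else data
    pred, _ = predict(model, eval_set.traces)
    metrics = _metrics(eval_set.labels, pred)
    metrics["evaluated_on"] = "validation" if val_data is not None else "train"
    model.metrics = metrics
    return model, metrics


def predict(model: TrainedModel, traces: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Classify Z-scored traces; returns (class names, class probabilities).

    Traces shorter than the model input length are zero-padded, longer
    ones truncated — both with a warning; anything but a 2-D float array
    is an error. Inference is deterministic and batch-size invariant.
    """
    x = np.asarray(traces, dtype=np.float32)
    if x.ndim == 1:
        x = x[None]
    if x.ndim != 2:
        raise ValueError("traces must be a (n, L) array")
    L = model.config.input_length
    if x.shape[1] != L:
        if x.shape[1] < L:
            warnings.warn(f"zero-padding traces from {x.shape[1]} to {L}",
                          stacklevel=2)
            x = np.pad(x, ((0, 0), (0, L - x.shape[1])))
        else:
            warnings.warn(f"truncating traces from {x.shape[1]} to {L}",
                          stacklevel=2)
            x = x[:, :L]
    probs = model.network.predict_proba(x)
    labels = np.array([model.class_names[i] for i in probs.argmax(axis=1)])
    return labels, probs


@dataclass
class CvReport:
    """Per-fold accuracy and macro-F1 from stratified k-fold CV."""

    fold_accuracy: list
    fold_macro_f1: list

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy))

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean(self.fold_macro_f1))

    @property
    def sd_macro_f1(self) -> float:
        return float(np.std(self.fold_macro_f1))


def cross_validate(data: LabeledTraceSet, config: ModelConfig, k: int = 5,
                   seed: int = 0) -> CvReport:
    """Stratified k-fold CV, retraining from fresh initialization per fold."""
    counts = data.class_counts()
    if min(counts.values()) < k:
        raise ValueError(f"every class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, f1s = [], []
    for fold, (tr, va) in enumerate(skf.split(data.traces, data.labels)):
        _, m = train(data.subset(tr), config, val_data=data.subset(va),
                     seed=derive_seed(seed, "fold", fold))
        accs.append(m["accuracy"])
        f1s.append(m["macro_f1"])
    return CvReport(fold_accuracy=accs, fold_macro_f1=f1s)


def default_demo_grid(n_classes: int = 4, input_length: int = 1000,
                      max_epochs: int = 8) -> list[ModelConfig]:
    """Demo architecture-search grid: 39 configurations.

    27 architectures (kernel in {5, 9, 15} x filters in {8, 16, 32} x
    dense in {(32,), (64,), (64, 32)}) at learning rate 1e-3, plus 12
    learning-rate variants at 1e-4 (the 9 kernel x filter combinations
    with dense (64,), and the three dense layouts at kernel 9 /
    filters 16 excluding the duplicate), spanning the three varied axes:
    kernel size, filter count, dense configuration.
    """
    grid = []
    kernels, filters, denses = (5, 9, 15), (8, 16, 32), ((32,), (64,), (64, 32))
    for k in kernels:
        for f in filters:
            for d in denses:
                grid.append(ModelConfig(conv_blocks=((k, f), (k, 2 * f)),
                                        pool_size=5, dense_layers=d,
                                        n_classes=n_classes,
                                        learning_rate=1e-3,
                                        input_length=input_length,
                                        max_epochs=max_epochs))
    for k in kernels:
        for f in filters:
            grid.append(ModelConfig(conv_blocks=((k, f), (k, 2 * f)),
                                    pool_size=5, dense_layers=(64,),
                                    n_classes=n_classes, learning_rate=1e-4,
                                    input_length=input_length,
                                    max_epochs=max_epochs))
    for d in ((32,), (64, 32), (32, 32)):
        grid.append(ModelConfig(conv_blocks=((9, 16), (9, 32)), pool_size=5,
                                dense_layers=d, n_classes=n_classes,
                                learning_rate=1e-4,
                                input_length=input_length,
                                max_epochs=max_epochs))
    assert len(grid) == 39
    return grid


def architecture_search(data: LabeledTraceSet, grid: list[ModelConfig],
                        seed: int = 0, top_k: int = 5, cv_folds: int = 5
                        ) -> tuple[ModelConfig, pd.DataFrame]:
    """Exploratory architecture search, then CV-based final selection.

    Every config is trained once on a stratified 80/20 split and ranked
    by validation accuracy (ties: higher macro-F1, then fewer
    parameters). The top ``top_k`` go through stratified
    ``cv_folds``-fold cross-validation; the final pick maximizes mean CV
    accuracy. Returns the winning config and the ranked results table.
    """
    if not grid:
        raise ValueError("architecture grid is empty")
    tr, va = stratified_split(data, 0.8, seed=derive_seed(seed, "search-split"))
    rows = []
    for i, cfg in enumerate(grid):
        model, m = train(tr, cfg, val_data=va, seed=derive_seed(seed, "cfg", i))
        rows.append({"config_index": i, "val_accuracy": m["accuracy"],
                     "val_macro_f1": m["macro_f1"],
                     "n_params": model.network.n_params})
    table = pd.DataFrame(rows).sort_values(
        by=["val_accuracy", "val_macro_f1", "n_params"],
        ascending=[False, False, True], kind="mergesort").reset_index(drop=True)
    finalists = table.head(top_k)["config_index"].tolist()
    cv_means = {}
    if len(finalists) == 1:
        best = finalists[0]
        cv_means[best] = float("nan")
    else:
        for i in finalists:
            rep = cross_validate(data, grid[i], k=cv_folds,
                                 seed=derive_seed(seed, "cv", i))
            cv_means[i] = rep.mean_accuracy
        best = max(finalists, key=lambda i: cv_means[i])
    table["cv_mean_accuracy"] = table["config_index"].map(cv_means)
    return grid[best], table
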