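"""Event-level deep neural network: the F-DNN and L-DNN classifiers.

Architecture: a fully connected 13 -> 64 -> 128 -> 64 -> 14 network with
ReLU hidden activations, softmax output, categorical cross-entropy loss and
the Adam optimizer, no dropout. Training stops when the per-epoch training
loss drops below the cost target (default 0.08) or after ``max_epochs``.

The network is backed by scikit-learn's ``MLPClassifier``, driven one epoch
at a time through ``partial_fit`` so the cost-target stopping rule and the
full loss history are under our control. Training is deterministic for a
fixed seed and single-threaded BLAS; with multi-threaded BLAS, floating-
point reduction order can perturb results in the last few ulps.

Inputs are raw, uncompensated intensities; the only preprocessing is a
single global affine rescale (division by one scalar, by default the
maximum absolute intensity of the training pool, frozen into the model) to
condition optimization without changing the "raw data" semantics.

Two instantiations share all machinery:

* **F-DNN** — trained on every case of the development cohort.
* **L-DNN** — trained only on cases with fewer than 1000 ground-truth CLL
  events (MRD-negative cases included), specializing it to the low-count
  regime the F-DNN quantifies poorly.

The event pools are split 80:10:10 into train/validation/test at the event
level (not the case level): events from one case can appear in more than
one pool. This mirrors the intended use — per-event gating with case-level
reassembly via retained provenance — and is documented rather than "fixed".
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .fcs_io import CaseSample, EventMatrix, PanelMismatchError
from .ontology import CLASSES, N_CHANNELS, N_CLASSES, class_ids

__all__ = [
    "NetworkSpec",
    "SplitSpec",
    "EventPool",
    "EventSplit",
    "TrainedModel",
    "EventPrediction",
    "split_events",
    "train",
    "train_f_dnn",
    "train_l_dnn",
    "predict",
    "LOW_COUNT_CASE_THRESHOLD",
]

#: Cases with fewer ground-truth CLL events than this belong to the
#: low-count training stratum (the L-DNN cohort).
LOW_COUNT_CASE_THRESHOLD = 1000


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the event classifier network."""

    input_dim: int = N_CHANNELS
    hidden: tuple[int, ...] = (64, 128, 64)
    output_dim: int = N_CLASSES
    hidden_activation: str = "relu"
    output_activation: str = "softmax"
    loss: str = "categorical_crossentropy"
    optimizer: str = "adam"
    cost_target: float = 0.08
    max_epochs: int = 3000
    batch_size: int = 4096
    learning_rate: float = 1e-3
    #: Fixed divisor for the affine input rescale. 2^10 places typical
    #: positive-marker intensities at order 1-100, conditioning Adam updates
    #: for dim-population boundaries; None uses the training-pool max.
    scale: float | None = 1024.0

    def __post_init__(self) -> None:
        if self.cost_target <= 0:
            raise ValueError("cost_target must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """Event-level train/validation/test split fractions (sum to 1)."""

    fractions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(eq=False)
class EventPool:
    """A pool of events with integer class ids and per-event provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: pd.DataFrame  # columns: case_id, event_index

    @property
    def n_events(self) -> int:
        return len(self.y)


@dataclass(eq=False)
class EventSplit:
    train: EventPool
    validation: EventPool
    test: EventPool


def split_events(cohort: Sequence[CaseSample], spec: SplitSpec) -> EventSplit:
    """Partition all cohort events into train/validation/test pools.

    Every event lands in exactly one pool; the assignment is a deterministic
    function of the event's position in the pooled cohort and the split
    seed. Pool sizes follow round(fraction * N) for train and validation,
    with the test pool taking the remainder. Provenance (case id, in-case
    event index) is retained so case-level results can be reassembled.
    """
    for case in cohort:
        if case.truth is None:
            raise ValueError(f"case {case.case_id!r} has no ground-truth labels")
    if not cohort:
        raise ValueError("cohort is empty")
    X = np.vstack([c.events.values for c in cohort])
    y = np.concatenate([class_ids(c.truth) for c in cohort])
    prov = pd.DataFrame(
        {
            "case_id": np.concatenate(
                [np.full(c.n_events, c.case_id, dtype=object) for c in cohort]
            ),
            "event_index": np.concatenate(
                [np.arange(c.n_events) for c in cohort]
            ),
        }
    )
    n = len(y)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(round(spec.fractions[0] * n))
    n_val = int(round(spec.fractions[1] * n))
    parts = (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )
    pools = [
        EventPool(X[idx], y[idx], prov.iloc[idx].reset_index(drop=True))
        for idx in parts
    ]
    return EventSplit(*pools)


@dataclass(eq=False)
class TrainedModel:
    """A trained network plus its training state and bookkeeping."""

    clf: MLPClassifier
    spec: NetworkSpec
    seed: int
    scale: float
    loss_history: list[float]
    val_loss_history: list[float]
    epochs_run: int
    training_cohort_tag: str = "F"  # F (full cohort) or L (low-count cohort)
    target_not_reached: bool = False
    class_order: tuple[str, ...] = CLASSES

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]

    def save(self, path: str | Path) -> None:
        """Checkpoint weights + spec + seed + ontology order."""
        with open(path, "wb") as fh:
            pickle.dump({"format": "mrdflow-model-v1", "model": self}, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if not (isinstance(blob, dict) and blob.get("format") == "mrdflow-model-v1"):
            raise ValueError(f"{path}: not a recognized model checkpoint")
        return blob["model"]

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.epochs_run + 1),
                "loss": self.loss_history,
                "val_loss": self.val_loss_history,
            }
        )


@dataclass(eq=False)
class EventPrediction:
    """Per-event class probabilities (simplex rows) and argmax labels."""

    probabilities: np.ndarray  # N x 14
    predicted_ids: np.ndarray  # N, int
    class_order: tuple[str, ...] = CLASSES

    @property
    def predicted_labels(self) -> np.ndarray:
        return np.asarray(self.class_order, dtype=object)[self.predicted_ids].astype(str)

    def __len__(self) -> int:
        return len(self.predicted_ids)


def train(
    spec: NetworkSpec,
    train_pool: EventPool,
    validation_pool: EventPool | None = None,
    seed: int = 0,
    *,
    training_cohort_tag: str = "F",
    verbose: bool = False,
) -> TrainedModel:
    """Train the network until the cost target is met or epochs run out.

    The monitored cost is the mean training-pool cross-entropy of each
    epoch; validation loss is recorded alongside but does not drive
    stopping (no early stopping, matching the design). If the target is
    never reached the model is returned flagged ``target_not_reached``
    with a warning, not an error.
    """
    if train_pool.n_events == 0:
        raise ValueError("training pool is empty")
    scale = spec.scale or float(np.abs(train_pool.X).max()) or 1.0
    Xtr = np.asarray(train_pool.X, dtype=np.float64) / scale
    ytr = train_pool.y
    Xval = yval = None
    if validation_pool is not None and validation_pool.n_events:
        Xval = np.asarray(validation_pool.X, dtype=np.float64) / scale
        yval = validation_pool.y

    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden,
        activation=spec.hidden_activation,
        solver=spec.optimizer,
        alpha=0.0,  # no weight penalty: regularization is deliberately absent
        batch_size=min(spec.batch_size, len(ytr)),
        learning_rate_init=spec.learning_rate,
        shuffle=True,
        random_state=seed,
        max_iter=1,
    )
    all_ids = np.arange(spec.output_dim)
    loss_hist: list[float] = []
    val_hist: list[float] = []
    reached = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-epoch ConvergenceWarning is expected
        for epoch in range(spec.max_epochs):
            if epoch == 0:
                clf.partial_fit(Xtr, ytr, classes=all_ids)
            else:
                clf.partial_fit(Xtr, ytr)
            loss_hist.append(float(clf.loss_))
            if Xval is not None:
                val_hist.append(
                    float(log_loss(yval, clf.predict_proba(Xval), labels=all_ids))
                )
            else:
                val_hist.append(float("nan"))
            if verbose:
                print(f"epoch {epoch + 1}: loss={loss_hist[-1]:.4f}")
            if loss_hist[-1] < spec.cost_target:
                reached = True
                break
    if not reached:
        warnings.warn(
            f"cost target {spec.cost_target} not reached after "
            f"{spec.max_epochs} epochs (final loss {loss_hist[-1]:.4f})",
            stacklevel=2,
        )
    return TrainedModel(
        clf=clf,
        spec=spec,
        seed=seed,
        scale=scale,
        loss_history=loss_hist,
        val_loss_history=val_hist,
        epochs_run=len(loss_hist),
        training_cohort_tag=training_cohort_tag,
        target_not_reached=not reached,
    )


def _train_on_cohort(
    cohort: Sequence[CaseSample],
    spec: NetworkSpec,
    split_spec: SplitSpec,
    seed: int,
    tag: str,
) -> tuple[TrainedModel, EventSplit]:
    split = split_events(cohort, split_spec)
    model = train(
        spec, split.train, split.validation, seed=seed, training_cohort_tag=tag
    )
    return model, split


def train_f_dnn(
    cohort: Sequence[CaseSample],
    spec: NetworkSpec = NetworkSpec(),
    split_spec: SplitSpec = SplitSpec(),
    seed: int = 0,
) -> tuple[TrainedModel, EventSplit]:
    """Train the full-cohort network (F-DNN) on every case."""
    return _train_on_cohort(cohort, spec, split_spec, seed, "F")


def low_count_cases(cohort: Sequence[CaseSample]) -> list[CaseSample]:
    """Cases with < 1000 ground-truth CLL events (MRD-negative included)."""
    out = []
    for c in cohort:
        if c.truth is None:
            raise ValueError(f"case {c.case_id!r} has no ground-truth labels")
        if int((c.truth == "CLL_cells").sum()) < LOW_COUNT_CASE_THRESHOLD:
            out.append(c)
    return out


def train_l_dnn(
    cohort: Sequence[CaseSample],
    spec: NetworkSpec = NetworkSpec(),
    split_spec: SplitSpec = SplitSpec(),
    seed: int = 0,
) -> tuple[TrainedModel, EventSplit]:
    """Train the low-count network (L-DNN) on the < 1000-CLL-event stratum."""
    subset = low_count_cases(cohort)
    if not subset:
        raise ValueError(
            "no cases with < 1000 CLL events: low-count cohort is empty"
        )
    return _train_on_cohort(subset, spec, split_spec, seed, "L")


def predict(
    model: TrainedModel,
    events: EventMatrix | np.ndarray,
    batch_size: int = 262_144,
) -> EventPrediction:
    """Classify events: per-event softmax probabilities and argmax labels.

    Outputs are independent of batching (a pure forward pass); argmax ties
    break toward the lower class id in the documented ontology order.
    """
    X = events.values if isinstance(events, EventMatrix) else np.asarray(events)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise PanelMismatchError(
            f"expected {model.spec.input_dim}-column events, got shape {X.shape}"
        )
    n = X.shape[0]
    if n == 0:
        return EventPrediction(
            probabilities=np.empty((0, model.spec.output_dim)),
            predicted_ids=np.empty(0, dtype=np.int64),
            class_order=model.class_order,
        )
    proba = np.empty((n, model.spec.output_dim))
    for start in range(0, n, batch_size):
        chunk = np.asarray(X[start : start + batch_size], dtype=np.float64)
        proba[start : start + batch_size] = model.clf.predict_proba(
            chunk / model.scale
        )
    ids = np.argmax(proba, axis=1).astype(np.int64)  # ties -> lowest class id
    return EventPrediction(
        probabilities=proba, predicted_ids=ids, class_order=model.class_order
    )
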