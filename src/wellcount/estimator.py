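"""The cell-counting CNN as a scikit-learn estimator.

:class:`CellCountCNN` wraps the network architecture and its training
protocol behind the standard ``fit`` / ``predict`` / ``predict_proba``
surface, so it composes with scikit-learn pipelines and model selection.
The protocol it implements:

* per-image min-max normalization to [0, 255], then scaling to [0, 1] at the
  network input;
* stratified mini-batches with a fixed per-category composition, by default
  77 / 21 / 10 / 11 samples from the 0, 1, 2 and >2-cell categories (119 per
  batch) — the heavy oversampling of rare categories is what makes the
  imbalanced counting task learnable;
* geometric augmentation (mirror or rotation) of about 20% of training draws;
* staged plate ("subset") scheduling: the first stages train on growing
  blocks of plates, later stages on random plate rotations — mini-batches are
  only ever drawn from the plates active in the current stage;
* plain SGD on the softmax cross-entropy, with periodic validation and early
  stopping on validation loss; the returned parameters are the best
  validation checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .network import NetworkSpec, build_spec
from .synth import CATEGORY_LABELS
from .wellio import SubsetPartition, WellImage, augment_image

#: per-category mini-batch composition for categories (0, 1, 2, >2)
DEFAULT_COMPOSITION: Tuple[int, int, int, int] = (77, 21, 10, 11)
#: staged schedule: (iterations, number of subsets) consumed in order
DEFAULT_STAGE_SCHEDULE: Tuple[Tuple[int, int], ...] = ((20000, 5), (10000, 5), (5000, 5))
#: after the fixed stages: repeated (iterations, subsets drawn at random)
DEFAULT_ROTATION_STAGE: Tuple[int, int] = (5000, 6)


@dataclass(frozen=True)
class TrainingConfig:
    """Bundle of the training-protocol knobs (mirrors the estimator params)."""

    minibatch_composition: Tuple[int, ...] = DEFAULT_COMPOSITION
    stage_schedule: Tuple[Tuple[int, int], ...] = DEFAULT_STAGE_SCHEDULE
    rotation_stage: Optional[Tuple[int, int]] = DEFAULT_ROTATION_STAGE
    max_iterations: Optional[int] = None
    learning_rate: float = 0.01
    eval_every: int = 100
    patience: int = 10
    transform_prob: float = 0.2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.minibatch_composition):
            raise ValueError("minibatch composition counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def batch_size(self) -> int:
        return int(sum(self.minibatch_composition))


@dataclass
class TrainingState:
    """Loss/accuracy traces recorded during training (one row per event)."""

    iterations: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)
    val_iterations: List[int] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    best_iteration: int = 0
    best_val_loss: float = np.inf
    stopped_early: bool = False


@dataclass(frozen=True)
class PredictionResult:
    """Posterior over the four categories for one well.

    ``highest_output`` is h(s), the maximum posterior entry — the confidence
    score used for ambiguity triage.  For a 4-way softmax it is >= 0.25.
    """

    posterior: np.ndarray
    predicted_category: int
    highest_output: float

    @property
    def predicted_label(self) -> str:
        return CATEGORY_LABELS[self.predicted_category]


def _category_pools(y: np.ndarray, n_categories: int = 4) -> List[np.ndarray]:
    return [np.flatnonzero(y == c) for c in range(n_categories)]


def compose_batch_indices(pools: Sequence[np.ndarray],
                          composition: Sequence[int],
                          rng: np.random.Generator) -> np.ndarray:
    """Indices of one stratified mini-batch.

    Draws ``composition[c]`` samples uniformly from ``pools[c]``; without
    replacement when the pool is large enough, with replacement otherwise
    (rare categories on a small plate).  Raises if a category is empty.
    """
    parts = []
    for c, need in enumerate(composition):
        pool = pools[c]
        if len(pool) == 0:
            raise ValueError(
                f"category {CATEGORY_LABELS[c]!r} is absent from the training pool"
            )
        replace = len(pool) < need
        parts.append(rng.choice(pool, size=need, replace=replace))
    return np.concatenate(parts)


def sample_minibatch(pool: Sequence[WellImage], config: TrainingConfig,
                     rng: np.random.Generator) -> List[WellImage]:
    """One stratified, augmented mini-batch of labeled :class:`WellImage`.

    Composition follows ``config.minibatch_composition`` exactly; each chosen
    image passes through the geometric augmentation.
    """
    y = np.array([w.category for w in pool])
    if np.any(y == None):  # noqa: E711  (None-valued categories)
        raise ValueError("all pool images need a true category")
    idx = compose_batch_indices(_category_pools(y.astype(int)),
                                config.minibatch_composition, rng)
    return [augment_image(pool[i], rng, config.transform_prob) for i in idx]


class CellCountCNN(ClassifierMixin, BaseEstimator):
    """CNN classifier of nanoliter-well images into 0 / 1 / 2 / >2 cells.

    Parameters
    ----------
    input_side : int or None
        Side of the (square) input images; inferred from ``X`` at fit time
        when None.  511 instantiates the native architecture.
    minibatch_composition : tuple of 4 ints
        Per-category counts in each training batch.
    stage_schedule : tuple of (n_iterations, n_subsets) or None
        Plate-block schedule; None uses the reference schedule.  Only
        meaningful when ``fit`` receives ``subset_ids``.
    rotation_stage : tuple (n_iterations, n_subsets) or None
        Stage repeated after the fixed schedule, drawing random subsets.
    n_iterations : int or None
        Total iteration budget.  When set without ``subset_ids`` this is the
        whole schedule (single stage over all data); with a stage schedule it
        caps the total.
    learning_rate : float
        Plain-SGD step size.
    dropout_rate : float
        Dropout on the two fully connected layers during training.
    transform_prob : float
        Probability that a training draw is mirrored/rotated.
    eval_every, patience : int
        Validate every ``eval_every`` iterations; stop after ``patience``
        validations without improvement in validation loss.
    random_state : int or None
        Seed for initialization, batch sampling, augmentation and dropout.

    Attributes
    ----------
    classes_ : ndarray (4,)
        Category codes 0..3 (3 = more than 2 cells).
    model_ : the fitted network (best validation checkpoint)
    spec_ : the instantiated :class:`NetworkSpec`
    history_ : :class:`TrainingState`
    n_iter_ : iterations actually run
    """

    def __init__(
        self,
        input_side: Optional[int] = None,
        minibatch_composition: Tuple[int, ...] = DEFAULT_COMPOSITION,
        stage_schedule: Optional[Tuple[Tuple[int, int], ...]] = None,
        rotation_stage: Optional[Tuple[int, int]] = DEFAULT_ROTATION_STAGE,
        n_iterations: Optional[int] = None,
        learning_rate: float = 0.01,
        dropout_rate: float = 0.3,
        transform_prob: float = 0.2,
        eval_every: int = 100,
        patience: int = 10,
        batch_chunk: int = 64,
        random_state: Optional[int] = None,
    ):
        self.input_side = input_side
        self.minibatch_composition = minibatch_composition
        self.stage_schedule = stage_schedule
        self.rotation_stage = rotation_stage
        self.n_iterations = n_iterations
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.transform_prob = transform_prob
        self.eval_every = eval_every
        self.patience = patience
        self.batch_chunk = batch_chunk
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, subset_ids: Optional[Sequence] = None,
            X_val=None, y_val=None):
        """Train on raw images ``X`` (n, side, side) with category codes ``y``.

        ``subset_ids`` assigns each sample to a plate/subset and activates the
        staged schedule; ``X_val``/``y_val`` supply a validation set for early
        stopping (without one, training runs the full budget and keeps the
        final parameters).
        """
        X = np.asarray(X)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"X must be (n, side, side), got {X.shape}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if y.size and (y.min() < 0 or y.max() > 3):
            raise ValueError("y must contain category codes 0..3")
        side = self.input_side or X.shape[1]
        self.spec_: NetworkSpec = build_spec(side, dropout_rate=self.dropout_rate)
        rng = np.random.default_rng(self.random_state)
        model = _nn.Sequential(self.spec_, seed=rng.integers(2**31))
        self.classes_ = np.arange(4)
        self.n_features_in_ = side * side

        Xn = self._condition(X)
        Xv = self._condition(np.asarray(X_val)) if X_val is not None else None
        yv = np.asarray(y_val, dtype=int) if y_val is not None else None

        stages = self._resolve_stages(subset_ids)
        subset_ids = np.asarray(subset_ids) if subset_ids is not None else None

        state = TrainingState()
        composition = tuple(self.minibatch_composition)
        best_params = model.state_dict()
        since_best = 0
        it = 0
        budget = self._total_budget()
        stop = False
        for stage_subsets, stage_iters in stages:
            if stop or it >= budget:
                break
            if subset_ids is None:
                active = np.arange(len(y))
            else:
                active = np.flatnonzero(np.isin(subset_ids, stage_subsets))
            pools = _category_pools(y[active])
            pools = [active[p] for p in pools]
            for _ in range(stage_iters):
                if it >= budget:
                    break
                idx = compose_batch_indices(pools, composition, rng)
                xb = self._augment_batch(Xn[idx], rng)
                loss, acc = model.loss_and_backward(xb, y[idx], rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at iteration {it}; "
                        "the learning rate is likely too high"
                    )
                model.sgd_step(self.learning_rate)
                it += 1
                state.iterations.append(it)
                state.train_loss.append(loss)
                state.train_accuracy.append(acc)
                if Xv is not None and it % self.eval_every == 0:
                    vl, va = self._evaluate(model, Xv, yv)
                    state.val_iterations.append(it)
                    state.val_loss.append(vl)
                    state.val_accuracy.append(va)
                    if vl < state.best_val_loss:
                        state.best_val_loss = vl
                        state.best_iteration = it
                        best_params = model.state_dict()
                        since_best = 0
                    else:
                        since_best += 1
                        if since_best >= self.patience:
                            state.stopped_early = True
                            stop = True
                            break
            if stop:
                break
        if Xv is not None and state.val_iterations:
            model.load_state(best_params)
        else:
            state.best_iteration = it
        self.model_ = model
        self.history_ = state
        self.n_iter_ = it
        return self

    # ------------------------------------------------------------ internals
    def _total_budget(self) -> int:
        if self.n_iterations is not None:
            return int(self.n_iterations)
        fixed = sum(n for n, _ in (self.stage_schedule or DEFAULT_STAGE_SCHEDULE))
        # without an explicit budget, allow four rotation stages past the
        # fixed schedule; early stopping normally ends training before that
        rot = self.rotation_stage[0] * 4 if self.rotation_stage else 0
        return fixed + rot

    def _resolve_stages(self, subset_ids):
        """Yield (subset list, n_iterations) stages in execution order."""
        if subset_ids is None:
            total = self._total_budget()
            return [((), total)] if total else []
        ids = list(dict.fromkeys(np.asarray(subset_ids).tolist()))  # first-appearance order
        schedule = self.stage_schedule or DEFAULT_STAGE_SCHEDULE
        stages = []
        cursor = 0
        for n_iter, n_sub in schedule:
            block = ids[cursor : cursor + n_sub]
            if not block:  # fewer subsets than the schedule assumes
                block = ids
            stages.append((block, n_iter))
            cursor += n_sub
        if self.rotation_stage is not None:
            srng = np.random.default_rng(
                None if self.random_state is None else self.random_state + 1
            )
            n_iter, n_sub = self.rotation_stage
            for _ in range(64):  # bounded; the budget/early stop ends sooner
                pick = srng.choice(len(ids), size=min(n_sub, len(ids)), replace=False)
                stages.append(([ids[i] for i in pick], n_iter))
        return stages

    def _condition(self, X: np.ndarray) -> np.ndarray:
        """Per-image min-max to [0, 255], then scale to [0, 1] (float32)."""
        X = X.astype(np.float32)
        lo = X.min(axis=(1, 2), keepdims=True)
        hi = X.max(axis=(1, 2), keepdims=True)
        span = hi - lo
        span[span == 0] = np.inf  # constant images -> all zeros
        return (X - lo) / span

    def _augment_batch(self, xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = xb.copy()
        for i in range(len(out)):
            out[i] = augment_image(out[i], rng, self.transform_prob)
        return out

    def _evaluate(self, model: _nn.Sequential, Xv: np.ndarray, yv: np.ndarray
                  ) -> Tuple[float, float]:
        losses, correct = [], 0
        for start in range(0, len(Xv), self.batch_chunk):
            xb = Xv[start : start + self.batch_chunk]
            yb = yv[start : start + self.batch_chunk]
            probs = model.predict_proba(xb)
            losses.append(-np.log(np.maximum(probs[np.arange(len(yb)), yb], 1e-12)))
            correct += int((probs.argmax(axis=1) == yb).sum())
        return float(np.mean(np.concatenate(losses))), correct / len(yv)

    # ------------------------------------------------------------- predict
    def _forward_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        Xn = self._condition(X)
        out = []
        for start in range(0, len(Xn), self.batch_chunk):
            out.append(self.model_.predict_proba(Xn[start : start + self.batch_chunk]))
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probabilities (n, 4) over the categories 0, 1, 2, >2."""
        return self._forward_proba(X)

    def predict(self, X) -> np.ndarray:
        """Predicted category codes (argmax of the posterior)."""
        return self._forward_proba(X).argmax(axis=1)

    def predict_result(self, X) -> List[PredictionResult]:
        """Per-well :class:`PredictionResult` (posterior, argmax, h(s))."""
        probs = self._forward_proba(X)
        return [
            PredictionResult(p, int(p.argmax()), float(p.max())) for p in probs
        ]

    def highest_outputs(self, X) -> np.ndarray:
        """h(s) = max posterior entry, per well."""
        return self._forward_proba(X).max(axis=1)


# ---------------------------------------------------------------- wrappers
def build_network(spec: NetworkSpec, seed: int = 0) -> _nn.Sequential:
    """Instantiate a differentiable network from an architecture spec."""
    return _nn.Sequential(spec, seed=seed)


def predict(model, images) -> List[PredictionResult]:
    """Per-image predictions from a fitted estimator or a bare network.

    Images are min-max normalized before entering the network; no
    augmentation, dropout disabled.
    """
    if isinstance(model, CellCountCNN):
        return model.predict_result(images)
    X = np.asarray(images, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    lo = X.min(axis=(1, 2), keepdims=True)
    hi = X.max(axis=(1, 2), keepdims=True)
    span = np.where(hi > lo, hi - lo, np.inf)
    probs = model.predict_proba((X - lo) / span)
    return [PredictionResult(p, int(p.argmax()), float(p.max())) for p in probs]


def train_on_plates(
    plates: Dict[str, Sequence[WellImage]],
    partition: SubsetPartition,
    estimator: Optional[CellCountCNN] = None,
    **estimator_kwargs,
) -> CellCountCNN:
    """Fit a :class:`CellCountCNN` from plates grouped per the partition.

    ``plates`` maps plate id -> list of labeled :class:`WellImage` (as
    returned by :func:`wellcount.wellio.load_dataset`).  Training plates feed
    the staged schedule in partition order; validation plates drive early
    stopping; test plates are ignored here.
    """
    for role, ids in (("train", partition.train_subsets),
                      ("validation", partition.validation_subsets)):
        for pid in ids:
            if pid not in plates:
                raise KeyError(f"{role} plate {pid!r} not found in dataset")
    def stack(ids):
        xs, ys, sids = [], [], []
        for pid in ids:
            for w in plates[pid]:
                if w.category is None:
                    raise ValueError(f"well {w.well_id} has no true category")
                xs.append(w.pixels)
                ys.append(w.category)
                sids.append(pid)
        return np.stack(xs), np.array(ys), np.array(sids)

    X, y, sids = stack(partition.train_subsets)
    est = estimator if estimator is not None else CellCountCNN(**estimator_kwargs)
    if partition.validation_subsets:
        Xv, yv, _ = stack(partition.validation_subsets)
        est.fit(X, y, subset_ids=sids, X_val=Xv, y_val=yv)
    else:
        est.fit(X, y, subset_ids=sids)
    return est
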