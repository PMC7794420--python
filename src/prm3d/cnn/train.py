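"""Training loop and stratified five-fold cross-validation.

"Iterations" are optimizer steps over mini-batches, not epochs: the
reference configuration is 2500 iterations at batch size 50 with Adam at
learning rate 1e-4.  A desk-scale configuration (a few hundred iterations,
batch 25) is the default here; the full schedule is one constructor argument
away.  Batches are drawn by reshuffling the training set every epoch with
the run's seeded generator, so a (dataset, config, seed) triple reproduces
bit-identical training.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ..evaluation import EvalReport, evaluate_predictions
from ..preprocess import NetworkInput
from .layers import Adam, cross_entropy, softmax
from .model import CNN3D, build_model, stack_inputs


@dataclass
class TrainConfig:
    """Optimizer schedule; defaults are the desk-scale configuration."""

    iterations: int = 300
    batch_size: int = 25
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.iterations < 1:
            raise ValueError("batch size and iterations must be ≥ 1")


FULL_SCALE = TrainConfig(iterations=2500, batch_size=50)


@dataclass
class FoldResult:
    """Outcome of training on one fold."""

    fold: int
    model: CNN3D
    loss_history: list[float]
    acc_history: list[float]
    test_ids: list[str] = dc_field(default_factory=list)
    test_labels: np.ndarray | None = None
    test_probs: np.ndarray | None = None  # P(COPD) per test subject


def train(model: CNN3D, dataset: list[NetworkInput], cfg: TrainConfig,
          fold: int = 0) -> FoldResult:
    """Train in place; records per-iteration batch loss and accuracy."""
    if not dataset:
        raise ValueError("empty training dataset")
    x, labels = stack_inputs(dataset)
    if labels.min() < 0:
        raise ValueError("all training inputs need labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    n = len(dataset)
    batch = min(cfg.batch_size, n)
    order = rng.permutation(n)
    cursor = 0
    loss_hist, acc_hist = [], []
    for _ in range(cfg.iterations):
        if cursor + batch > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor:cursor + batch]
        cursor += batch
        xb, yb = x[idx], labels[idx]
        logits = model.forward(xb, train=True)
        probs = softmax(logits)
        loss_hist.append(cross_entropy(probs, yb))
        acc_hist.append(float(np.mean(probs.argmax(axis=1) == yb)))
        dlogits = probs.copy()
        dlogits[np.arange(len(yb)), yb] -= 1.0
        model.backward(dlogits / len(yb))
        opt.step(model.grads())
    # one extra pass over the full training set fixing the BN population
    # statistics at the final weights; a class-imbalanced subset would skew
    # the activation statistics and with them the probability calibration
    model.recalibrate_batchnorm(x, batch_size=batch)
    model.clear_caches()
    return FoldResult(fold=fold, model=model, loss_history=loss_hist,
                      acc_history=acc_hist)


def fold_partition(labels: np.ndarray, k: int, seed: int = 0
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train, test) index pairs: a disjoint cover with
    per-fold class ratios within one subject of the global ratio."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(dataset: list[NetworkInput], k: int = 5,
                   cfg: TrainConfig | None = None,
                   ) -> tuple[list[FoldResult], EvalReport]:
    """Stratified k-fold cross-validation with pooled test-fold predictions.

    Every subject appears in exactly one test fold; per-fold class ratios
    stay within one subject of the global ratio.  Returns the per-fold
    results (each with its trained model and held-out predictions) plus the
    evaluation report on the pooled predictions.
    """
    if cfg is None:
        cfg = TrainConfig()
    if k < 2:
        raise ValueError("need at least 2 folds")
    labels = np.array([inp.label for inp in dataset])
    if np.bincount(labels, minlength=2).min() < k:
        raise ValueError(f"need at least {k} subjects per class")
    channels = dataset[0].values.shape[0]
    results: list[FoldResult] = []
    for fold, (tr_idx, te_idx) in enumerate(fold_partition(labels, k, cfg.seed)):
        model = build_model(channels, seed=cfg.seed + fold)
        fold_cfg = TrainConfig(cfg.iterations, cfg.batch_size,
                               cfg.learning_rate, cfg.seed + fold)
        res = train(model, [dataset[i] for i in tr_idx], fold_cfg, fold=fold)
        x_te, y_te = stack_inputs([dataset[i] for i in te_idx])
        probs = model.predict_proba(x_te)
        res.test_ids = [dataset[i].subject_id for i in te_idx]
        res.test_labels = y_te
        res.test_probs = probs[:, 1]
        results.append(res)
    pooled_probs = np.concatenate([r.test_probs for r in results])
    pooled_labels = np.concatenate([r.test_labels for r in results])
    report = evaluate_predictions(pooled_probs, pooled_labels)
    return results, report
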