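"""Bag construction and gradient training of the attention MIL model.

Bags are homogeneous: all instances of a bag belong to one cancer type and
the bag carries that label. Two sampling schemes are provided —
``epoch_partition`` (shuffle each class and chunk into bags of K; a
remainder of at least 2 samples stays as a smaller bag, a singleton is
dropped for that epoch) and ``resample`` (per class, draw a fixed number of
bags of K distinct samples). ``equal_bags`` gives every class the same
number of bags per epoch regardless of class size, the safer default under
strong class imbalance; ``proportional`` draws bags in proportion to class
size.

The optimizer is Adam with decoupled weight decay on the weight matrices;
plain gradient descent is available for diagnostics (its full-batch loss
curve is monotone at small learning rates, a property the tests assert).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .io import LabeledCohort, split_cohort
from .mil import Bag, MILModelParams, bag_nll, classify_bag, forward_backward
from .utils import derive_seed, logger


@dataclass
class TrainConfig:
    bag_size: int = 10
    bags_per_class_per_epoch: int = 8
    epochs: int = 100
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0
    class_balancing: Literal["equal_bags", "proportional"] = "equal_bags"
    early_stop_patience: int = 10
    bag_mode: Literal["epoch_partition", "resample"] = "resample"
    optimizer: Literal["adam", "sgd"] = "adam"
    val_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.bag_size < 2:
            raise ValueError("bag_size must be >= 2 for training")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class EvalReport:
    bag_accuracy: float
    instance_accuracy: float
    confusion: np.ndarray  # (C, C), rows = true class, row-stochastic over predictions
    class_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "bag_accuracy": self.bag_accuracy,
            "instance_accuracy": self.instance_accuracy,
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
        }


def make_bags(cohort: LabeledCohort, K: int, seed: int,
              mode: Literal["epoch_partition", "resample"] = "epoch_partition",
              bags_per_class: int = 8,
              class_balancing: Literal["equal_bags", "proportional"] = "equal_bags",
              ) -> list[Bag]:
    """Build homogeneous bags of up to K instances per class."""
    rng = np.random.default_rng(seed)
    X = cohort.matrix.values.astype(float)
    by_class: dict[int, list[int]] = {c: [] for c in range(cohort.n_classes)}
    pos = {c: i for i, c in enumerate(cohort.class_names)}
    for i, s in enumerate(cohort.matrix.sample_ids):
        by_class[pos[cohort.labels[s]]].append(i)

    counts = {c: len(idx) for c, idx in by_class.items()}
    bags: list[Bag] = []
    for c in range(cohort.n_classes):
        idx = by_class[c]
        if len(idx) < 2:
            if idx:
                logger.warning("class %r has a single sample; excluded from bagging",
                               cohort.class_names[c])
            continue
        if mode == "epoch_partition":
            order = rng.permutation(len(idx))
            shuffled = [idx[i] for i in order]
            for start in range(0, len(shuffled), K):
                chunk = shuffled[start:start + K]
                if len(chunk) < 2:
                    continue  # singleton remainder dropped this epoch
                bags.append(_bag(cohort, X, chunk, c))
        elif mode == "resample":
            n_bags = bags_per_class
            if class_balancing == "proportional":
                total = sum(counts.values())
                n_bags = max(1, round(bags_per_class * cohort.n_classes
                                      * counts[c] / total))
            size = min(K, len(idx))
            for _ in range(n_bags):
                chosen = rng.choice(len(idx), size=size, replace=False)
                bags.append(_bag(cohort, X, [idx[i] for i in chosen], c))
        else:
            raise ValueError(f"unknown bag mode {mode!r}")
    return bags


def _bag(cohort: LabeledCohort, X: np.ndarray, rows: list[int], label: int) -> Bag:
    ids = [cohort.matrix.sample_ids[i] for i in rows]
    return Bag(instances=X[rows], sample_ids=ids, label=label)


class _Adam:
    def __init__(self, params: MILModelParams, lr: float, weight_decay: float):
        self.lr, self.wd = lr, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.arrays().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays().items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: MILModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            arr = getattr(params, k)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and arr.ndim > 1:  # decoupled decay, weights only
                update = update + self.wd * arr
            arr -= self.lr * update


class _SGD:
    def __init__(self, params: MILModelParams, lr: float, weight_decay: float):
        self.lr, self.wd = lr, weight_decay

    def step(self, params: MILModelParams, grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            arr = getattr(params, k)
            if self.wd and arr.ndim > 1:
                g = g + self.wd * arr
            arr -= self.lr * g


def fit_bags(params: MILModelParams, bags: list[Bag], epochs: int,
             learning_rate: float, weight_decay: float = 0.0,
             optimizer: Literal["adam", "sgd"] = "sgd",
             full_batch: bool = True) -> list[float]:
    """Low-level loop over a fixed bag set; returns per-epoch mean loss.

    With ``full_batch=True`` gradients are averaged over all bags before one
    update per epoch (plain gradient descent when ``optimizer='sgd'``).
    """
    opt = (_Adam if optimizer == "adam" else _SGD)(params, learning_rate, weight_decay)
    losses: list[float] = []
    for _ in range(epochs):
        if full_batch:
            total = 0.0
            acc: dict[str, np.ndarray] = {}
            for bag in bags:
                loss, grads = forward_backward(params, bag.instances, bag.label)
                total += loss
                for k, g in grads.items():
                    acc[k] = acc.get(k, 0) + g
            n = len(bags)
            opt.step(params, {k: g / n for k, g in acc.items()})
            losses.append(total / n)
        else:
            total = 0.0
            for bag in bags:
                loss, grads = forward_backward(params, bag.instances, bag.label)
                opt.step(params, grads)
                total += loss
            losses.append(total / len(bags))
    return losses


def train(cohort: LabeledCohort, selected_genes: Optional[list[str]],
          embed_dim: int = 128, attention_dim: int = 64,
          config: Optional[TrainConfig] = None,
          val_cohort: Optional[LabeledCohort] = None,
          ) -> tuple[MILModelParams, dict]:
    """Fit the MIL model by minimizing mean bag NLL over regenerated bags.

    Bags are rebuilt each epoch with an epoch-derived seed. A validation
    cohort (carved from the input when not given) drives early stopping on
    held-out bag NLL; the parameters returned are the best-validation ones.
    Deterministic given the config seed.
    """
    config = config or TrainConfig()
    if selected_genes is not None:
        cohort = LabeledCohort(cohort.matrix.subset_genes(selected_genes),
                               cohort.labels, cohort.class_names)
    if val_cohort is None and config.val_fraction > 0:
        cohort, val_cohort = split_cohort(
            cohort, config.val_fraction, derive_seed(config.seed, "val_split"))
    elif val_cohort is not None and selected_genes is not None:
        val_cohort = LabeledCohort(val_cohort.matrix.subset_genes(selected_genes),
                                   val_cohort.labels, val_cohort.class_names)

    D = cohort.matrix.n_genes
    C = cohort.n_classes
    params = MILModelParams.initialize(
        D, embed_dim, attention_dim, C, seed=derive_seed(config.seed, "init"),
        gene_ids=cohort.matrix.gene_ids, class_names=cohort.class_names)
    opt_cls = _Adam if config.optimizer == "adam" else _SGD
    opt = opt_cls(params, config.learning_rate, config.weight_decay)

    log: dict = {"epoch_loss": [], "val_nll": [], "val_bag_accuracy": [],
                 "stopped_epoch": None, "best_epoch": None}
    best_nll = np.inf
    best_params = params.copy()
    patience_left = config.early_stop_patience
    order_rng = np.random.default_rng(derive_seed(config.seed, "order"))

    for epoch in range(config.epochs):
        bags = make_bags(cohort, config.bag_size,
                         seed=derive_seed(config.seed, "bags", epoch),
                         mode=config.bag_mode,
                         bags_per_class=config.bags_per_class_per_epoch,
                         class_balancing=config.class_balancing)
        order = order_rng.permutation(len(bags))
        total = 0.0
        for i in order:
            bag = bags[i]
            loss, grads = forward_backward(params, bag.instances, bag.label)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, bag label "
                    f"{bag.label}; reduce the learning rate")
            opt.step(params, grads)
            total += loss
        log["epoch_loss"].append(total / max(len(bags), 1))

        if val_cohort is not None and val_cohort.matrix.n_samples:
            val_bags = make_bags(val_cohort, config.bag_size,
                                 seed=derive_seed(config.seed, "val_bags"),
                                 mode="epoch_partition")
            nlls, hits = [], 0
            for bag in val_bags:
                out = classify_bag(params, bag)
                nlls.append(bag_nll(out.bag_probs, bag.label))
                hits += int(np.argmax(out.bag_probs) == bag.label)
            val_nll = float(np.mean(nlls)) if nlls else np.nan
            log["val_nll"].append(val_nll)
            log["val_bag_accuracy"].append(hits / len(val_bags) if val_bags else np.nan)
            if val_nll < best_nll - 1e-9:
                best_nll = val_nll
                best_params = params.copy()
                log["best_epoch"] = epoch
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    log["stopped_epoch"] = epoch
                    break
        else:
            best_params = params

    if val_cohort is not None and log["best_epoch"] is not None:
        params = best_params
    return params, log


def evaluate(params: MILModelParams, cohort: LabeledCohort, K: int = 10,
             seed: int = 0) -> EvalReport:
    """Bag- and instance-level accuracy plus the row-stochastic confusion matrix.

    Bag accuracy uses an epoch-partition bagging of the cohort; instance
    accuracy and the confusion matrix use per-instance predicted classes
    (attention-normalized singleton-bag probabilities). Confusion rows are
    fractions of each true class assigned to each predicted class; rows of
    classes absent from the cohort are all-zero.
    """
    from .signatures import instance_predictions  # local import to avoid cycle

    bags = make_bags(cohort, K, seed=seed, mode="epoch_partition")
    hits = sum(int(np.argmax(classify_bag(params, b).bag_probs) == b.label) for b in bags)
    bag_accuracy = hits / len(bags) if bags else float("nan")

    preds = instance_predictions(params, bags)
    pos = {c: i for i, c in enumerate(cohort.class_names)}
    C = cohort.n_classes
    confusion = np.zeros((C, C))
    correct = 0
    for p in preds:
        true = pos[cohort.labels[p.sample_id]]
        confusion[true, p.predicted_class] += 1
        correct += int(p.predicted_class == true)
    instance_accuracy = correct / len(preds) if preds else float("nan")
    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        confusion = np.where(row_sums > 0, confusion / np.maximum(row_sums, 1), 0.0)
    return EvalReport(bag_accuracy, instance_accuracy, confusion, list(cohort.class_names))
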