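"""Transductive training protocol, metrics, and the repeat-and-aggregate runner.

Protocol: nodes are split 80/20 into train/test masks, the model is trained
full-batch with Adam (lr 1e-3, weight decay 1e-4) for a fixed 200 epochs,
the loss is computed on the training mask only, and classification metrics
(accuracy, NMI, macro-F1, ARI) are evaluated on the test mask.  Modularity
— a whole-graph partition property — is scored on the predicted partition
of all nodes.  Experiments are repeated with per-repeat reseeding
(``seed_i = base_seed + i``) and aggregated as mean ± std.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    adjusted_rand_score,
    f1_score,
    normalized_mutual_info_score,
)

from .autodiff import Tensor
from .graph import Graph, modularity
from .model import BatchStructure, DAMAModel, ModelConfig, model_loss

logger = logging.getLogger(__name__)

__all__ = [
    "SplitMasks", "TrainConfig", "MetricsReport", "Adam",
    "make_split", "train", "evaluate", "run_experiment", "aggregate_reports",
]


@dataclass(frozen=True)
class SplitMasks:
    train: np.ndarray
    test: np.ndarray
    seed: int


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 200
    repeats: int = 50
    base_seed: int = 0
    train_ratio: float = 0.8

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class MetricsReport:
    accuracy: float
    nmi: float
    f1_macro: float
    ari: float
    modularity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "nmi": self.nmi,
            "f1_macro": self.f1_macro, "ari": self.ari,
            "modularity": self.modularity,
        }


def make_split(n_labeled: int, ratio: float = 0.8, seed: int = 0) -> SplitMasks:
    """Random boolean train/test masks, reproducible given the seed."""
    if n_labeled < 5:
        raise ValueError("need at least 5 labeled nodes to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_labeled)
    n_train = int(np.floor(ratio * n_labeled))
    train = np.zeros(n_labeled, dtype=bool)
    train[perm[:n_train]] = True
    return SplitMasks(train=train, test=~train, seed=seed)


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    x: np.ndarray,
    labels: np.ndarray,
    batch: BatchStructure,
    masks: SplitMasks,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[DAMAModel, list[float]]:
    """Train the model full-batch for a fixed number of epochs.

    Returns the trained model and the per-epoch loss history.  Aborts on a
    non-finite loss.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    n_classes = int(labels[masks.train].max()) + 1
    n_classes = max(n_classes, int(labels.max()) + 1)
    model = DAMAModel(x.shape[1], n_classes, model_cfg, seed=seed)
    opt = Adam(model.params, lr=train_cfg.learning_rate,
               weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(seed + 1)
    history: list[float] = []
    for epoch in range(train_cfg.epochs):
        opt.zero_grad()
        scores, g_final, _ = model.forward(x, batch, train=True, rng=rng)
        loss = model_loss(scores, labels, masks.train, g_final,
                          model_cfg.kappa, model_cfg.l1_mode)
        lval = float(loss.data)
        if not np.isfinite(lval):
            raise FloatingPointError(
                f"non-finite loss {lval!r} at epoch {epoch}; aborting")
        loss.backward()
        opt.step()
        history.append(lval)
        logger.debug("epoch %d loss %.6f", epoch, lval)
    return model, history


def predict(model: DAMAModel, x: np.ndarray, batch: BatchStructure) -> np.ndarray:
    scores, _, _ = model.forward(x, batch, train=False)
    return np.argmax(scores.data, axis=1)


def evaluate(
    model: DAMAModel,
    g: Graph,
    x: np.ndarray,
    batch: BatchStructure,
    masks: SplitMasks,
    metrics_on_all_nodes: bool = False,
) -> MetricsReport:
    """Score predictions: classification metrics on the test mask,
    modularity on the whole-graph predicted partition."""
    pred = predict(model, x, batch)
    y = g.labels
    if y is None:
        raise ValueError("graph has no labels to evaluate against")
    sel = np.ones(g.n_nodes, dtype=bool) if metrics_on_all_nodes else masks.test
    return MetricsReport(
        accuracy=float(accuracy_score(y[sel], pred[sel])),
        nmi=float(normalized_mutual_info_score(y[sel], pred[sel],
                                               average_method="arithmetic")),
        f1_macro=float(f1_score(y[sel], pred[sel], average="macro",
                                zero_division=0)),
        ari=float(adjusted_rand_score(y[sel], pred[sel])),
        modularity=float(modularity(g, pred)),
    )


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for key in ("accuracy", "nmi", "f1_macro", "ari", "modularity"):
        vals = np.array([getattr(r, key) for r in reports])
        out[key] = {"mean": float(vals.mean()), "std": float(vals.std())}
    return out


def run_experiment(
    g: Graph,
    x: np.ndarray,
    batch: BatchStructure,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    repeats: int | None = None,
) -> tuple[dict[str, dict[str, float]], list[MetricsReport]]:
    """Repeat the train/evaluate cycle with per-repeat reseeded splits and
    initialisations; returns (aggregate mean/std, per-repeat reports)."""
    train_cfg = train_cfg or TrainConfig()
    n_rep = repeats if repeats is not None else train_cfg.repeats
    reports: list[MetricsReport] = []
    for i in range(n_rep):
        seed_i = train_cfg.base_seed + i
        masks = make_split(g.n_nodes, train_cfg.train_ratio, seed=seed_i)
        model, _ = train(x, g.labels, batch, masks, model_cfg, train_cfg,
                         seed=seed_i)
        reports.append(evaluate(model, g, x, batch, masks))
    return aggregate_reports(reports), reports
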