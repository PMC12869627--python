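"""Training: AdamW, BCE objective, stratified five-fold cross-validation.

Each slide is one optimization step (batch size 1, the usual choice in MIL).
Per fold the model trains for up to ``max_epochs`` epochs and early-stops when
the validation AUC has not improved for ``patience`` epochs, restoring the
best-AUC checkpoint.  The fold whose validation AUC is highest supplies the
single model used for zero-shot external evaluation.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._autodiff import Tensor
from .evaluation import MetricsReport, classification_metrics
from .model import (
    POSITIVE_CLASS,
    PanSubNetConfig,
    PredictionResult,
    bce_loss,
    forward_bag,
    forward_baseline,
    forward_slide,
    init_baseline_params,
    init_params,
)
from .tissue import SlideBag

logger = logging.getLogger(__name__)


class AdamW:
    """AdamW with decoupled weight decay over a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m, v = self.m[k], self.v[k]
            # in-place moment updates; scratch buffer reused for the step
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            np.multiply(g, g, out=g)
            v += (1 - self.b2) * g
            denom = np.sqrt(v / bc2, out=g)
            denom += self.eps
            p.data -= self.lr * ((m / bc1) / denom + self.wd * p.data)
            p.grad = None

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def clip_gradients(params: dict[str, Tensor], max_norm: float) -> float:
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            flat = p.grad.ravel()
            total += float(np.dot(flat, flat))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return norm


@dataclass
class EpochLog:
    fold: int
    epoch: int
    train_loss: float
    val_auc: float


@dataclass
class FoldResult:
    fold: int
    params: dict[str, Tensor]
    metrics: MetricsReport
    val_auc: float
    n_epochs: int
    train_idx: np.ndarray
    val_idx: np.ndarray


@dataclass
class CVResult:
    folds: list[FoldResult]
    best_fold: int
    epoch_log: list[EpochLog] = field(default_factory=list)

    @property
    def best_params(self) -> dict[str, Tensor]:
        return self.folds[self.best_fold].params

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = np.array([getattr(f.metrics, metric) for f in self.folds])
        return float(vals.mean()), float(vals.std())

    @property
    def fold_assignments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(f.train_idx, f.val_idx) for f in self.folds]


def _labels_to_y(bags: list[SlideBag]) -> np.ndarray:
    for b in bags:
        if b.label is None:
            raise ValueError(f"slide {b.slide_id!r} has no label")
    return np.array([1 if b.label == POSITIVE_CLASS else 0 for b in bags])


def _val_auc(bags: list[SlideBag], params, config, baseline: bool) -> float:
    from sklearn.metrics import roc_auc_score

    y = _labels_to_y(bags)
    if len(np.unique(y)) < 2:
        raise ValueError("validation split contains a single class; AUC undefined")
    p = [forward_slide(b, params, config, baseline=baseline).p for b in bags]
    return float(roc_auc_score(y, p))


def train_fold(
    train_bags: list[SlideBag],
    val_bags: list[SlideBag],
    config: PanSubNetConfig,
    seed: int,
    baseline: bool = False,
    fold: int = 0,
    epoch_log: list[EpochLog] | None = None,
) -> tuple[dict[str, Tensor], float, int]:
    """Train one fold; returns (best-AUC params, best val AUC, epochs run)."""
    y_train = _labels_to_y(train_bags)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    rng = np.random.default_rng(seed)
    init = init_baseline_params if baseline else init_params
    fwd = forward_baseline if baseline else forward_bag
    params = init(config, rng)
    opt = AdamW(params, config.lr, config.weight_decay)
    best_auc, best_state, best_epoch = -np.inf, None, 0
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_bags))
        losses = []
        for i in order:
            bag = train_bags[i]
            opt.zero_grad()
            logit, _ = fwd(bag, params, config)
            loss = bce_loss(logit, float(y_train[i]))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at fold {fold} epoch {epoch} slide {bag.slide_id!r}"
                )
            loss.backward()
            clip_gradients(params, config.grad_clip)
            opt.step()
            losses.append(float(loss.data))
        auc = _val_auc(val_bags, params, config, baseline)
        if epoch_log is not None:
            epoch_log.append(EpochLog(fold, epoch, float(np.mean(losses)), auc))
        if auc > best_auc:
            best_auc, best_epoch = auc, epoch
            best_state = {k: v.data.copy() for k, v in params.items()}
        if epoch - best_epoch >= config.patience:
            logger.info("fold %d: early stop at epoch %d (best %d)", fold, epoch, best_epoch)
            break
    assert best_state is not None
    for k, v in params.items():
        v.data = best_state[k]
        v.grad = None
    return params, best_auc, epoch


def train_cv(bags: list[SlideBag], config: PanSubNetConfig,
             baseline: bool = False) -> CVResult:
    """Stratified k-fold cross-validation of the network (or the baseline).

    Folds are a deterministic function of (labels, config.seed, n_folds), so
    the baseline trained with the same config sees identical splits.
    """
    y = _labels_to_y(bags)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if len(bags) < config.n_folds:
        raise ValueError("fewer slides than folds")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds: list[FoldResult] = []
    epoch_log: list[EpochLog] = []
    for k, (tr, va) in enumerate(skf.split(np.zeros(len(bags)), y)):
        train_bags = [bags[i] for i in tr]
        val_bags = [bags[i] for i in va]
        params, val_auc, n_epochs = train_fold(
            train_bags, val_bags, config, seed=config.seed + 1000 * (k + 1),
            baseline=baseline, fold=k, epoch_log=epoch_log,
        )
        preds = [forward_slide(b, params, config, baseline=baseline).p for b in val_bags]
        report, _ = classification_metrics([b.label for b in val_bags], preds)
        folds.append(FoldResult(k, params, report, val_auc, n_epochs, tr, va))
    best = int(np.argmax([f.val_auc for f in folds]))
    return CVResult(folds=folds, best_fold=best, epoch_log=epoch_log)


def baseline_attmil(bags: list[SlideBag], config: PanSubNetConfig) -> CVResult:
    """Patch-only gated-attention MIL under the identical CV protocol."""
    return train_cv(bags, config, baseline=True)


def predict_bags(bags: list[SlideBag], params: dict[str, Tensor],
                 config: PanSubNetConfig, baseline: bool = False) -> list[PredictionResult]:
    """Zero-shot inference, e.g. the fold-best model on an external cohort."""
    return [forward_slide(b, params, config, baseline=baseline) for b in bags]


def save_checkpoint(params: dict[str, Tensor], config: PanSubNetConfig,
                    path, baseline: bool = False) -> None:
    """Single-file archive of parameter arrays plus the config and seed."""
    import dataclasses
    import json

    meta = json.dumps({"config": dataclasses.asdict(config), "baseline": baseline})
    arrays = {k: v.data for k, v in params.items()}
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], PanSubNetConfig, bool]:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        params = {k: Tensor(archive[k], requires_grad=True)
                  for k in archive.files if k != "__meta__"}
    config = PanSubNetConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in meta["config"].items()})
    return params, config, bool(meta["baseline"])
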