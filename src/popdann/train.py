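"""Two-component minibatch training for GRL networks.

Each domain-adaptive training step processes one :class:`DomainBatch` with
two components: (1) ``batch_size`` labeled source examples through the
feature extractor and label predictor (cross-entropy for classification,
MSE for regression), and (2) ``batch_size`` unlabeled examples — a mixture
of source and target per the domain-mixture fraction — through the feature
extractor and domain classifier (cross-entropy through the GRL). The
backward passes of both components accumulate into the feature extractor
before a single Adam update, so its weights move along the combined
gradient (label gradient plus lambda-reversed domain gradient, equal
weights). The source examples of the domain component are the same pool as
the labeled component, shuffled independently.

An epoch is one pass over the labeled source training data; target data is
cycled with reshuffling as needed (relevant for 10:1 source:target runs).
Early stopping returns the parameter state at the epoch with the lowest
label-predictor validation loss — never the domain loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    DannNetwork,
    batch_input,
    label_inverse,
    label_transform,
    predict_values,
)
from .nn import Adam, mse_loss, softmax_cross_entropy

__all__ = [
    "TrainingConfig",
    "DomainBatch",
    "TrainingHistory",
    "make_minibatch",
    "minibatch_stream",
    "train_standard",
    "train_domain_adaptive",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    grl_lambda: float = 1.0
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 5
    seed: int = 0
    domain_mix_fraction: float = 0.5  # source share of the domain half-batch

    def __post_init__(self) -> None:
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not (0.0 <= self.domain_mix_fraction <= 1.0):
            raise ValueError("domain_mix_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DomainBatch:
    """Index view of one two-component minibatch.

    ``labeled_source``: indices into the labeled source pool.
    ``domain_source`` / ``domain_target``: indices into the source pool and
    target pool forming the domain-classification mixture (domain labels
    0 = source, 1 = target).
    """

    labeled_source: np.ndarray
    domain_source: np.ndarray
    domain_target: np.ndarray


class _CycledStream:
    """Reshuffled, endlessly cycled index stream over a pool of n examples."""

    def __init__(self, n: int, rng: np.random.Generator):
        if n <= 0:
            raise ValueError("stream over an empty pool")
        self.n = n
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def take(self, k: int) -> np.ndarray:
        if k == 0:
            return np.empty(0, dtype=int)
        out = []
        while k > 0:
            avail = self.n - self._pos
            grab = min(avail, k)
            out.append(self._order[self._pos : self._pos + grab])
            self._pos += grab
            k -= grab
            if self._pos == self.n:
                self._order = self.rng.permutation(self.n)
                self._pos = 0
        return np.concatenate(out)


def make_minibatch(
    source_labeled: _CycledStream,
    source_unlabeled: _CycledStream,
    target_unlabeled: _CycledStream | None,
    cfg: TrainingConfig,
) -> DomainBatch:
    """Draw one two-component minibatch from the three index streams."""
    if target_unlabeled is None:
        raise ValueError(
            "domain-adaptive training requires unlabeled target data"
        )
    b = cfg.batch_size
    n_src = int(round(b * cfg.domain_mix_fraction))
    return DomainBatch(
        labeled_source=source_labeled.take(b),
        domain_source=source_unlabeled.take(n_src),
        domain_target=target_unlabeled.take(b - n_src),
    )


def minibatch_stream(n_source: int, n_target: int, cfg: TrainingConfig, rng_labeled, rng_domain):
    """All DomainBatches of one epoch (one labeled pass over the source)."""
    labeled = _CycledStream(n_source, rng_labeled)
    unlabeled_src = _CycledStream(n_source, rng_domain)
    target = _CycledStream(n_target, rng_domain) if n_target else None
    steps = max(1, n_source // cfg.batch_size)
    for _ in range(steps):
        yield make_minibatch(labeled, unlabeled_src, target, cfg)


@dataclass
class TrainingHistory:
    label_train_loss: list = field(default_factory=list)
    label_val_loss: list = field(default_factory=list)
    domain_train_loss: list = field(default_factory=list)
    domain_val_loss: list = field(default_factory=list)
    best_epoch: int = -1
    n_epochs: int = 0


def _label_loss_grad(model: DannNetwork, x, y_scaled):
    out, caches = model.label_logits(x, train=True)
    if model.spec.task == "sweep_classification":
        loss, dout = softmax_cross_entropy(out, y_scaled.astype(int))
    else:
        loss, dout = mse_loss(out, y_scaled)
    return loss, dout.astype(out.dtype), caches


def _backprop_label(model, caches, dout):
    fc, lc = caches
    dfeat = model.label_predictor.backward(lc, dout)
    model.feature_extractor.backward(fc, dfeat)


def _domain_loss_grad(model: DannNetwork, x, d_labels):
    out, caches = model.domain_logits(x, train=True)
    loss, dout = softmax_cross_entropy(out, d_labels)
    return loss, dout.astype(out.dtype), caches


def _backprop_domain(model, caches, dout):
    fc, dc = caches
    dfeat = model.domain_classifier.backward(dc, dout)  # GRL reverses inside
    model.feature_extractor.backward(fc, dfeat)


def _eval_label_loss(model, X, y, batch_size=256):
    spec = model.spec
    y_scaled = label_transform(spec, y)
    N = len(y)
    total = 0.0
    for k in range(0, N, batch_size):
        sl = np.arange(k, min(k + batch_size, N))
        x = batch_input(spec, X, sl)
        out, _ = model.label_logits(x, train=False)
        if spec.task == "sweep_classification":
            loss, _ = softmax_cross_entropy(out, y_scaled[sl].astype(int))
        else:
            loss, _ = mse_loss(out, y_scaled[sl])
        total += loss * len(sl)
    return total / N


def _eval_domain_loss(model, X_src, X_tgt, batch_size=256):
    spec = model.spec
    def _n(X):
        return len(X["pos"]) if isinstance(X, dict) else len(X)

    total, count = 0.0, 0
    for X, d in ((X_src, 0), (X_tgt, 1)):
        N = _n(X)
        for k in range(0, N, batch_size):
            sl = np.arange(k, min(k + batch_size, N))
            x = batch_input(spec, X, sl)
            out, _ = model.domain_logits(x, train=False)
            loss, _ = softmax_cross_entropy(out, np.full(len(sl), d))
            total += loss * len(sl)
            count += len(sl)
    return total / count


def _fit(
    model: DannNetwork,
    bundle,
    cfg: TrainingConfig,
    domain_adaptive: bool,
) -> TrainingHistory:
    spec = model.spec
    Xs, ys = bundle.source_train
    Xv, yv = bundle.source_val
    ys_scaled = label_transform(spec, ys)
    n_source = len(ys)
    Xt = bundle.target_train

    def _n(X):
        return len(X["pos"]) if isinstance(X, dict) else len(X)

    n_target = _n(Xt) if domain_adaptive else 0
    if domain_adaptive and n_target == 0:
        raise ValueError("domain-adaptive training requires target data")
    model.grl.lam = cfg.grl_lambda

    opt = Adam(model.trainable_params(domain_adaptive=domain_adaptive), lr=cfg.learning_rate)
    ss = np.random.SeedSequence(cfg.seed)
    kids = ss.spawn(2)
    rng_labeled = np.random.default_rng(kids[0])
    rng_domain = np.random.default_rng(kids[1])

    hist = TrainingHistory()
    best_loss = np.inf
    best_state = model.get_state()
    since_best = 0
    for epoch in range(cfg.max_epochs):
        lab_losses, dom_losses = [], []
        if domain_adaptive:
            batches = minibatch_stream(n_source, n_target, cfg, rng_labeled, rng_domain)
        else:
            labeled = _CycledStream(n_source, rng_labeled)
            batches = (
                DomainBatch(labeled.take(cfg.batch_size), np.array([], int), np.array([], int))
                for _ in range(max(1, n_source // cfg.batch_size))
            )
        for batch in batches:
            opt.zero_grad()
            x = batch_input(spec, Xs, batch.labeled_source)
            loss, dout, caches = _label_loss_grad(model, x, ys_scaled[batch.labeled_source])
            _backprop_label(model, caches, dout)
            lab_losses.append(loss)
            if domain_adaptive:
                xs_d = batch_input(spec, Xs, batch.domain_source)
                xt_d = batch_input(spec, Xt, batch.domain_target)
                xd = np.concatenate([xs_d, xt_d], axis=0)
                d_labels = np.concatenate(
                    [np.zeros(len(xs_d), int), np.ones(len(xt_d), int)]
                )
                dloss, ddout, dcaches = _domain_loss_grad(model, xd, d_labels)
                _backprop_domain(model, dcaches, ddout)
                dom_losses.append(dloss)
            opt.step()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: label loss {loss}"
                )
        hist.label_train_loss.append(float(np.mean(lab_losses)))
        val_loss = _eval_label_loss(model, Xv, yv)
        hist.label_val_loss.append(val_loss)
        if domain_adaptive:
            hist.domain_train_loss.append(float(np.mean(dom_losses)))
            hist.domain_val_loss.append(
                _eval_domain_loss(model, Xv, bundle.target_val)
            )
        hist.n_epochs = epoch + 1
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.set_state(best_state)
    return hist


def train_standard(model: DannNetwork, bundle, cfg: TrainingConfig) -> TrainingHistory:
    """Train feature extractor + label predictor on labeled source data only."""
    return _fit(model, bundle, cfg, domain_adaptive=False)


def train_domain_adaptive(model: DannNetwork, bundle, cfg: TrainingConfig) -> TrainingHistory:
    """Train with the two-component minibatch and combined GRL update."""
    return _fit(model, bundle, cfg, domain_adaptive=True)
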