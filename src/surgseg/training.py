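"""Multi-task optimization and experiment orchestration.

The loss is the weighted sum ``L = alpha * L_gesture + beta * L_skill`` of
two categorical cross-entropies: the per-frame gesture loss (averaged over
annotated frames) and the per-video skill loss (counted once per sequence).
Optimization is Adam over one full-length sequence per step, with seeded
epoch-level shuffling; there is no learning-rate schedule or early
stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ABLATION_PRESETS, LossConfig, ModelConfig, TrainConfig, ablation_config
from .data_io import FoldSpec
from .metrics import EvalReport, aggregate_reports, evaluate
from .network import DilatedAttentionNet

__all__ = [
    "gesture_loss",
    "skill_loss",
    "multitask_loss",
    "Adam",
    "TrainedModel",
    "train",
    "evaluate_fold",
    "cross_validate",
    "run_ablation",
]

_EPS = 1e-12


def gesture_loss(probs: np.ndarray, labels) -> float:
    """Mean per-frame categorical cross-entropy; frames labelled -1 are skipped."""
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs and labels must have the same length")
    mask = labels >= 0
    if not mask.any():
        raise ValueError("no annotated frames")
    if np.any(labels[mask] >= probs.shape[1]):
        raise ValueError("gesture label out of range")
    p = probs[mask, labels[mask]]
    return float(-np.log(np.maximum(p, _EPS)).mean())


def skill_loss(probs: np.ndarray, label: int) -> float:
    """Negative log-probability of the true skill class."""
    probs = np.asarray(probs)
    if not 0 <= int(label) < probs.shape[0]:
        raise ValueError("skill label out of range")
    return float(-np.log(max(probs[label], _EPS)))


def multitask_loss(l_gesture: float, l_skill: float,
                   cfg: LossConfig | None = None) -> float:
    cfg = cfg if cfg is not None else LossConfig()
    if not (np.isfinite(l_gesture) and np.isfinite(l_skill)):
        raise ValueError("component losses must be finite")
    return cfg.alpha * l_gesture + cfg.beta * l_skill


class Adam:
    """Adam with bias-corrected first and second moments."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


@dataclass
class TrainedModel:
    """A fitted network plus the configs and per-epoch loss history."""

    network: DilatedAttentionNet
    model_config: ModelConfig
    train_config: TrainConfig
    loss_config: LossConfig
    history: pd.DataFrame  # columns: epoch, gesture, skill, total

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        return self.network.predict_labels(x)

    def predict_skill(self, x: np.ndarray) -> int:
        _, sp = self.network.forward(x)
        return int(sp.argmax())


def train(dataset, model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None,
          loss_config: LossConfig | None = None,
          callback=None) -> TrainedModel:
    """Fit the network on a list of ``(features, labels, skill)`` triples.

    ``skill`` entries may be None when the trial has no skill annotation.
    Raises with the offending epoch and sequence index if the loss ever
    becomes non-finite.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    mc = model_config if model_config is not None else ModelConfig()
    tc = train_config if train_config is not None else TrainConfig()
    lc = loss_config if loss_config is not None else LossConfig()
    dims = {np.asarray(x).shape[1] for x, _, _ in dataset}
    if dims != {mc.in_dim}:
        raise ValueError(f"feature dims {sorted(dims)} inconsistent with config in_dim={mc.in_dim}")

    net = DilatedAttentionNet(mc, seed=tc.seed)
    opt = Adam(net.params, lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    rows = []
    order = np.arange(len(dataset))
    for epoch in range(tc.epochs):
        if tc.shuffle:
            rng.shuffle(order)
        tot_g = tot_s = tot = 0.0
        for i in order:
            x, labels, skill = dataset[i]
            try:
                losses, grads = net.forward_backward(x, labels, skill, lc)
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"epoch {epoch}, sequence {i}: {exc}") from exc
            if tc.grad_clip is not None:
                norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if norm > tc.grad_clip:
                    scale = tc.grad_clip / norm
                    grads = {k: g * scale for k, g in grads.items()}
            opt.step(net.params, grads)
            tot_g += losses["gesture"]
            tot_s += losses["skill"]
            tot += losses["total"]
        n = len(dataset)
        rows.append({"epoch": epoch, "gesture": tot_g / n,
                     "skill": tot_s / n, "total": tot / n})
        if callback is not None:
            callback(rows[-1])
    history = pd.DataFrame(rows)
    return TrainedModel(network=net, model_config=mc, train_config=tc,
                        loss_config=lc, history=history)


def evaluate_fold(model: TrainedModel, test_set) -> EvalReport:
    """Evaluate a fitted model on held-out trials.

    Metrics are computed per trial and averaged; the skill accuracy is the
    fraction of test trials whose skill class is predicted correctly.
    """
    reports, hits, n_skill = [], 0, 0
    for x, labels, skill in test_set:
        pred = model.predict_labels(x)
        reports.append(evaluate(pred, labels, model.model_config.n_gestures))
        if skill is not None and model.model_config.use_skill_head:
            n_skill += 1
            hits += int(model.predict_skill(x) == skill)
    agg = aggregate_reports(reports)
    if n_skill:
        agg.skill_accuracy = 100.0 * hits / n_skill
    return agg


def cross_validate(trials_by_id: dict[str, tuple], folds: list[FoldSpec],
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   loss_config: LossConfig | None = None,
                   callback=None) -> tuple[EvalReport, list[EvalReport]]:
    """Train and evaluate once per fold; returns (mean report, per-fold reports).

    ``trials_by_id`` maps trial id to a ``(features, labels, skill)`` triple.
    """
    per_fold = []
    for fold in folds:
        train_set = [trials_by_id[t] for t in fold.train]
        test_set = [trials_by_id[t] for t in fold.test]
        model = train(train_set, model_config, train_config, loss_config)
        report = evaluate_fold(model, test_set)
        per_fold.append(report)
        if callback is not None:
            callback(fold, report)
    return aggregate_reports(per_fold), per_fold


def run_ablation(trials_by_id: dict[str, tuple], folds: list[FoldSpec],
                 base_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 loss_config: LossConfig | None = None,
                 presets=None, callback=None) -> pd.DataFrame:
    """Run the ablation grid; one row of fold-averaged metrics per preset.

    The presets range from the attention-only and dilation-only baselines
    through one-sided encoder/decoder variants to the full pooled
    multi-task network.
    """
    presets = list(presets) if presets is not None else list(ABLATION_PRESETS)
    rows = []
    for preset in presets:
        mc = ablation_config(preset, base_config)
        mean, _ = cross_validate(trials_by_id, folds, mc, train_config,
                                 loss_config, callback=None)
        row = {"config": preset, **mean.to_dict()}
        rows.append(row)
        if callback is not None:
            callback(preset, mean)
    return pd.DataFrame(rows).set_index("config")
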