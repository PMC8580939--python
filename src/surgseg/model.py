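"""Model/Results interface over the training machinery.

`GestureSkillModel` holds a cohort of trials plus the architecture and loss
configuration; `fit()` optimizes the network and returns a
`GestureSkillResults` carrying the fitted parameters, the loss history,
prediction and evaluation methods and a text `summary()`.  This mirrors the
model-object convention of the statistical-modelling stack: build from
data, fit, interrogate the results object.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LossConfig, ModelConfig, TrainConfig
from .data_io import GestureVocabulary, load_trial, read_manifest
from .metrics import EvalReport
from .network import DilatedAttentionNet
from .training import TrainedModel, evaluate_fold, train

__all__ = ["GestureSkillModel", "GestureSkillResults"]


class GestureSkillModel:
    """Joint per-frame gesture segmentation and per-video skill classification.

    Parameters
    ----------
    trials:
        List of ``(features, labels, skill)`` triples — features a T x f
        matrix, labels a length-T integer vector (-1 for unannotated
        frames), skill an integer class or None.
    model_config, loss_config:
        Architecture and loss-weight settings; defaults reproduce the full
        multi-task network.

    Examples
    --------
    >>> from surgseg import GestureSkillModel, SimConfig
    >>> from surgseg.synthetic import generate_trials
    >>> cohort = generate_trials(SimConfig(seed=1))
    >>> data = [(t["features"], t["labels"], t["skill"]) for t in cohort]
    >>> res = GestureSkillModel(data).fit()          # doctest: +SKIP
    >>> print(res.summary())                         # doctest: +SKIP
    """

    def __init__(self, trials, model_config: ModelConfig | None = None,
                 loss_config: LossConfig | None = None):
        self.trials = list(trials)
        if not self.trials:
            raise ValueError("model needs at least one trial")
        self.model_config = model_config if model_config is not None else ModelConfig()
        self.loss_config = loss_config if loss_config is not None else LossConfig()

    @classmethod
    def from_manifest(cls, manifest_path, model_config: ModelConfig | None = None,
                      loss_config: LossConfig | None = None,
                      vocab: GestureVocabulary | None = None,
                      trial_ids=None) -> "GestureSkillModel":
        """Build the model from an on-disk dataset manifest."""
        records = read_manifest(manifest_path)
        if trial_ids is not None:
            wanted = set(trial_ids)
            records = [r for r in records if r.trial_id in wanted]
        mc = model_config if model_config is not None else ModelConfig()
        trials = [load_trial(r, vocab, expected_dim=mc.in_dim) for r in records]
        return cls(trials, mc, loss_config)

    def fit(self, train_config: TrainConfig | None = None,
            callback=None) -> "GestureSkillResults":
        """Optimize the network and return the results object."""
        fitted = train(self.trials, self.model_config, train_config,
                       self.loss_config, callback=callback)
        return GestureSkillResults(self, fitted)


class GestureSkillResults:
    """Fitted parameters, training history and evaluation methods."""

    def __init__(self, model: GestureSkillModel, fitted: TrainedModel):
        self.model = model
        self._fitted = fitted
        self.network: DilatedAttentionNet = fitted.network
        self.params: dict[str, np.ndarray] = fitted.network.params
        self.history: pd.DataFrame = fitted.history

    # -- prediction -------------------------------------------------------

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Per-frame gesture class probabilities (T x n_gestures)."""
        probs, _ = self.network.forward(features)
        return probs

    def predict_labels(self, features: np.ndarray) -> np.ndarray:
        """Frame-wise argmax gesture labels."""
        return self.network.predict_labels(features)

    def predict_skill(self, features: np.ndarray) -> np.ndarray:
        """Video-level skill class probabilities (n_skills,)."""
        _, sp = self.network.forward(features)
        return sp

    def evaluate(self, trials) -> EvalReport:
        """Frame accuracy, edit score, F1@k, confusion and skill accuracy
        on a held-out list of ``(features, labels, skill)`` triples."""
        return evaluate_fold(self._fitted, trials)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        mc = self.model.model_config
        lc = self.model.loss_config
        tc = self._fitted.train_config
        first, last = self.history.iloc[0], self.history.iloc[-1]
        stages = [name for name, flag in [
            ("encoder", mc.use_encoder), ("pooling", mc.use_pooling),
            ("attention", mc.use_attention), ("decoder", mc.use_decoder),
            ("skill head", mc.use_skill_head)] if flag]
        n_params = sum(v.size for v in self.params.values())
        lines = [
            "Joint gesture segmentation / skill assessment",
            "=" * 54,
            f"stages:           {', '.join(stages)}",
            f"layers per stack: {mc.n_layers} (dilations {mc.dilations[0]}..{mc.dilations[-1]})",
            f"channels:         {mc.channels} (input dim {mc.in_dim}, kernel {mc.kernel})",
            f"pool factor:      {mc.pool}   attention d_k/d_v: {mc.d_k}/{mc.d_v}",
            f"classes:          {mc.n_gestures} gestures, {mc.n_skills} skill levels",
            f"parameters:       {n_params:,}",
            f"loss weights:     alpha={lc.alpha} (gesture), beta={lc.beta} (skill)",
            f"optimizer:        Adam, lr={tc.learning_rate}, {tc.epochs} epochs, seed={tc.seed}",
            f"training trials:  {len(self.model.trials)}",
            "-" * 54,
            f"loss (total):     {first['total']:.4f} (epoch 0) -> {last['total']:.4f} "
            f"(epoch {int(last['epoch'])})",
            f"loss (gesture):   {first['gesture']:.4f} -> {last['gesture']:.4f}",
            f"loss (skill):     {first['skill']:.4f} -> {last['skill']:.4f}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss curves per epoch (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for col in ("total", "gesture", "skill"):
            ax.plot(self.history["epoch"], self.history[col], label=col)
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean training loss")
        ax.legend()
        return ax

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Write parameters (.npz) and configs (.json sidecar)."""
        path = Path(path)
        np.savez(path, **self.params)
        meta = {
            "model_config": _config_dict(self.model.model_config),
            "loss_config": dataclasses.asdict(self.model.loss_config),
            "train_config": dataclasses.asdict(self._fitted.train_config),
            "history": self.history.to_dict(orient="list"),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load(path) -> "GestureSkillResults":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        mc_kwargs = meta["model_config"]
        mc_kwargs["dilations"] = tuple(mc_kwargs["dilations"])
        mc = ModelConfig(**mc_kwargs)
        lc = LossConfig(**meta["loss_config"])
        tc = TrainConfig(**meta["train_config"])
        with np.load(path) as npz:
            params = {k: npz[k] for k in npz.files}
        net = DilatedAttentionNet(mc, params=params)
        history = pd.DataFrame(meta["history"])
        fitted = TrainedModel(network=net, model_config=mc, train_config=tc,
                              loss_config=lc, history=history)
        dummy = GestureSkillModel.__new__(GestureSkillModel)
        dummy.trials = []
        dummy.model_config = mc
        dummy.loss_config = lc
        return GestureSkillResults(dummy, fitted)


def _config_dict(mc: ModelConfig) -> dict:
    d = dataclasses.asdict(mc)
    d["dilations"] = list(mc.dilations)
    return d
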