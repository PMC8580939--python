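"""The joint gesture-segmentation / skill-assessment network.

The full architecture is symmetric: a 1x1 input projection, an encoder of
``L`` dilated residual layers (dilation ``2**l`` at layer ``l``), a temporal
max-pool, a single-head scaled dot-product self-attention block with
sinusoidal positional encoding at the bottleneck, nearest-neighbour
unpooling, a decoder of ``L`` dilated residual layers with the encoder's
dilation schedule, and two task heads: a per-frame softmax over gesture
classes and a per-video softmax over skill levels (temporal mean of the
frame-wise skill logits).

Each stage can be switched off through the ``use_*`` flags of
:class:`~surgseg.config.ModelConfig`, which is how the ablation variants
(attention only, dilation only, one-sided stacks, no pooling, no skill
branch) are expressed; the forward pass composes exactly the enabled
stages, and the temporal length contract (gesture output has one row per
input frame) holds for every variant.
"""

from __future__ import annotations

import numpy as np

from .config import LossConfig, ModelConfig
from . import layers as L

__all__ = [
    "DilatedAttentionNet",
    "init_params",
    "gesture_head",
    "skill_head",
    "encoder_forward",
    "decoder_forward",
    "measure_receptive_field",
]


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Fan-in-scaled Gaussian initialization of every parameter array."""
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}

    def dense(name: str, fin: int, fout: int) -> None:
        p[f"{name}.W"] = rng.standard_normal((fin, fout)) / np.sqrt(fin)
        p[f"{name}.b"] = np.zeros(fout)

    f, k = config.channels, config.kernel
    dense("in", config.in_dim, f)
    for stack in ("enc", "dec"):
        for l in range(config.n_layers):
            p[f"{stack}{l}.W1"] = rng.standard_normal((k, f, f)) / np.sqrt(k * f)
            p[f"{stack}{l}.b1"] = np.zeros(f)
            p[f"{stack}{l}.W2"] = rng.standard_normal((f, f)) / np.sqrt(f)
            p[f"{stack}{l}.b2"] = np.zeros(f)
    for name, dim in (("q", config.d_k), ("k", config.d_k), ("v", config.d_v)):
        p[f"att.W{name}"] = rng.standard_normal((f, dim)) / np.sqrt(f)
        p[f"att.b{name}"] = np.zeros(dim)
    p["att.Wo"] = rng.standard_normal((config.d_v, f)) / np.sqrt(config.d_v)
    p["att.bo"] = np.zeros(f)
    p["att.Wf1"] = rng.standard_normal((f, config.ffn_hidden)) / np.sqrt(f)
    p["att.cf1"] = np.zeros(config.ffn_hidden)
    p["att.Wf2"] = rng.standard_normal((config.ffn_hidden, f)) / np.sqrt(config.ffn_hidden)
    p["att.cf2"] = np.zeros(f)
    for ln in ("ln1", "ln2"):
        p[f"att.{ln}_g"] = np.ones(f)
        p[f"att.{ln}_b"] = np.zeros(f)
    dense("gest", f, config.n_gestures)
    dense("skill", f, config.n_skills)
    return p


def _sub(params: dict, prefix: str) -> dict:
    """View of a flat parameter dict restricted to one layer's keys."""
    n = len(prefix) + 1
    return {key[n:]: val for key, val in params.items() if key.startswith(prefix + ".")}


def gesture_head(D: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-frame class probabilities: softmax over gesture logits, row-wise."""
    return L.softmax(D @ W + b, axis=1)


def skill_head(D: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Video-level skill probabilities.

    The per-frame skill logits are averaged over time before the softmax;
    since the head is affine this equals applying the head to the temporal
    mean feature, and is invariant to permuting the frames.
    """
    return L.softmax(D.mean(axis=0) @ W + b, axis=-1)


def encoder_forward(x: np.ndarray, config: ModelConfig, params: dict) -> np.ndarray:
    """Input projection, encoder stack and max-pool; returns the bottleneck."""
    h, _ = linear(x, params, "in")
    if config.use_encoder:
        h = _run_stack(h, config, params, "enc")
    if config.use_pooling:
        h, _ = L.max_pool_forward(h, config.pool)
    return h


def decoder_forward(h: np.ndarray, T: int, config: ModelConfig, params: dict) -> np.ndarray:
    """Unpool back to T frames and run the decoder stack."""
    if config.use_pooling:
        h, _ = L.unpool_forward(h, config.pool, T)
    if config.use_decoder:
        h = _run_stack(h, config, params, "dec")
    return h


def linear(x: np.ndarray, params: dict, name: str):
    return L.linear_forward(x, params[f"{name}.W"], params[f"{name}.b"])


def _run_stack(h: np.ndarray, config: ModelConfig, params: dict, stack: str) -> np.ndarray:
    for l, s in enumerate(config.dilations):
        h, _ = L.dilated_residual_forward(h, _sub(params, f"{stack}{l}"), s)
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"non-finite activations in {stack} layer {l}")
    return h


class DilatedAttentionNet:
    """Symmetric dilated encoder-decoder with a self-attention bottleneck.

    Parameters are a flat ``dict[str, ndarray]`` initialized with a seeded
    generator, so two networks built with the same config and seed are
    bit-identical.  :meth:`forward` returns calibrated probabilities;
    :meth:`forward_backward` additionally returns the multi-task loss and
    its analytic gradient with respect to every parameter.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 params: dict[str, np.ndarray] | None = None):
        self.config = config if config is not None else ModelConfig()
        self.params = params if params is not None else init_params(self.config, seed)

    # -- forward ----------------------------------------------------------

    def _forward(self, x: np.ndarray):
        """Run the enabled stages; returns logits and the backward tape."""
        cfg = self.config
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError("input must be a T x f matrix with T >= 1")
        if x.shape[1] != cfg.in_dim:
            raise ValueError(f"input has {x.shape[1]} channels, config expects {cfg.in_dim}")
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        T = x.shape[0]
        tape: list[tuple] = []

        h, cache = linear(x, self.params, "in")
        tape.append(("linear", "in", cache))
        if cfg.use_encoder:
            for l, s in enumerate(cfg.dilations):
                h, cache = L.dilated_residual_forward(h, _sub(self.params, f"enc{l}"), s)
                if not np.all(np.isfinite(h)):
                    raise FloatingPointError(f"non-finite activations in enc layer {l}")
                tape.append(("res", f"enc{l}", cache))
        if cfg.use_pooling:
            h, cache = L.max_pool_forward(h, cfg.pool)
            tape.append(("pool", None, cache))
        if cfg.use_attention:
            h = h + L.positional_encoding(h.shape[0], cfg.channels)
            h, cache = L.attention_block_forward(h, _sub(self.params, "att"))
            tape.append(("att", "att", cache))
        if cfg.use_pooling:
            h, cache = L.unpool_forward(h, cfg.pool, T)
            tape.append(("unpool", None, cache))
        if cfg.use_decoder:
            for l, s in enumerate(cfg.dilations):
                h, cache = L.dilated_residual_forward(h, _sub(self.params, f"dec{l}"), s)
                if not np.all(np.isfinite(h)):
                    raise FloatingPointError(f"non-finite activations in dec layer {l}")
                tape.append(("res", f"dec{l}", cache))

        gest_logits = h @ self.params["gest.W"] + self.params["gest.b"]
        pooled = h.mean(axis=0)
        skill_logits = pooled @ self.params["skill.W"] + self.params["skill.b"]
        return h, gest_logits, skill_logits, pooled, tape

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(gesture probabilities (T x G), skill probabilities (S,))``."""
        _, gest_logits, skill_logits, _, _ = self._forward(x)
        return L.softmax(gest_logits, axis=1), L.softmax(skill_logits, axis=-1)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        """Frame-wise argmax decoding (ties broken toward the lowest class)."""
        probs, _ = self.forward(x)
        return probs.argmax(axis=1)

    # -- backward ---------------------------------------------------------

    def forward_backward(self, x: np.ndarray, labels: np.ndarray,
                         skill_label: int | None,
                         loss_config: LossConfig | None = None):
        """Multi-task loss and its gradients for one sequence.

        ``labels`` is a length-T integer vector; frames labelled ``-1`` are
        unannotated and excluded from the gesture loss.  ``skill_label`` may
        be None (or the skill head disabled), in which case the skill loss
        is zero and no gradient reaches the skill parameters.

        Losses are computed from logits through log-sum-exp, which is
        algebraically the categorical cross-entropy of the softmax outputs
        but immune to underflow.
        """
        cfg = self.config
        lc = loss_config if loss_config is not None else LossConfig()
        labels = np.asarray(labels)
        D, gest_logits, skill_logits, pooled, tape = self._forward(x)
        T = gest_logits.shape[0]
        if labels.shape[0] != T:
            raise ValueError("label sequence length does not match input length")

        mask = labels >= 0
        n_lab = int(mask.sum())
        if np.any(labels[mask] >= cfg.n_gestures):
            raise ValueError("gesture label out of range")
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        # gesture loss: mean over labelled frames of (logsumexp - true logit)
        if n_lab:
            zl = gest_logits[mask]
            m = zl.max(axis=1)
            lse = m + np.log(np.exp(zl - m[:, None]).sum(axis=1))
            loss_g = float((lse - zl[np.arange(n_lab), labels[mask]]).mean())
            d_zl = L.softmax(zl, axis=1)
            d_zl[np.arange(n_lab), labels[mask]] -= 1.0
            d_gest = np.zeros_like(gest_logits)
            d_gest[mask] = d_zl / n_lab
        else:
            loss_g = 0.0
            d_gest = np.zeros_like(gest_logits)

        use_skill = cfg.use_skill_head and skill_label is not None and lc.beta > 0
        if skill_label is not None and not (0 <= int(skill_label) < cfg.n_skills):
            raise ValueError("skill label out of range")
        if use_skill:
            m = skill_logits.max()
            loss_s = float(m + np.log(np.exp(skill_logits - m).sum()) - skill_logits[skill_label])
            d_skill = L.softmax(skill_logits, axis=-1)
            d_skill[skill_label] -= 1.0
        else:
            loss_s = 0.0
            d_skill = None

        total = lc.alpha * loss_g + lc.beta * loss_s
        if not np.isfinite(total):
            raise FloatingPointError("non-finite loss")

        # head gradients
        dD = (lc.alpha * d_gest) @ self.params["gest.W"].T
        grads["gest.W"] = D.T @ (lc.alpha * d_gest)
        grads["gest.b"] = (lc.alpha * d_gest).sum(axis=0)
        if use_skill:
            ds = lc.beta * d_skill
            grads["skill.W"] = np.outer(pooled, ds)
            grads["skill.b"] = ds
            dD += np.broadcast_to(ds @ self.params["skill.W"].T / T, D.shape)

        # walk the tape backwards
        dh = dD
        for kind, name, cache in reversed(tape):
            if kind == "linear":
                dh, g = L.linear_backward(dh, cache)
                for key, val in g.items():
                    grads[f"{name}.{key}"] = val
            elif kind == "res":
                dh, g = L.dilated_residual_backward(dh, cache)
                for key, val in g.items():
                    grads[f"{name}.{key}"] = val
            elif kind == "pool":
                dh = L.max_pool_backward(dh, cache)
            elif kind == "unpool":
                dh = L.unpool_backward(dh, cache)
            elif kind == "att":
                dh, g = L.attention_block_backward(dh, cache)
                for key, val in g.items():
                    grads[f"{name}.{key}"] = val

        losses = {"total": total, "gesture": loss_g, "skill": loss_s}
        return losses, grads


def measure_receptive_field(n_layers: int, kernel: int = 3, channels: int = 16,
                            seed: int = 0, n_probes: int = 2) -> int:
    """Empirical receptive field of an encoder stack, in frames.

    Builds a random-weight stack of ``n_layers`` dilated residual layers
    (dilations ``2**l``, no pooling or attention), perturbs the middle
    input frame by a large +/- delta, and counts the output frames that
    change.  The union over probe signs and several input draws makes the
    count robust to ReLU units that happen to block one particular path.

    For kernel 3 the theoretical value is ``2**(n_layers + 1) - 1``.
    """
    cfg = ModelConfig(n_layers=n_layers, in_dim=channels, channels=channels,
                      kernel=kernel, use_encoder=True, use_decoder=False,
                      use_attention=False, use_pooling=False)
    params = init_params(cfg, seed=seed)
    radius = (kernel - 1) // 2 * sum(cfg.dilations)
    T = 2 * radius + 5
    mid = T // 2
    rng = np.random.default_rng(seed)

    changed = np.zeros(T, dtype=bool)
    for _ in range(n_probes):
        x = rng.standard_normal((T, channels))
        base = _run_stack(x @ params["in.W"] + params["in.b"], cfg, params, "enc")
        for delta in (100.0, -100.0):
            xp = x.copy()
            xp[mid] += delta
            out = _run_stack(xp @ params["in.W"] + params["in.b"], cfg, params, "enc")
            changed |= np.any(out != base, axis=1)
    return int(changed.sum())
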