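"""The interpretable sequence-to-function architecture.

Five composable blocks, each reading directly as a biological quantity:

1. input transform  — one-hot DNA plus a learned positional profile and,
   optionally, a residual self-attention term capturing nucleotide context;
2. motif scan       — valid cross-correlation with fixed log-odds PWM
   kernels (both strands), then a per-motif sigmoid calibration
   sigma(a_i * score + b_i) mapping raw match scores to [0, 1];
3. trainable pooling— per-motif softmax-weighted aggregation over positions
   whose temperature alpha_i interpolates from average (alpha -> 0) to max
   (alpha -> inf) pooling;
4. interaction gate — each motif's pooled occupancy is multiplied by
   sigma(A @ pooled), letting motif j up- or down-weight motif i;
5. linear read-out  — y = B @ gated + gamma, so the final coefficients B
   are per-output motif effects with no post hoc attribution needed.

Every trainable quantity lives in :class:`ModelParams` under the name used
throughout the interpretation reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .motifs import KernelBank

__all__ = ["ModelConfig", "ModelParams", "LayerTrace", "SequenceModel", "mse_loss"]


@dataclass(frozen=True)
class ModelConfig:
    m: int
    L: int
    c: int
    use_attention: bool = False
    use_interaction: bool = False
    attention_heads: int = 1
    attention_dim: int = 8
    strands: str = "both"  # both | forward
    kernels_frozen: bool = True

    def __post_init__(self):
        if min(self.m, self.L, self.c) < 1:
            raise ValueError("m, L and c must be positive")
        if self.strands not in ("both", "forward"):
            raise ValueError(f"unknown strands setting {self.strands!r}")
        if self.use_attention:
            if self.attention_heads < 1 or self.attention_dim < 1:
                raise ValueError("attention dimensions must be positive")
            if self.attention_dim % self.attention_heads:
                raise ValueError("attention_dim must be divisible by attention_heads")


@dataclass
class LayerTrace:
    """Intermediate tensors of one sequence's forward pass (numpy arrays)."""

    post_transform: np.ndarray  # (4, L)
    match_probs: np.ndarray  # (m, L')
    pool_weights: np.ndarray  # (m, L'), rows sum to 1
    pooled: np.ndarray  # (m,)
    gated: np.ndarray  # (m,)
    prediction: np.ndarray  # (c,)


class ModelParams:
    """Named trainable tensors; the names are the interpretation surface."""

    GROUPS = (
        "embedding",
        "attn_q",
        "attn_k",
        "attn_v",
        "attn_out",
        "kernels",
        "scale",
        "offset",
        "pool",
        "interaction",
        "coef",
        "intercept",
    )

    def __init__(self, tensors: dict[str, Tensor]):
        self.tensors = tensors

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def items(self):
        return self.tensors.items()

    def trainable(self) -> dict[str, Tensor]:
        return {k: t for k, t in self.tensors.items() if t.requires_grad}

    def copy_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.tensors.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, arr in arrays.items():
            self.tensors[k].data[...] = arr

    @classmethod
    def initialize(
        cls, config: ModelConfig, bank: KernelBank, seed: int = 0
    ) -> "ModelParams":
        """Start every nonlinearity in its identifiable, unsaturated regime.

        The calibration (a_i, b_i) is set per motif so that the expected
        background score maps to sigma(...) = 0.1 and the best attainable
        match score to 0.9: log-odds scores span tens of units, so a unit
        scale would saturate the sigmoid across the whole sequence and wipe
        out the match/background contrast. alpha = 0 starts at average
        pooling; the interaction matrix, read-out and attention output
        projection start at zero so the initial model is the residual
        identity plus a trainable linear head.
        """
        rng = np.random.default_rng(seed)
        if bank.m != config.m:
            raise ValueError("kernel bank size does not match config.m")
        mean_scores = bank.mean_scores()
        span = np.maximum(bank.max_scores() - mean_scores, 1e-6)
        scale = 2.0 * np.log(9.0) / span  # logit(0.9) - logit(0.1) over span
        offset = -np.log(9.0) - scale * mean_scores  # sigma at s_mean = 0.1
        t: dict[str, Tensor] = {
            "embedding": ad.parameter(np.zeros(config.L)),
            "kernels": Tensor(
                bank.weights.copy(), requires_grad=not config.kernels_frozen
            ),
            "scale": ad.parameter(scale),
            "offset": ad.parameter(offset),
            "pool": ad.parameter(np.zeros(config.m)),
            "interaction": ad.parameter(np.zeros((config.m, config.m))),
            "coef": ad.parameter(np.zeros((config.c, config.m))),
            "intercept": ad.parameter(np.zeros(config.c)),
        }
        d = config.attention_dim
        t["attn_q"] = ad.parameter(rng.normal(scale=0.1, size=(d, 4)))
        t["attn_k"] = ad.parameter(rng.normal(scale=0.1, size=(d, 4)))
        t["attn_v"] = ad.parameter(rng.normal(scale=0.1, size=(d, 4)))
        t["attn_out"] = ad.parameter(np.zeros((4, d)))  # residual identity start
        if not config.use_attention:
            for k in ("attn_q", "attn_k", "attn_v", "attn_out"):
                t[k].requires_grad = False
        if not config.use_interaction:
            t["interaction"].requires_grad = False
        return cls(t)


class SequenceModel:
    """Bundles config + params + the valid kernel widths and runs blocks."""

    def __init__(self, config: ModelConfig, params: ModelParams, valid_width):
        self.config = config
        self.params = params
        self.valid_width = np.asarray(valid_width, dtype=int)

    @classmethod
    def build(cls, config: ModelConfig, bank: KernelBank, seed: int = 0):
        return cls(config, ModelParams.initialize(config, bank, seed), bank.valid_width)

    # ------------------------------------------------------------- blocks
    def transform_input(self, x: Tensor) -> Tensor:
        """x + positional profile; with attention, x + selfAttention(x + p).

        The attention output is added to the *raw* one-hot input (residual
        form), so a zeroed output projection reduces the block to identity.
        """
        p = self.params["embedding"].reshape(1, 1, self.config.L)
        if not self.config.use_attention:
            return x + p
        return x + self._self_attention(x + p)

    def _self_attention(self, x: Tensor) -> Tensor:
        cfg = self.config
        h = cfg.attention_heads
        dk = cfg.attention_dim // h
        n = x.shape[0]
        q = (self.params["attn_q"] @ x).reshape(n, h, dk, cfg.L)
        k = (self.params["attn_k"] @ x).reshape(n, h, dk, cfg.L)
        v = (self.params["attn_v"] @ x).reshape(n, h, dk, cfg.L)
        scores = q.transpose(0, 1, 3, 2) @ k * (1.0 / np.sqrt(dk))
        attn = ad.softmax(scores, axis=-1)  # (n, h, L, L), rows over keys
        mixed = v @ attn.transpose(0, 1, 3, 2)  # (n, h, dk, L)
        mixed = mixed.reshape(n, h * dk, cfg.L)
        return self.params["attn_out"] @ mixed

    def match_and_calibrate(self, xt: Tensor) -> Tensor:
        """Motif match probabilities: (n, L', m) in (0, 1)."""
        m, L = self.config.m, self.config.L
        kernels = self.params["kernels"]
        W = kernels.shape[2]
        if L < W:
            raise ValueError(f"input length {L} shorter than widest kernel {W}")
        patches = ad.sliding_windows(xt, W)  # (n, L', 4W)
        kf = kernels.reshape(m, 4 * W)
        scores = patches @ kf.transpose(1, 0)  # (n, L', m)
        if self.config.strands == "both":
            krc = kernels.flip((1, 2)).reshape(m, 4 * W)
            scores = ad.maximum(scores, patches @ krc.transpose(1, 0))
        a = self.params["scale"].reshape(1, 1, m)
        b = self.params["offset"].reshape(1, 1, m)
        return ad.sigmoid(scores * a + b)

    def trainable_pool(self, probs: Tensor) -> tuple[Tensor, Tensor]:
        """Softmax pooling over positions; returns (pooled (n, m), weights)."""
        alpha = self.params["pool"].reshape(1, 1, self.config.m)
        weights = ad.softmax(probs * alpha, axis=1)  # over positions
        pooled = (weights * probs).sum(axis=1)
        return pooled, weights

    def interaction_gate(self, pooled: Tensor) -> Tensor:
        if not self.config.use_interaction:
            return pooled
        gate = ad.sigmoid(pooled @ self.params["interaction"].transpose(1, 0))
        return gate * pooled

    def predict_head(self, gated: Tensor) -> Tensor:
        B = self.params["coef"]
        gamma = self.params["intercept"].reshape(1, self.config.c)
        return gated @ B.transpose(1, 0) + gamma

    # ------------------------------------------------------------ forward
    def forward(self, onehot: np.ndarray) -> Tensor:
        x = ad.constant(onehot)
        xt = self.transform_input(x)
        probs = self.match_and_calibrate(xt)
        pooled, _ = self.trainable_pool(probs)
        gated = self.interaction_gate(pooled)
        return self.predict_head(gated)

    def features(self, onehot: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Gated per-motif occupancy features feeding the linear read-out:
        the (n, m) input of the final layer."""
        outs = []
        for lo in range(0, onehot.shape[0], batch_size):
            x = ad.constant(onehot[lo : lo + batch_size])
            probs = self.match_and_calibrate(self.transform_input(x))
            pooled, _ = self.trainable_pool(probs)
            outs.append(self.interaction_gate(pooled).data)
        return np.concatenate(outs, axis=0)

    def predict(self, onehot: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Batched inference returning a plain (n, c) array."""
        outs = []
        for lo in range(0, onehot.shape[0], batch_size):
            outs.append(self.forward(onehot[lo : lo + batch_size]).data)
        return np.concatenate(outs, axis=0)

    def trace(self, onehot_single: np.ndarray) -> LayerTrace:
        """Forward pass of one (4, L) sequence exposing every intermediate."""
        x = ad.constant(onehot_single[None])
        xt = self.transform_input(x)
        probs = self.match_and_calibrate(xt)
        pooled, weights = self.trainable_pool(probs)
        gated = self.interaction_gate(pooled)
        pred = self.predict_head(gated)
        return LayerTrace(
            post_transform=xt.data[0],
            match_probs=probs.data[0].T,
            pool_weights=weights.data[0].T,
            pooled=pooled.data[0],
            gated=gated.data[0],
            prediction=pred.data[0],
        )

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            valid_width=self.valid_width,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "SequenceModel":
        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
            valid_width = z["valid_width"]
            tensors = {}
            for k in ModelParams.GROUPS:
                if k in z:
                    tensors[k] = Tensor(z[k].copy())
        params = ModelParams(tensors)
        # restore trainability flags
        fresh = ModelParams.initialize(
            cfg,
            KernelBank(
                tensors["kernels"].data.copy(), valid_width, np.full(4, 0.25)
            ),
        )
        for k, t in params.items():
            t.requires_grad = fresh[k].requires_grad
        return cls(cfg, params, valid_width)

    def set_kernels_frozen(self, frozen: bool) -> None:
        self.config = replace(self.config, kernels_frozen=frozen)
        self.params["kernels"].requires_grad = not frozen


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - ad.constant(target)
    return (diff * diff).sum() * (1.0 / target.size)
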