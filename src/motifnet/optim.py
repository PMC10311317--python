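"""ADAM with proximal sparsity steps, and the warm-started penalty path.

Sparsity is imposed only on the final-layer coefficient matrix: after the
usual (bias-corrected) ADAM update produces a candidate iterate, a proximal
operator for the chosen penalty is applied coordinate-wise with a threshold
scaled by the same preconditioner as the step itself,

    tau_i = lr * lambda / (sqrt(v_hat_i) + delta).

L1 soft-thresholds (uniform shrinkage); the minimax concave penalty (MCP)
firm-thresholds: exact zero below tau, a linear b/(b-1) rescaling in the
middle zone, and no shrinkage at all once |theta_hat| >= b * tau, which is
what makes large selected coefficients nearly unbiased.

The preconditioner enters the threshold as sqrt(v_hat) by default (the
standard ADAM scaling); ``precond="raw"`` uses v_hat itself instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "prox_l1",
    "prox_mcp",
    "ProxAdam",
    "PathResult",
    "run_path",
    "default_lambda_grid",
]


def prox_l1(theta_hat: np.ndarray, thresh: np.ndarray | float) -> np.ndarray:
    """Soft-thresholding: sign(x) * max(|x| - thresh, 0)."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    return np.sign(theta_hat) * np.maximum(np.abs(theta_hat) - thresh, 0.0)


def prox_mcp(
    theta_hat: np.ndarray, thresh: np.ndarray | float, b: float
) -> np.ndarray:
    """MCP firm-thresholding with concavity parameter b > 1.

    sign(x) * min(b * max(|x| - thresh, 0) / (b - 1), |x|): a dead zone
    below ``thresh``, linear rescaling up to b * thresh, identity beyond.
    """
    if b <= 1:
        raise ValueError("MCP concavity parameter b must exceed 1")
    theta_hat = np.asarray(theta_hat, dtype=float)
    mag = np.abs(theta_hat)
    middle = b * np.maximum(mag - thresh, 0.0) / (b - 1.0)
    return np.sign(theta_hat) * np.minimum(middle, mag)


class ProxAdam:
    """ADAM over named tensors, with a proximal step on penalized ones.

    Parameters named in ``penalized`` (by default the final-layer ``coef``)
    receive prox_l1 / prox_mcp after each ADAM update; all other tensors
    get the vanilla update.
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        delta: float = 1e-8,
        penalty: str = "none",  # none | l1 | mcp
        lam: float = 0.0,
        b_mcp: float = 3.0,
        penalized: tuple[str, ...] = ("coef",),
        precond: str = "sqrt",  # sqrt | raw
    ):
        if penalty not in ("none", "l1", "mcp"):
            raise ValueError(f"unknown penalty {penalty!r}")
        if precond not in ("sqrt", "raw"):
            raise ValueError(f"unknown preconditioner mode {precond!r}")
        if lam < 0:
            raise ValueError("penalty strength must be nonnegative")
        if penalty == "mcp" and b_mcp <= 1:
            raise ValueError("MCP requires b > 1")
        self.params = dict(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.delta = delta
        self.penalty = penalty
        self.lam = lam
        self.b_mcp = b_mcp
        self.penalized = set(penalized)
        self.precond = precond
        self.t = 0
        self.m = {k: np.zeros_like(t.data) for k, t in self.params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in self.params.items()}

    def add_param(self, name: str, tensor: Tensor) -> None:
        """Register a newly unfrozen tensor with fresh moment estimates."""
        self.params[name] = tensor
        self.m[name] = np.zeros_like(tensor.data)
        self.v[name] = np.zeros_like(tensor.data)

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def _denom(self, vhat: np.ndarray) -> np.ndarray:
        core = np.sqrt(vhat) if self.precond == "sqrt" else vhat
        return core + self.delta

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for name, tensor in self.params.items():
            g = tensor.grad
            if g is None:
                continue
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for parameter {name!r}")
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            denom = self._denom(v / bc2)
            theta_hat = tensor.data - self.lr * (m / bc1) / denom
            if name in self.penalized and self.penalty != "none" and self.lam > 0:
                tau = self.lr * self.lam / denom
                if self.penalty == "l1":
                    theta_hat = prox_l1(theta_hat, tau)
                else:
                    theta_hat = prox_mcp(theta_hat, tau, self.b_mcp)
            tensor.data[...] = theta_hat


# ------------------------------------------------------------------- paths
@dataclass
class PathResult:
    """One warm-started fit per penalty strength, in increasing order."""

    lambdas: np.ndarray
    coefs: list[np.ndarray]  # (c, m) per lambda
    val_loss: np.ndarray
    support_size: np.ndarray  # exact-zero test

    def best_index(self, tol: float = 0.0) -> int:
        """Index of the selected penalty strength.

        With ``tol`` = 0 this is the validation-loss minimizer. A positive
        ``tol`` applies the usual parsimony rule for flat validation
        profiles (in the spirit of the one-standard-error rule): the
        largest lambda whose validation loss is within a relative ``tol``
        of the minimum.
        """
        vmin = float(np.min(self.val_loss))
        ok = np.flatnonzero(self.val_loss <= vmin * (1.0 + tol))
        return int(ok[-1])

    def support(self, i: int) -> np.ndarray:
        """Indices of motifs with any nonzero coefficient at step i."""
        return np.flatnonzero(np.any(self.coefs[i] != 0.0, axis=0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "val_loss": self.val_loss,
                "support_size": self.support_size,
            }
        )


def default_lambda_grid(
    lam_min: float = 1e-3, lam_max: float = 10.0, num: int = 20
) -> np.ndarray:
    """Log-spaced penalty grid; the top of the default range is chosen to
    empty most of the support on the bundled synthetic benchmarks."""
    return np.logspace(np.log10(lam_min), np.log10(lam_max), num)


def _as_xy(data):
    X, Y = data
    X = X.onehot if hasattr(X, "onehot") else np.asarray(X, float)
    Y = Y.values if hasattr(Y, "values") else np.asarray(Y, float)
    return X, Y


def _linear_prox_fit(G, Y, B, gamma, lam, penalty, b_mcp,
                     max_iter=5000, atol=1e-10):
    """Deterministic proximal-gradient fit of Y ~ G B^T + gamma.

    Classic ISTA-style iteration with a fixed 1/Lipschitz step: the
    stochastic prox-ADAM threshold is gradient-adaptive, which is the right
    behavior during noisy minibatch training but degenerates on a fully
    converged batch problem (vanishing gradients blow the effective
    threshold up); a constant step keeps the threshold tau = step * lambda
    stable so the support evolves smoothly along the path.

    Features are standardized internally (the usual convention for
    penalized regression, and the batch analogue of the preconditioner
    scaling in the stochastic prox step) so that one threshold is
    commensurate across motifs regardless of each feature's dynamic range;
    coefficients are mapped back to the original scale on return. The
    intercept is never penalized. Zero-variance features are unidentifiable
    next to the intercept and get coefficient zero.
    """
    n, m = G.shape
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    dead = sd < 1e-12
    sd_safe = np.where(dead, 1.0, sd)
    Gs = (G - mu) / sd_safe
    Gt = np.column_stack([Gs, np.ones(n)])  # last column carries the intercept
    Bs = B * sd_safe
    Bs[:, dead] = 0.0
    W = np.column_stack([Bs, gamma + B @ mu])  # (c, m + 1), standardized scale
    size = Y.size
    lips = 2.0 * np.linalg.norm(Gt, 2) ** 2 / size
    step = 1.0 / lips
    tau = step * lam
    for _ in range(max_iter):
        R = Gt @ W.T - Y  # (n, c)
        grad = 2.0 * R.T @ Gt / size
        W_new = W - step * grad
        if penalty != "none" and lam > 0:
            pen = W_new[:, :m]
            W_new[:, :m] = (prox_l1(pen, tau) if penalty == "l1"
                            else prox_mcp(pen, tau, b_mcp))
        W_new[:, :m][:, dead] = 0.0
        delta = np.max(np.abs(W_new - W))
        W = W_new
        if delta <= atol:
            break
    B_out = W[:, :m] / sd_safe
    gamma_out = W[:, m] - W[:, :m] @ (mu / sd_safe)
    return B_out, gamma_out


def run_path(
    model,
    train_data,
    val_data,
    lambdas,
    schedule=None,
    penalty: str = "mcp",
    b_mcp: float = 3.0,
    warm_start: bool = True,
    seed: int = 0,
    precond: str = "sqrt",
    final_layer_only: bool = True,
) -> PathResult:
    """Increasing-penalty path, each step warm-started from the previous fit.

    ``model`` should already be trained at zero penalty. The penalty acts
    on the final-layer coefficients only, so by default each grid point
    refits just the final layer against the trained model's (fixed) gated
    motif features -- a deterministic full-batch proximal fit that converges
    cleanly and keeps the rest of the network at its validated optimum.
    With ``final_layer_only=False`` the whole model continues training
    under the (short) schedule instead.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.ndim != 1 or len(lambdas) == 0:
        raise ValueError("lambda grid must be a nonempty 1-D sequence")
    if len(lambdas) > 1 and np.any(np.diff(lambdas) <= 0):
        raise ValueError("lambda grid must be strictly increasing")

    coefs, vloss = [], []
    if final_layer_only:
        Xtr, Ytr = _as_xy(train_data)
        Xva, Yva = _as_xy(val_data)
        Gtr = model.features(Xtr)
        Gva = model.features(Xva)
        B0 = model.params["coef"].data.copy()
        g0 = model.params["intercept"].data.copy()
        B, gamma = B0.copy(), g0.copy()
        for lam in lambdas:
            if not warm_start:
                B, gamma = B0.copy(), g0.copy()
            B, gamma = _linear_prox_fit(
                Gtr, Ytr, B, gamma, float(lam), penalty, b_mcp
            )
            coefs.append(B.copy())
            vloss.append(float(np.mean((Gva @ B.T + gamma - Yva) ** 2)))
    else:
        from .training import PathSchedule, fit

        if schedule is None:
            schedule = PathSchedule()
        start_state = model.params.copy_arrays()
        for i, lam in enumerate(lambdas):
            if not warm_start and i > 0:
                model.params.load_arrays(start_state)
            opt = ProxAdam(
                model.params.trainable(),
                lr=schedule.initial_lr,
                penalty=penalty,
                lam=float(lam),
                b_mcp=b_mcp,
                precond=precond,
            )
            # each step converges under its own penalty; the dense incumbent
            # must not displace the sparse solution, so keep the final state
            fit(model, train_data, val_data, schedule=schedule, optimizer=opt,
                seed=seed + i, restore_best=False)
            coefs.append(model.params["coef"].data.copy())
            Xva, Yva = _as_xy(val_data)
            vloss.append(float(np.mean((model.predict(Xva) - Yva) ** 2)))
    supp = [int(np.count_nonzero(np.any(Bi != 0.0, axis=0))) for Bi in coefs]
    return PathResult(
        lambdas=lambdas,
        coefs=coefs,
        val_loss=np.asarray(vloss),
        support_size=np.asarray(supp, dtype=int),
    )
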