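"""Denoising score matching for passive and active processes.

The score approximator is a small multilayer perceptron (tanh hidden layers,
sinusoidal time embedding) implemented directly in NumPy with Adam, which is
ample for the toy targets this package handles.  Training regresses the model
onto the conditional Gaussian-channel residuals
(:func:`activediff.analytic_scores.conditional_score_target`), whose posterior
expectation is the true score; the objective is the plain unweighted MSE, with
a sum of x- and eta-terms in the active case.  When ``Tp = 0`` the x-score
never enters the reverse dynamics and only the eta network is formed.

Each training iteration draws one time ``t ~ U(t_min, tf)`` shared by the
batch, and fresh noise, so the loss trajectory is a stochastic estimate of the
population DSM objective.  Trained providers plug directly into
:func:`activediff.reverse_sampler.generate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .analytic_scores import active_channel_moments, conditional_score_target
from .sde_core import ActiveParams, Params, PassiveParams, transition_moments

__all__ = [
    "ScoreModelSpec",
    "MLP",
    "time_embedding",
    "dsm_loss_passive",
    "dsm_loss_active",
    "train",
    "PassiveLearnedScore",
    "ActiveLearnedScore",
    "save_provider",
    "load_provider",
]


@dataclass(frozen=True)
class ScoreModelSpec:
    """Architecture and optimization settings for a learned score model."""

    hidden: tuple = (128, 128, 128)
    time_embed_dim: int = 16
    lr: float = 2e-3
    batch_size: int = 256
    n_iters: int = 3000
    t_min: float = 1e-3
    tf: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_embed_dim % 2 or self.time_embed_dim < 2:
            raise ValueError("time_embed_dim must be even and >= 2")
        if not (0 < self.t_min < self.tf):
            raise ValueError("need 0 < t_min < tf")

    def to_dict(self) -> dict:
        return {
            "hidden": list(self.hidden),
            "time_embed_dim": self.time_embed_dim,
            "lr": self.lr,
            "batch_size": self.batch_size,
            "n_iters": self.n_iters,
            "t_min": self.t_min,
            "tf": self.tf,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModelSpec":
        d = dict(d)
        d["hidden"] = tuple(d["hidden"])
        return cls(**d)


def time_embedding(t, dim: int) -> np.ndarray:
    """Sinusoidal embedding of (scalar or per-sample) time into ``dim`` features."""
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(100.0), half))
    tt = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
    ang = tt * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class MLP:
    """Plain tanh MLP with explicit backprop (linear output layer)."""

    def __init__(self, in_dim: int, hidden: tuple, out_dim: int, seed=0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sizes = [in_dim, *hidden, out_dim]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(b) for b in sizes[1:]]

    def forward(self, X: np.ndarray):
        hs = [X]
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.tanh(h @ W + b)
            hs.append(h)
        out = h @ self.W[-1] + self.b[-1]
        return out, hs

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def grads_from_output_grad(self, hs, g):
        """Backprop an output gradient; returns (gW, gb) lists."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        gW[-1] = hs[-1].T @ g
        gb[-1] = g.sum(axis=0)
        back = g @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            back = back * (1.0 - hs[i + 1] ** 2)
            gW[i] = hs[i].T @ back
            gb[i] = back.sum(axis=0)
            back = back @ self.W[i].T
        return gW, gb

    def params_flat(self):
        return self.W + self.b

    def state_dict(self) -> dict:
        return {"W": [w.tolist() for w in self.W], "b": [b.tolist() for b in self.b]}

    def load_state_dict(self, d: dict) -> None:
        self.W = [np.array(w) for w in d["W"]]
        self.b = [np.array(b) for b in d["b"]]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class PassiveLearnedScore:
    """Learned passive score: callable ``(x, t) -> score``."""

    def __init__(self, mlp: MLP, spec: ScoreModelSpec, d: int):
        self.mlp = mlp
        self.spec = spec
        self.d = d

    def _inputs(self, x, t):
        x = np.atleast_2d(x)
        emb = np.broadcast_to(
            time_embedding(t, self.spec.time_embed_dim), (x.shape[0], self.spec.time_embed_dim)
        )
        return np.concatenate([x, emb], axis=1)

    def __call__(self, x, t):
        return self.mlp(self._inputs(x, t))


class ActiveLearnedScore:
    """Learned active scores: callable ``(x, eta, t) -> (score_x, score_eta)``.

    ``mlp_x`` is None when Tp = 0 (the x-score is irrelevant for the reverse
    process and is never trained); the x slot of the result is then None.
    """

    def __init__(self, mlp_eta: MLP, mlp_x: MLP | None, spec: ScoreModelSpec, d: int):
        self.mlp_eta = mlp_eta
        self.mlp_x = mlp_x
        self.spec = spec
        self.d = d

    def _inputs(self, x, eta, t):
        x = np.atleast_2d(x)
        eta = np.atleast_2d(eta)
        emb = np.broadcast_to(
            time_embedding(t, self.spec.time_embed_dim), (x.shape[0], self.spec.time_embed_dim)
        )
        return np.concatenate([x, eta, emb], axis=1)

    def __call__(self, x, eta, t):
        inp = self._inputs(x, eta, t)
        fe = self.mlp_eta(inp)
        fx = self.mlp_x(inp) if self.mlp_x is not None else None
        return fx, fe


def _draw_passive_batch(params: PassiveParams, x0: np.ndarray, t: float, z: np.ndarray):
    tm = transition_moments(params, t)
    x_t = tm.propagator * x0 + np.sqrt(tm.covariance) * z
    target = -z / np.sqrt(tm.covariance)
    return x_t, target


def dsm_loss_passive(
    model, x0: np.ndarray, t: float, z: np.ndarray, params: PassiveParams, t_min: float = 1e-3
) -> float:
    """Denoising score-matching loss for one batch: MSE between the model and
    the conditional score target built from noise draws ``z``."""
    if t < t_min:
        raise ValueError(f"t={t} below t_min={t_min}: channel variance vanishes")
    x_t, target = _draw_passive_batch(params, np.atleast_2d(x0), t, z)
    pred = model(x_t, t) if not isinstance(model, MLP) else model(x_t)
    return float(np.mean((pred - target) ** 2))


def _draw_active_batch(params: ActiveParams, x0: np.ndarray, t: float, z: np.ndarray):
    """z has shape (n, d, 2); returns (x_t, eta_t, target_x, target_eta)."""
    A, cov = active_channel_moments(params, t, "stationary")
    l11 = np.sqrt(cov[0, 0])
    l21 = cov[0, 1] / l11
    l22 = np.sqrt(max(cov[1, 1] - l21 * l21, 0.0))
    x_t = A[0, 0] * x0 + l11 * z[..., 0]
    eta_t = l21 * z[..., 0] + l22 * z[..., 1]
    tx, te = conditional_score_target(params, t, x_t, eta_t, x0)
    return x_t, eta_t, tx, te


def dsm_loss_active(
    model: ActiveLearnedScore,
    x0: np.ndarray,
    t: float,
    z: np.ndarray,
    params: ActiveParams,
    t_min: float = 1e-3,
) -> float:
    """Sum of the x- and eta-score MSE terms; the x-term is absent when Tp=0."""
    if t < t_min:
        raise ValueError(f"t={t} below t_min={t_min}: channel variance vanishes")
    x_t, eta_t, tx, te = _draw_active_batch(params, np.atleast_2d(x0), t, z)
    fx, fe = model(x_t, eta_t, t)
    loss = float(np.mean((fe - te) ** 2))
    if params.Tp > 0:
        if fx is None:
            raise ValueError("Tp > 0 requires an x-score model")
        loss += float(np.mean((fx - tx) ** 2))
    return loss


def train(dataset, params: Params, spec: ScoreModelSpec):
    """Fit score model(s) by denoising score matching.

    ``dataset`` is an (n, d) array (or anything with a ``samples`` attribute).
    Returns ``(score_provider, log)`` where the provider plugs into
    :func:`activediff.reverse_sampler.generate` and ``log`` is a DataFrame
    with columns (iteration, loss).
    """
    x_data = np.atleast_2d(
        np.asarray(getattr(dataset, "samples", dataset), dtype=float)
    )
    if not np.all(np.isfinite(x_data)):
        raise ValueError("dataset must be finite")
    n, d = x_data.shape
    if n < spec.batch_size:
        raise ValueError(f"dataset size {n} below batch size {spec.batch_size}")
    rng = np.random.default_rng(spec.seed)
    losses = np.empty(spec.n_iters)
    # fixed validation batch (fixed x0, t, z): a deterministic loss whose
    # decrease tracks optimization progress, unlike the raw trajectory whose
    # scale is dominated by the random per-batch time
    n_val = min(512, n)
    val_idx = rng.choice(n, size=n_val, replace=False)
    val_t = 0.5 * (spec.t_min + spec.tf)
    eval_every = max(1, spec.n_iters // 60)
    val_losses = np.full(spec.n_iters, np.nan)

    def lr_scale(it: int) -> float:
        # cosine decay to 5% of the base rate; averages out target noise late
        return 0.05 + 0.95 * 0.5 * (1.0 + np.cos(np.pi * it / spec.n_iters))

    if isinstance(params, PassiveParams):
        mlp = MLP(d + spec.time_embed_dim, spec.hidden, d, seed=rng)
        opt = _Adam(mlp.params_flat(), spec.lr)
        provider = PassiveLearnedScore(mlp, spec, d)
        val_z = rng.standard_normal((n_val, d))
        val_xt, val_target = _draw_passive_batch(params, x_data[val_idx], val_t, val_z)
        for it in range(spec.n_iters):
            idx = rng.integers(0, n, size=spec.batch_size)
            t = rng.uniform(spec.t_min, spec.tf)
            z = rng.standard_normal((spec.batch_size, d))
            x_t, target = _draw_passive_batch(params, x_data[idx], t, z)
            out, hs = mlp.forward(provider._inputs(x_t, t))
            diff = out - target
            losses[it] = np.mean(diff**2)
            if not np.isfinite(losses[it]):
                raise RuntimeError(f"training diverged (loss={losses[it]}) at iteration {it}")
            gW, gb = mlp.grads_from_output_grad(hs, 2.0 * diff / diff.size)
            opt.step(gW + gb, lr_scale(it))
            if it % eval_every == 0 or it == spec.n_iters - 1:
                val_losses[it] = np.mean((provider(val_xt, val_t) - val_target) ** 2)
        log = pd.DataFrame(
            {"iteration": np.arange(spec.n_iters), "loss": losses, "val_loss": val_losses}
        )
        return provider, log

    in_dim = 2 * d + spec.time_embed_dim
    mlp_eta = MLP(in_dim, spec.hidden, d, seed=rng)
    mlp_x = MLP(in_dim, spec.hidden, d, seed=rng) if params.Tp > 0 else None
    opt_e = _Adam(mlp_eta.params_flat(), spec.lr)
    opt_x = _Adam(mlp_x.params_flat(), spec.lr) if mlp_x is not None else None
    provider = ActiveLearnedScore(mlp_eta, mlp_x, spec, d)
    val_z = rng.standard_normal((n_val, d, 2))
    val_xt, val_et, val_tx, val_te = _draw_active_batch(params, x_data[val_idx], val_t, val_z)
    for it in range(spec.n_iters):
        idx = rng.integers(0, n, size=spec.batch_size)
        t = rng.uniform(spec.t_min, spec.tf)
        z = rng.standard_normal((spec.batch_size, d, 2))
        x_t, eta_t, tx, te = _draw_active_batch(params, x_data[idx], t, z)
        inp = provider._inputs(x_t, eta_t, t)
        out_e, hs_e = mlp_eta.forward(inp)
        diff_e = out_e - te
        loss = np.mean(diff_e**2)
        gW, gb = mlp_eta.grads_from_output_grad(hs_e, 2.0 * diff_e / diff_e.size)
        opt_e.step(gW + gb, lr_scale(it))
        if mlp_x is not None:
            out_x, hs_x = mlp_x.forward(inp)
            diff_x = out_x - tx
            loss += np.mean(diff_x**2)
            gW, gb = mlp_x.grads_from_output_grad(hs_x, 2.0 * diff_x / diff_x.size)
            opt_x.step(gW + gb, lr_scale(it))
        losses[it] = loss
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged (loss={loss}) at iteration {it}")
        if it % eval_every == 0 or it == spec.n_iters - 1:
            vfx, vfe = provider(val_xt, val_et, val_t)
            vloss = np.mean((vfe - val_te) ** 2)
            if mlp_x is not None:
                vloss += np.mean((vfx - val_tx) ** 2)
            val_losses[it] = vloss
    log = pd.DataFrame(
        {"iteration": np.arange(spec.n_iters), "loss": losses, "val_loss": val_losses}
    )
    return provider, log


def save_provider(path, provider, params: Params) -> None:
    """Serialize a learned provider as JSON (weights + spec sidecar in one file)."""
    path = Path(path)
    if isinstance(provider, PassiveLearnedScore):
        blob = {
            "kind": "passive",
            "d": provider.d,
            "spec": provider.spec.to_dict(),
            "params": params.to_dict(),
            "mlp": provider.mlp.state_dict(),
        }
    else:
        blob = {
            "kind": "active",
            "d": provider.d,
            "spec": provider.spec.to_dict(),
            "params": params.to_dict(),
            "mlp_eta": provider.mlp_eta.state_dict(),
            "mlp_x": provider.mlp_x.state_dict() if provider.mlp_x is not None else None,
        }
    path.write_text(json.dumps(blob))


def load_provider(path):
    """Inverse of :func:`save_provider`; returns ``(provider, params)``."""
    from .sde_core import params_from_dict

    blob = json.loads(Path(path).read_text())
    spec = ScoreModelSpec.from_dict(blob["spec"])
    params = params_from_dict(blob["params"])
    d = blob["d"]
    if blob["kind"] == "passive":
        mlp = MLP(d + spec.time_embed_dim, spec.hidden, d)
        mlp.load_state_dict(blob["mlp"])
        return PassiveLearnedScore(mlp, spec, d), params
    in_dim = 2 * d + spec.time_embed_dim
    mlp_eta = MLP(in_dim, spec.hidden, d)
    mlp_eta.load_state_dict(blob["mlp_eta"])
    mlp_x = None
    if blob["mlp_x"] is not None:
        mlp_x = MLP(in_dim, spec.hidden, d)
        mlp_x.load_state_dict(blob["mlp_x"])
    return ActiveLearnedScore(mlp_eta, mlp_x, spec, d), params
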