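"""Euler-Maruyama integration of the reverse-time generative SDEs.

The forward processes are linear with drift matrix ``M`` and noise intensity
``D``; the corresponding reverse-time dynamics, integrated in reverse time
``s = tf - t``, have drift ``-M X + D * score`` and the same noise intensity.
Concretely, per dimension::

    passive:  dx   = ( k x + 2 T  F(x, t)) ds            + sqrt(2 Tp) dW
    active:   dx   = ( k x - eta + 2 Tp F_x(x, eta, t)) ds + sqrt(2 Tp) dW1
              deta = ( eta/tau + (2 Ta/tau^2) F_eta )   ds + sqrt(2 Ta)/tau dW2

When ``Tp = 0`` the x-update is deterministic given eta and the x-score is
never queried.  The integrator is deliberately plain Euler-Maruyama on a
uniform grid so that the dependence of sample quality on the step size dt is
meaningful; the score is queried at the current (larger) process time of each
step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sde_core import (
    ActiveParams,
    AugmentedEnsemble,
    Params,
    PassiveParams,
    stationary_moments,
)

__all__ = [
    "ReverseSchedule",
    "reverse_step_passive",
    "reverse_step_active",
    "integrate_reverse",
    "generate",
]


@dataclass(frozen=True)
class ReverseSchedule:
    """Uniform reverse-time grid: ``n_steps`` steps of size ``tf / n_steps``.

    ``denoise_last=None`` selects the process default: on for passive (final
    update drift-only), off for active (where the final denoising acts on eta
    and has no effect on the data coordinates).
    """

    tf: float
    n_steps: int
    denoise_last: bool | None = None

    def __post_init__(self) -> None:
        if not (self.tf > 0):
            raise ValueError(f"tf must be > 0, got {self.tf}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")

    @property
    def dt(self) -> float:
        return self.tf / self.n_steps

    def resolve_denoise_last(self, params: Params) -> bool:
        if self.denoise_last is not None:
            return self.denoise_last
        return isinstance(params, PassiveParams)


def reverse_step_passive(
    x: np.ndarray,
    score_value: np.ndarray,
    params: PassiveParams,
    dt: float,
    noise_draw: np.ndarray | None,
) -> np.ndarray:
    """One reverse-time update.  ``noise_draw`` is standard normal (scaled
    internally); pass ``None`` for a drift-only (denoising) step."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = x + dt * (params.k * x + 2.0 * params.T * score_value)
    if noise_draw is not None:
        out = out + np.sqrt(2.0 * params.T * dt) * noise_draw
    return out


def reverse_step_active(
    x: np.ndarray,
    eta: np.ndarray,
    score_x: np.ndarray | None,
    score_eta: np.ndarray,
    params: ActiveParams,
    dt: float,
    noise_x: np.ndarray | None,
    noise_eta: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """One coupled reverse-time update of (x, eta).

    ``score_x`` may be None when ``Tp == 0`` (the x-score term vanishes).
    Noise draws are standard normal or None for drift-only.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    drift_x = params.k * x - eta
    if params.Tp > 0:
        if score_x is None:
            raise ValueError("score_x required when Tp > 0")
        drift_x = drift_x + 2.0 * params.Tp * score_x
    x_new = x + dt * drift_x
    if params.Tp > 0 and noise_x is not None:
        x_new = x_new + np.sqrt(2.0 * params.Tp * dt) * noise_x
    eta_new = eta + dt * (eta / params.tau + (2.0 * params.Ta / params.tau**2) * score_eta)
    if noise_eta is not None:
        eta_new = eta_new + (np.sqrt(2.0 * params.Ta * dt) / params.tau) * noise_eta
    return x_new, eta_new


def integrate_reverse(
    score_provider,
    params: Params,
    state,
    schedule: ReverseSchedule,
    seed=None,
):
    """Integrate the reverse SDE from ``t = schedule.tf`` down to 0.

    ``state`` is an (n, d) array for the passive process or an
    ``(x, eta)`` pair / :class:`AugmentedEnsemble` for the active one.
    Returns the same shape of object at t = 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = schedule.dt
    denoise_last = schedule.resolve_denoise_last(params)
    if isinstance(params, PassiveParams):
        x = np.array(np.atleast_2d(state), dtype=float)
        for i in range(schedule.n_steps):
            t = schedule.tf - i * dt
            try:
                score = score_provider(x, t)
            except Exception as exc:  # re-raise with grid context
                raise RuntimeError(f"score provider failed at grid time t={t}") from exc
            last = i == schedule.n_steps - 1
            noise = None if (last and denoise_last) else rng.standard_normal(x.shape)
            x = reverse_step_passive(x, score, params, dt, noise)
        return x
    if isinstance(state, AugmentedEnsemble):
        x, eta = state.x.copy(), state.eta.copy()
    else:
        x, eta = (np.array(np.atleast_2d(s), dtype=float) for s in state)
    for i in range(schedule.n_steps):
        t = schedule.tf - i * dt
        try:
            fx, fe = score_provider(x, eta, t)
        except Exception as exc:
            raise RuntimeError(f"score provider failed at grid time t={t}") from exc
        last = i == schedule.n_steps - 1
        if last and denoise_last:
            # denoising acts on the eta dimension only; x is left unchanged
            _, eta = reverse_step_active(x, eta, fx, fe, params, dt, None, None)
            continue
        nx = rng.standard_normal(x.shape) if params.Tp > 0 else None
        ne = rng.standard_normal(eta.shape)
        x, eta = reverse_step_active(x, eta, fx, fe, params, dt, nx, ne)
    return AugmentedEnsemble(x=x, eta=eta, t=0.0, seed_record={"seed": seed})


def generate(
    score_provider,
    params: Params,
    schedule: ReverseSchedule,
    n_samples: int,
    d: int,
    seed=None,
    init="stationary",
):
    """Draw reverse-diffusion samples at t = 0.

    ``init="stationary"`` starts from the exact stationary law of the forward
    process (passive: N(0, T/k); active: the joint stationary Gaussian).
    Alternatively pass an explicit initial state -- e.g. an exact draw from the
    forward marginal at ``tf`` obtained from
    :meth:`activediff.analytic_scores.NoisedMixture.sample` -- to remove the
    O(e^{-2 k tf}) initialization bias.

    Returns an (n, d) array for the passive process, an
    :class:`AugmentedEnsemble` for the active one.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(init, str):
        if init != "stationary":
            raise ValueError(f"unknown init {init!r}")
        if isinstance(params, PassiveParams):
            state = rng.normal(
                0.0, np.sqrt(params.stationary_variance), size=(n_samples, d)
            )
        else:
            sig = stationary_moments(params)
            L = np.linalg.cholesky(sig)
            z = rng.standard_normal((n_samples, d, 2))
            ze = z @ L.T
            state = (ze[..., 0], ze[..., 1])
    else:
        state = init
    return integrate_reverse(score_provider, params, state, schedule, seed=rng)
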