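"""Information-retention diagnostics of the forward noising processes.

* Fisher memory matrix/curve: ``F_t = exp(M^T t) C_t^{-1} exp(M t)`` is the
  quadratic-form kernel of the KL divergence between forward conditionals
  whose initial conditions differ by a small perturbation; its trace (per data
  dimension) quantifies how long the process remembers its input.
* Speciation times: the forward times at which reverse trajectories commit to
  a mode of the target, in the printed closed forms.
* The equivalent passive temperature: the white-noise temperature whose
  stationary data variance matches the active process's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sde_core import (
    ActiveParams,
    Params,
    PassiveParams,
    stationary_moments,
    transition_moments,
)

__all__ = [
    "FisherMemoryCurve",
    "fisher_memory_matrix",
    "fmc_curve",
    "fmc_decay_rate",
    "speciation_time_active",
    "speciation_time_passive",
    "equivalent_passive_temperature",
]

# Ridge used when C_t is numerically singular (Tp = 0 at very small t makes
# the x-block reachable only through eta, so C_t is badly conditioned there).
_RIDGE = 1e-12


@dataclass(frozen=True)
class FisherMemoryCurve:
    """Fisher memory curve values (trace per data dimension) on a time grid."""

    times: np.ndarray
    values: np.ndarray
    params: Params

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.times <= 0):
            raise ValueError("FMC times must be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("FMC times must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("FMC values must be finite and positive")


def fisher_memory_matrix(params: Params, t: float) -> np.ndarray:
    """Per-dimension Fisher memory matrix at time ``t`` (> 0).

    Active: the 2x2 block ``A^T C^{-1} A`` on a perturbation of (x_i, eta_i).
    Passive: the 1x1 scalar ``k e^{-2kt} / (T (1 - e^{-2kt}))``.
    The matrix depends only on the drift and the noise statistics, not on the
    base input around which the perturbation is taken.
    """
    if t <= 0:
        raise ValueError(f"Fisher memory matrix requires t > 0, got {t}")
    tm = transition_moments(params, t)
    if isinstance(params, PassiveParams):
        return np.array([[tm.propagator**2 / tm.covariance]])
    A, C = tm.propagator, tm.covariance
    try:
        X = np.linalg.solve(C, A)
        F = A.T @ X
        if not np.all(np.isfinite(F)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        Cr = C + _RIDGE * max(np.max(np.diag(C)), 1.0) * np.eye(2)
        F = A.T @ np.linalg.solve(Cr, A)
    return 0.5 * (F + F.T)


def fmc_curve(params: Params, times) -> FisherMemoryCurve:
    """Fisher memory curve: trace of F_t per data dimension, on a time grid.

    The state is 2d-dimensional for the active process, so the per-dimension
    trace sums both the x and eta diagonal entries of the 2x2 block.
    """
    times = np.asarray(times, dtype=float)
    vals = np.array([np.trace(fisher_memory_matrix(params, t)) for t in times])
    return FisherMemoryCurve(times=times, values=vals, params=params)


def fmc_decay_rate(params: Params, t_window=(2.0, 6.0), n_grid: int = 41) -> float:
    """Exponential decay-rate estimate: minus the least-squares slope of
    log FMC(t) over ``t_window``.  Positive for any decaying curve."""
    ts = np.linspace(t_window[0], t_window[1], n_grid)
    curve = fmc_curve(params, ts)
    slope = np.polyfit(ts, np.log(curve.values), 1)[0]
    return -float(slope)


def speciation_time_active(lambda_max: float, Ta: float, tau: float) -> float:
    """Forward time at which active reverse trajectories commit to a mode:
    ``1/2 log(lambda_max (1 + tau) / Ta)``, with ``lambda_max`` the largest
    eigenvalue of the data covariance."""
    if lambda_max <= 0 or Ta <= 0:
        raise ValueError("lambda_max and Ta must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return 0.5 * np.log(lambda_max * (1.0 + tau) / Ta)


def speciation_time_passive(lambda_max: float, Tp: float) -> float:
    """Passive speciation time ``1/2 log(lambda_max / Tp)``."""
    if lambda_max <= 0 or Tp <= 0:
        raise ValueError("lambda_max and Tp must be > 0")
    return 0.5 * np.log(lambda_max / Tp)


def equivalent_passive_temperature(params: ActiveParams) -> float:
    """The passive temperature whose stationary x-variance matches the active
    process's: ``T = Tp + Ta / (1 + k tau)`` (equal to k * Var_stat(x))."""
    return float(params.k * stationary_moments(params)[0, 0])
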