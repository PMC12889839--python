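"""Exact transition statistics and samplers for the forward noising processes.

Two linear forward processes are supported:

* a *passive* Ornstein-Uhlenbeck process
  ``dx = -k x dt + sqrt(2 T) dW``, and
* an *active* process in which each data coordinate ``x_i`` is driven by an
  auxiliary Ornstein-Uhlenbeck coordinate ``eta_i`` with persistence time
  ``tau``::

      dx   = (-k x + eta) dt + sqrt(2 Tp)       dW1
      deta = (-eta / tau)  dt + sqrt(2 Ta)/tau  dW2

Both processes are linear and dimension-wise independent, so all transition
laws are Gaussian and are represented per dimension by a scalar (passive) or a
2x2 block (active).  Everything downstream (analytic scores, Fisher memory,
belief-propagation channels) is built on the closed forms computed here; no
time-stepping error enters except in the explicitly named Euler-Maruyama
reference integrators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "PassiveParams",
    "ActiveParams",
    "AugmentedEnsemble",
    "TransitionMoments",
    "drift_matrix",
    "transition_moments",
    "stationary_moments",
    "sample_forward",
    "sample_forward_passive",
    "euler_maruyama_forward",
    "euler_maruyama_forward_passive",
    "save_ensemble",
    "load_ensemble",
]

# Relative threshold below which |k - 1/tau| is treated as the confluent
# (equal-eigenvalue) branch of the matrix exponential.
_DEGENERATE_RTOL = 1e-8


@dataclass(frozen=True)
class PassiveParams:
    """Stiffness and temperature of the passive forward process."""

    k: float
    T: float

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"stiffness k must be > 0, got {self.k}")
        if not (self.T > 0):
            raise ValueError(f"temperature T must be > 0, got {self.T}")

    @property
    def stationary_variance(self) -> float:
        return self.T / self.k

    def to_dict(self) -> dict:
        return {"k": self.k, "T": self.T}

    @classmethod
    def from_dict(cls, d: dict) -> "PassiveParams":
        return cls(k=float(d["k"]), T=float(d["T"]))


@dataclass(frozen=True)
class ActiveParams:
    """Hyperparameters of the active forward process.

    ``Tp`` may be zero: in that case the reverse x-equation carries neither
    noise nor a score term, and only the eta-score is needed downstream.
    """

    k: float
    Tp: float
    Ta: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"stiffness k must be > 0, got {self.k}")
        if not (self.tau > 0):
            raise ValueError(f"persistence time tau must be > 0, got {self.tau}")
        if not (self.Ta > 0):
            raise ValueError(f"active temperature Ta must be > 0, got {self.Ta}")
        if self.Tp < 0:
            raise ValueError(f"passive temperature Tp must be >= 0, got {self.Tp}")

    @property
    def eta_stationary_variance(self) -> float:
        return self.Ta / self.tau

    def to_dict(self) -> dict:
        return {"k": self.k, "Tp": self.Tp, "Ta": self.Ta, "tau": self.tau}

    @classmethod
    def from_dict(cls, d: dict) -> "ActiveParams":
        return cls(
            k=float(d["k"]), Tp=float(d["Tp"]), Ta=float(d["Ta"]), tau=float(d["tau"])
        )


Params = Union[PassiveParams, ActiveParams]


def params_from_dict(d: dict) -> Params:
    """Deserialize either parameter type from its JSON dict form."""
    if "tau" in d:
        return ActiveParams.from_dict(d)
    return PassiveParams.from_dict(d)


@dataclass
class AugmentedEnsemble:
    """A batch of augmented states ``(x, eta)`` at a common process time."""

    x: np.ndarray
    eta: np.ndarray
    t: float
    seed_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.x.shape != self.eta.shape:
            raise ValueError(
                f"x and eta must share a shape, got {self.x.shape} vs {self.eta.shape}"
            )
        if self.t < 0:
            raise ValueError(f"process time must be >= 0, got {self.t}")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]


@dataclass(frozen=True)
class TransitionMoments:
    """Per-dimension propagator and covariance of a linear forward process.

    For the active process ``propagator`` and ``covariance`` are 2x2 arrays
    acting on ``(x_i, eta_i)``; for the passive process they are scalars.
    """

    propagator: np.ndarray
    covariance: np.ndarray
    t: float

    def compose(self, later: "TransitionMoments") -> "TransitionMoments":
        """Chapman-Kolmogorov composition: first self, then ``later``."""
        prop = np.atleast_2d(later.propagator) @ np.atleast_2d(self.propagator)
        cov = (
            np.atleast_2d(later.propagator)
            @ np.atleast_2d(self.covariance)
            @ np.atleast_2d(later.propagator).T
            + np.atleast_2d(later.covariance)
        )
        if np.ndim(self.propagator) == 0:
            prop = prop[0, 0]
            cov = cov[0, 0]
        return TransitionMoments(propagator=prop, covariance=cov, t=self.t + later.t)


def drift_matrix(params: ActiveParams) -> np.ndarray:
    """Per-dimension drift (Jacobian) of the active forward SDE on (x_i, eta_i)."""
    return np.array([[-params.k, 1.0], [0.0, -1.0 / params.tau]])


def _propagator_active(params: ActiveParams, t: float) -> np.ndarray:
    k, b = params.k, 1.0 / params.tau
    ek = np.exp(-k * t)
    eb = np.exp(-b * t)
    if abs(k - b) < _DEGENERATE_RTOL * k:
        # confluent branch: equal eigenvalues give the t*exp(-kt) secular term
        a = t * ek
    else:
        a = (eb - ek) / (k - b)
    return np.array([[ek, a], [0.0, eb]])


def _covariance_active(params: ActiveParams, t: float) -> np.ndarray:
    k, b = params.k, 1.0 / params.tau
    Tp, Ta = params.Tp, params.Ta
    e2k = np.exp(-2.0 * k * t)
    e2b = np.exp(-2.0 * b * t)
    ekb = np.exp(-(k + b) * t)
    c22 = Ta * b * (1.0 - e2b)
    if abs(k - b) < _DEGENERATE_RTOL * k:
        c12 = 0.5 * Ta * (1.0 - (1.0 + 2.0 * k * t) * e2k)
        c11 = (Tp / k) * (1.0 - e2k) + Ta * (
            2.0 - e2k * (4.0 * k * k * t * t + 4.0 * k * t + 2.0)
        ) / (4.0 * k)
    else:
        c12 = (
            2.0
            * Ta
            * b
            * b
            / (k - b)
            * ((1.0 - e2b) / (2.0 * b) - (1.0 - ekb) / (k + b))
        )
        c11 = (Tp / k) * (1.0 - e2k) + 2.0 * Ta * b * b / (k - b) ** 2 * (
            (1.0 - e2b) / (2.0 * b)
            - 2.0 * (1.0 - ekb) / (k + b)
            + (1.0 - e2k) / (2.0 * k)
        )
    return np.array([[c11, c12], [c12, c22]])


def transition_moments(params: Params, t: float) -> TransitionMoments:
    """Closed-form propagator exp(M t) and finite-time noise covariance at time t.

    Passive case returns scalar ``e^{-kt}`` and ``Delta_t = (T/k)(1 - e^{-2kt})``;
    active case returns the 2x2 per-dimension blocks, handling the degenerate
    eigenvalue branch ``k == 1/tau``.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if isinstance(params, PassiveParams):
        prop = np.exp(-params.k * t)
        cov = (params.T / params.k) * (1.0 - np.exp(-2.0 * params.k * t))
        return TransitionMoments(propagator=float(prop), covariance=float(cov), t=t)
    return TransitionMoments(
        propagator=_propagator_active(params, t),
        covariance=_covariance_active(params, t),
        t=t,
    )


def stationary_moments(params: ActiveParams) -> np.ndarray:
    """Per-dimension 2x2 stationary covariance of the augmented state (x_i, eta_i)."""
    k, tau, Tp, Ta = params.k, params.tau, params.Tp, params.Ta
    var_eta = Ta / tau
    cov_xe = Ta / (1.0 + k * tau)
    var_x = Tp / k + Ta / (k * (1.0 + k * tau))
    return np.array([[var_x, cov_xe], [cov_xe, var_eta]])


def _chol2_psd(c: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a symmetric PSD 2x2 matrix, tolerating zeros."""
    a, b_, d = c[0, 0], c[0, 1], c[1, 1]
    l11 = np.sqrt(max(a, 0.0))
    l21 = b_ / l11 if l11 > 0 else 0.0
    l22 = np.sqrt(max(d - l21 * l21, 0.0))
    return np.array([[l11, 0.0], [l21, l22]])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_eta0(
    params: ActiveParams, shape: tuple, policy: str, rng: np.random.Generator
) -> np.ndarray:
    if policy == "stationary":
        return rng.normal(0.0, np.sqrt(params.eta_stationary_variance), size=shape)
    if policy == "zero":
        return np.zeros(shape)
    raise ValueError(f"unknown eta0 policy {policy!r}")


def sample_forward(
    params: ActiveParams,
    x0: np.ndarray,
    t: float,
    eta0_policy: str = "stationary",
    seed=None,
) -> AugmentedEnsemble:
    """Exact one-shot draw from the active forward process at time ``t``.

    Uses the closed-form transition moments, so there is no discretization
    error.  ``eta0_policy`` selects the initial law of the auxiliary
    coordinates: the stationary OU marginal N(0, Ta/tau) (default) or a point
    mass at zero.
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    rng = _as_rng(seed)
    eta0 = _draw_eta0(params, x0.shape, eta0_policy, rng)
    tm = transition_moments(params, t)
    A = tm.propagator
    mean_x = A[0, 0] * x0 + A[0, 1] * eta0
    mean_e = A[1, 1] * eta0
    L = _chol2_psd(tm.covariance)
    z = rng.standard_normal(x0.shape + (2,))
    noise = z @ L.T  # (..., 2) rows are (x, eta) noise
    return AugmentedEnsemble(
        x=mean_x + noise[..., 0],
        eta=mean_e + noise[..., 1],
        t=t,
        seed_record={"seed": seed, "eta0_policy": eta0_policy, "t": t},
    )


def sample_forward_passive(
    params: PassiveParams, x0: np.ndarray, t: float, seed=None
) -> np.ndarray:
    """Exact draw from the passive forward process: N(x0 e^{-kt}, Delta_t)."""
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    rng = _as_rng(seed)
    tm = transition_moments(params, t)
    return tm.propagator * x0 + np.sqrt(tm.covariance) * rng.standard_normal(x0.shape)


def euler_maruyama_forward(
    params: ActiveParams,
    x0: np.ndarray,
    t: float,
    dt: float,
    eta0_policy: str = "stationary",
    seed=None,
) -> AugmentedEnsemble:
    """Time-stepped reference integrator for the active forward process.

    Exists as an independent check on :func:`transition_moments` /
    :func:`sample_forward`; production code should use the exact sampler.
    """
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    rng = _as_rng(seed)
    eta = _draw_eta0(params, x.shape, eta0_policy, rng)
    n_steps = int(round(t / dt))
    sx = np.sqrt(2.0 * params.Tp * dt)
    se = np.sqrt(2.0 * params.Ta * dt) / params.tau
    for _ in range(n_steps):
        x_new = x + dt * (-params.k * x + eta) + sx * rng.standard_normal(x.shape)
        eta = eta + dt * (-eta / params.tau) + se * rng.standard_normal(x.shape)
        x = x_new
    return AugmentedEnsemble(x=x, eta=eta, t=n_steps * dt, seed_record={"seed": seed})


def euler_maruyama_forward_passive(
    params: PassiveParams, x0: np.ndarray, t: float, dt: float, seed=None
) -> np.ndarray:
    """Time-stepped reference integrator for the passive forward process."""
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    rng = _as_rng(seed)
    n_steps = int(round(t / dt))
    s = np.sqrt(2.0 * params.T * dt)
    for _ in range(n_steps):
        x = x + dt * (-params.k * x) + s * rng.standard_normal(x.shape)
    return x


def save_ensemble(
    path, ensemble: AugmentedEnsemble, params: Params | None = None
) -> None:
    """Write an ensemble as CSV plus a JSON metadata sidecar (``<path>.json``)."""
    import pandas as pd

    path = Path(path)
    d = ensemble.d
    cols = {f"x_{i + 1}": ensemble.x[:, i] for i in range(d)}
    cols.update({f"eta_{i + 1}": ensemble.eta[:, i] for i in range(d)})
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"t": ensemble.t, "seed_record": ensemble.seed_record}
    if params is not None:
        meta["params"] = params.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, default=str))


def load_ensemble(path) -> AugmentedEnsemble:
    """Read an ensemble written by :func:`save_ensemble`."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    xcols = sorted([c for c in df.columns if c.startswith("x_")], key=lambda c: int(c[2:]))
    ecols = sorted([c for c in df.columns if c.startswith("eta_")], key=lambda c: int(c[4:]))
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    x = df[xcols].to_numpy()
    eta = df[ecols].to_numpy() if ecols else np.zeros_like(x)
    return AugmentedEnsemble(
        x=x, eta=eta, t=float(meta.get("t", 0.0)), seed_record=meta.get("seed_record", {})
    )
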