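"""Closed-form scores for Gaussian-mixture targets under passive and active noising.

A diagonal-covariance Gaussian mixture pushed through either linear forward
process stays a Gaussian mixture with unchanged weights; per component and per
dimension the noised law is a 1D Gaussian (passive) or a 2x2 joint Gaussian on
(x_i, eta_i) (active).  Scores are responsibility-weighted sums of the
per-component Gaussian scores, computed in log space.

Also provides the per-sample denoising regression targets whose posterior
expectation equals the true score -- the training targets for denoising score
matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .sde_core import ActiveParams, Params, PassiveParams, transition_moments

__all__ = [
    "GaussianMixture",
    "NoisedMixture",
    "DegenerateCovarianceError",
    "noised_mixture",
    "active_channel_moments",
    "passive_score",
    "active_score",
    "conditional_score_target",
    "PassiveAnalyticScore",
    "ActiveAnalyticScore",
]

_LOG_2PI = np.log(2.0 * np.pi)


class DegenerateCovarianceError(ValueError):
    """Raised when a noised component covariance is singular (e.g. t=0 with a
    zero-variance eta policy)."""


@dataclass(frozen=True)
class GaussianMixture:
    """Weighted diagonal-covariance Gaussian mixture.

    Attributes
    ----------
    weights : (K,) probability vector, all entries > 0.
    means : (K, d) component means.
    variances : (K, d) per-dimension component variances, all > 0.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "means", np.atleast_2d(np.asarray(self.means, dtype=float)))
        object.__setattr__(
            self, "variances", np.atleast_2d(np.asarray(self.variances, dtype=float))
        )
        if self.weights.ndim != 1 or len(self.weights) != self.means.shape[0]:
            raise ValueError("weights must be a vector aligned with means")
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must share a shape")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be > 0")

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        r = x[:, None, :] - self.means[None, :, :]
        ll = -0.5 * np.sum(
            r * r / self.variances + np.log(self.variances) + _LOG_2PI, axis=2
        )
        return logsumexp(ll + np.log(self.weights), axis=1)

    def score(self, x: np.ndarray) -> np.ndarray:
        """Gradient of log density of the un-noised mixture."""
        return passive_score(self, None, 0.0, x)

    def sample(self, n: int, seed=None, return_labels: bool = False):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        labels = rng.choice(self.n_components, size=n, p=self.weights)
        x = self.means[labels] + np.sqrt(self.variances[labels]) * rng.standard_normal(
            (n, self.d)
        )
        return (x, labels) if return_labels else x

    def to_json(self, path=None) -> str:
        s = json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "GaussianMixture":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
        )


@dataclass(frozen=True)
class NoisedMixture:
    """A Gaussian mixture pushed through a linear forward process to time t.

    ``kind == "passive"``: ``means`` is (K, d) and ``covs`` is (K, d) diagonal
    variances.  ``kind == "active"``: ``means`` is (K, d, 2) over (x_i, eta_i)
    and ``covs`` is (K, d, 2, 2).
    """

    kind: str
    weights: np.ndarray
    means: np.ndarray
    covs: np.ndarray
    t: float

    # ---- passive marginal interface -------------------------------------
    def logpdf(self, x: np.ndarray, eta: np.ndarray | None = None) -> np.ndarray:
        if self.kind == "passive":
            r = np.atleast_2d(x)[:, None, :] - self.means[None, :, :]
            ll = -0.5 * np.sum(r * r / self.covs + np.log(self.covs) + _LOG_2PI, axis=2)
            return logsumexp(ll + np.log(self.weights), axis=1)
        if eta is None:
            raise ValueError("active noised mixture requires both x and eta")
        ll = self._joint_component_loglik(np.atleast_2d(x), np.atleast_2d(eta))
        return logsumexp(ll + np.log(self.weights), axis=1)

    def _precision(self) -> tuple[np.ndarray, np.ndarray]:
        a = self.covs[..., 0, 0]
        b = self.covs[..., 0, 1]
        d = self.covs[..., 1, 1]
        det = a * d - b * b
        if np.any(det <= 0):
            raise DegenerateCovarianceError(
                "singular noised component covariance; need t > 0 or a "
                "nondegenerate eta policy"
            )
        P = np.empty_like(self.covs)
        P[..., 0, 0] = d / det
        P[..., 1, 1] = a / det
        P[..., 0, 1] = P[..., 1, 0] = -b / det
        return P, np.log(det)

    def _joint_component_loglik(self, x: np.ndarray, eta: np.ndarray) -> np.ndarray:
        P, logdet = self._precision()
        rx = x[:, None, :] - self.means[None, :, :, 0]
        re = eta[:, None, :] - self.means[None, :, :, 1]
        quad = (
            P[..., 0, 0] * rx * rx
            + 2.0 * P[..., 0, 1] * rx * re
            + P[..., 1, 1] * re * re
        )
        return -0.5 * np.sum(quad + logdet + 2.0 * _LOG_2PI, axis=2)

    def score(self, x: np.ndarray, eta: np.ndarray | None = None):
        """Gradient(s) of the log noised density at the given points."""
        if self.kind == "passive":
            x = np.atleast_2d(x)
            r = x[:, None, :] - self.means[None, :, :]
            ll = -0.5 * np.sum(r * r / self.covs + np.log(self.covs) + _LOG_2PI, axis=2)
            ll = ll + np.log(self.weights)
            resp = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
            return np.einsum("nk,nkd->nd", resp, -r / self.covs)
        if eta is None:
            raise ValueError("active noised mixture requires both x and eta")
        x = np.atleast_2d(x)
        eta = np.atleast_2d(eta)
        P, _ = self._precision()
        rx = x[:, None, :] - self.means[None, :, :, 0]
        re = eta[:, None, :] - self.means[None, :, :, 1]
        ll = self._joint_component_loglik(x, eta) + np.log(self.weights)
        resp = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
        sx = -(P[..., 0, 0] * rx + P[..., 0, 1] * re)
        se = -(P[..., 0, 1] * rx + P[..., 1, 1] * re)
        return (
            np.einsum("nk,nkd->nd", resp, sx),
            np.einsum("nk,nkd->nd", resp, se),
        )

    def sample(self, n: int, seed=None, return_labels: bool = False):
        """Exact draw from the noised mixture (the forward marginal at time t)."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        K = len(self.weights)
        labels = rng.choice(K, size=n, p=self.weights)
        if self.kind == "passive":
            x = self.means[labels] + np.sqrt(self.covs[labels]) * rng.standard_normal(
                (n, self.means.shape[1])
            )
            return (x, labels) if return_labels else x
        d = self.means.shape[1]
        # per-(component, dim) 2x2 Cholesky factors
        a = self.covs[..., 0, 0]
        b = self.covs[..., 0, 1]
        c = self.covs[..., 1, 1]
        l11 = np.sqrt(np.maximum(a, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            l21 = np.where(l11 > 0, b / np.where(l11 > 0, l11, 1.0), 0.0)
        l22 = np.sqrt(np.maximum(c - l21 * l21, 0.0))
        z = rng.standard_normal((n, d, 2))
        l11s, l21s, l22s = l11[labels], l21[labels], l22[labels]
        x = self.means[labels, :, 0] + l11s * z[..., 0]
        eta = self.means[labels, :, 1] + l21s * z[..., 0] + l22s * z[..., 1]
        out = (x, eta)
        return out + (labels,) if return_labels else out


def noised_mixture(
    gmm: GaussianMixture,
    params: Params | None,
    t: float,
    eta0_policy: str = "stationary",
) -> NoisedMixture:
    """Push a Gaussian mixture through the forward process to time ``t``.

    ``params=None`` (or t=0 passive) returns the target itself in passive form.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if params is None or (isinstance(params, PassiveParams) and t == 0.0):
        return NoisedMixture(
            kind="passive",
            weights=gmm.weights,
            means=gmm.means,
            covs=gmm.variances,
            t=t,
        )
    if isinstance(params, PassiveParams):
        tm = transition_moments(params, t)
        return NoisedMixture(
            kind="passive",
            weights=gmm.weights,
            means=gmm.means * tm.propagator,
            covs=gmm.variances * tm.propagator**2 + tm.covariance,
            t=t,
        )
    tm = transition_moments(params, t)
    A, C = tm.propagator, tm.covariance
    if eta0_policy == "stationary":
        s_eta = params.eta_stationary_variance
    elif eta0_policy == "zero":
        s_eta = 0.0
    else:
        raise ValueError(f"unknown eta0 policy {eta0_policy!r}")
    K, d = gmm.means.shape
    means = np.zeros((K, d, 2))
    means[:, :, 0] = A[0, 0] * gmm.means
    covs = np.empty((K, d, 2, 2))
    # A diag(h, s_eta) A^T + C, with A upper triangular
    covs[..., 0, 0] = A[0, 0] ** 2 * gmm.variances + A[0, 1] ** 2 * s_eta + C[0, 0]
    covs[..., 0, 1] = covs[..., 1, 0] = A[0, 1] * A[1, 1] * s_eta + C[0, 1]
    covs[..., 1, 1] = A[1, 1] ** 2 * s_eta + C[1, 1]
    nm = NoisedMixture(kind="active", weights=gmm.weights, means=means, covs=covs, t=t)
    nm._precision()  # validate non-degeneracy eagerly
    return nm


def passive_score(
    gmm: GaussianMixture, params: PassiveParams | None, t: float, x: np.ndarray
) -> np.ndarray:
    """Gradient of the log noised-mixture density for the passive process."""
    return noised_mixture(gmm, params, t).score(x)


def active_score(
    gmm: GaussianMixture,
    params: ActiveParams,
    t: float,
    x: np.ndarray,
    eta: np.ndarray,
    eta0_policy: str = "stationary",
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the joint log noised density over (x, eta)."""
    return noised_mixture(gmm, params, t, eta0_policy).score(x, eta)


def active_channel_moments(params: ActiveParams, t: float, eta0_policy: str = "stationary"):
    """Mean map and covariance of (x_t, eta_t) given x0, with eta0 marginalized.

    Returns ``(A, cov)`` where the channel is
    ``(x_t, eta_t) ~ N((A[0,0] x0, 0), cov)`` per dimension."""
    tm = transition_moments(params, t)
    A, C = tm.propagator, tm.covariance
    if eta0_policy == "stationary":
        s_eta = params.eta_stationary_variance
    elif eta0_policy == "zero":
        s_eta = 0.0
    else:
        raise ValueError(f"unknown eta0 policy {eta0_policy!r}")
    cov = C + np.array(
        [
            [A[0, 1] ** 2 * s_eta, A[0, 1] * A[1, 1] * s_eta],
            [A[0, 1] * A[1, 1] * s_eta, A[1, 1] ** 2 * s_eta],
        ]
    )
    return A, cov


def conditional_score_target(
    params: Params,
    t: float,
    x_t: np.ndarray,
    eta_t: np.ndarray | None,
    x0: np.ndarray,
    eta0_policy: str = "stationary",
):
    """Denoising regression target(s): the score of the Gaussian transition
    channel P(state_t | x0), whose posterior average over x0 is the true score.

    Passive: ``-(x_t - x0 e^{-kt}) / Delta_t``.  Active: the analogous
    residual for the joint (x, eta) channel with eta0 marginalized under the
    given policy.  ``t == 0`` is rejected (zero channel variance).
    """
    if t <= 0:
        raise ValueError("conditional score target requires t > 0")
    x_t = np.asarray(x_t, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if isinstance(params, PassiveParams):
        tm = transition_moments(params, t)
        return -(x_t - tm.propagator * x0) / tm.covariance
    if eta_t is None:
        raise ValueError("active target requires eta_t")
    eta_t = np.asarray(eta_t, dtype=float)
    A, cov = active_channel_moments(params, t, eta0_policy)
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det <= 0:
        raise DegenerateCovarianceError("degenerate active channel covariance")
    p00, p01, p11 = cov[1, 1] / det, -cov[0, 1] / det, cov[0, 0] / det
    rx = x_t - A[0, 0] * x0
    re = eta_t  # channel mean of eta_t is zero for both eta0 policies
    return (-(p00 * rx + p01 * re), -(p01 * rx + p11 * re))


class PassiveAnalyticScore:
    """Callable ``(x, t) -> score`` backed by the closed-form noised mixture."""

    def __init__(self, gmm: GaussianMixture, params: PassiveParams):
        self.gmm = gmm
        self.params = params

    def __call__(self, x: np.ndarray, t: float) -> np.ndarray:
        return passive_score(self.gmm, self.params, t, x)


class ActiveAnalyticScore:
    """Callable ``(x, eta, t) -> (score_x, score_eta)``."""

    def __init__(
        self, gmm: GaussianMixture, params: ActiveParams, eta0_policy: str = "stationary"
    ):
        self.gmm = gmm
        self.params = params
        self.eta0_policy = eta0_policy

    def __call__(self, x: np.ndarray, eta: np.ndarray, t: float):
        return active_score(self.gmm, self.params, t, x, eta, self.eta0_policy)
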