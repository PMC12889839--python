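"""Seeded generators for the synthetic target distributions used throughout.

Each fixture returns both samples and, where one exists, the exact generating
law (a :class:`GaussianMixture` or a parameter record), so that analytic
scores and Bayes-optimal classification are available downstream.  All
parameter defaults are artifact conventions chosen to realize the intended
qualitative regimes (well-separated vs. overlapping peaks, multi-scale rolls,
three Ramachandran-like basins); they are configurable.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import vonmises

from .analytic_scores import GaussianMixture
from .experiments import LabeledDataset

__all__ = [
    "diamond_gmm",
    "cluster_gmm",
    "swiss_rolls",
    "multi_peak_1d",
    "dihedral_proxy",
    "DIHEDRAL_BASINS",
]

# (phi, psi) basin centers in degrees: alpha_R, P_II, C5.
DIHEDRAL_BASINS = np.array([[-60.0, -45.0], [-75.0, 145.0], [-180.0, 180.0]])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def diamond_gmm(
    n: int, seed=None, spacing: float = 2.0, sigma: float = 0.1
) -> tuple[LabeledDataset, GaussianMixture]:
    """Nine equal-weight isotropic Gaussians on a diamond lattice, rescaled to
    unit per-dimension data variance.  Labels are component indices."""
    s = spacing
    centers = np.array(
        [
            [0.0, 0.0],
            [s, 0.0],
            [-s, 0.0],
            [0.0, s],
            [0.0, -s],
            [s / 2, s / 2],
            [s / 2, -s / 2],
            [-s / 2, s / 2],
            [-s / 2, -s / 2],
        ]
    )
    weights = np.full(9, 1.0 / 9.0)
    var = sigma**2
    # total per-dim variance of the mixture (means average to zero)
    total = np.mean(np.sum(weights[:, None] * centers**2, axis=0)) + var
    scale = 1.0 / np.sqrt(total)
    gmm = GaussianMixture(
        weights=weights,
        means=centers * scale,
        variances=np.full((9, 2), var * scale**2),
    )
    x, labels = gmm.sample(n, seed=_rng(seed), return_labels=True)
    ds = LabeledDataset(samples=x, labels=labels, gmm=gmm, meta={"name": "diamond"})
    return ds, gmm


def cluster_gmm(
    n: int,
    n_classes: int = 3,
    seed=None,
    radius: float = 2.0,
    sigma: float = 0.25,
) -> tuple[LabeledDataset, GaussianMixture]:
    """Equal-weight well-separated 2D clusters on a circle; one class per
    component.  The labeled dataset for class-recovery experiments."""
    angles = 2.0 * np.pi * np.arange(n_classes) / n_classes
    means = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    gmm = GaussianMixture(
        weights=np.full(n_classes, 1.0 / n_classes),
        means=means,
        variances=np.full((n_classes, 2), sigma**2),
    )
    x, labels = gmm.sample(n, seed=_rng(seed), return_labels=True)
    return (
        LabeledDataset(samples=x, labels=labels, gmm=gmm, meta={"name": "clusters"}),
        gmm,
    )


def swiss_rolls(
    n: int, n_rolls: int = 2, seed=None, noise: float = 0.02
) -> LabeledDataset:
    """Overlapping 2D spiral point clouds: global roll placement and interior
    winding give the distribution structure at two length scales."""
    rng = _rng(seed)
    labels = rng.integers(0, n_rolls, size=n)
    theta = rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=n)
    r = theta / (4.5 * np.pi)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    # roll centers offset by one radius so neighbouring rolls overlap
    offsets = np.column_stack(
        [np.arange(n_rolls) * 1.0 - 0.5 * (n_rolls - 1), np.zeros(n_rolls)]
    )
    # alternate handedness so interiors interleave in the overlap region
    signs = np.where(labels % 2 == 0, 1.0, -1.0)
    pts[:, 0] *= signs
    pts += offsets[labels]
    pts += noise * rng.standard_normal(pts.shape)
    return LabeledDataset(samples=pts, labels=labels, meta={"name": "swiss_rolls"})


def multi_peak_1d(
    kind: str, n: int, seed=None
) -> tuple[LabeledDataset, GaussianMixture]:
    """1D multi-peak targets: ``coarse3`` has three equal, nearly disjoint
    peaks; ``fine5`` has one dominant peak flanked by four overlapping minor
    ones (weights 0.8 and 4 x 0.05)."""
    if kind == "coarse3":
        means = np.array([[-4.0], [0.0], [4.0]])
        weights = np.full(3, 1.0 / 3.0)
        variances = np.full((3, 1), 0.09)
    elif kind == "fine5":
        means = np.array([[-1.6], [-0.8], [0.0], [0.8], [1.6]])
        weights = np.array([0.05, 0.05, 0.8, 0.05, 0.05])
        variances = np.full((5, 1), 0.16)
    else:
        raise ValueError(f"unknown kind {kind!r}; expected 'coarse3' or 'fine5'")
    gmm = GaussianMixture(weights=weights, means=means, variances=variances)
    x, labels = gmm.sample(n, seed=_rng(seed), return_labels=True)
    return (
        LabeledDataset(samples=x, labels=labels, gmm=gmm, meta={"name": kind}),
        gmm,
    )


def dihedral_proxy(
    n: int,
    seed=None,
    weights=(0.5, 0.35, 0.15),
    kappa: float = 20.0,
) -> LabeledDataset:
    """Von Mises mixture on the (phi, psi) torus standing in for a
    Ramachandran-sampled dipeptide: basins at alpha_R(-60, -45),
    P_II(-75, 145) and C5(-180, 180) degrees, wrapped to [-180, 180)."""
    rng = _rng(seed)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != 3 or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("need 3 weights summing to 1")
    labels = rng.choice(3, size=n, p=weights)
    loc = np.deg2rad(DIHEDRAL_BASINS[labels])
    ang = vonmises.rvs(kappa, loc=loc, size=(n, 2), random_state=rng)
    deg = (np.rad2deg(ang) + 180.0) % 360.0 - 180.0
    return LabeledDataset(
        samples=deg,
        labels=labels,
        meta={
            "name": "dihedral_proxy",
            "basins_deg": DIHEDRAL_BASINS.tolist(),
            "weights": weights.tolist(),
            "kappa": kappa,
            "period": 360.0,
        },
    )
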