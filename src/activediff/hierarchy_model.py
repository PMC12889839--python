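"""Random-hierarchy data model with noisy leaves and exact root inference.

A depth-L grammar expands a root symbol (the class) level by level: each
symbol at a level has ``m`` ordered productions, each an s-tuple of symbols of
the next level, drawn without replacement so that no tuple is shared between
two (symbol, rule) pairs -- this unambiguity makes sum-product inference
exact.  Leaves are embedded one-hot in R^v and corrupted by the passive or
active forward process; belief propagation then recovers the posterior over
root classes from the noised (x[, eta]) leaf vectors.

The class-recovery curves measure, as a function of noising time, how long
each noising process preserves the class identity, and the marginal-vs-joint
comparison isolates the information stored in the auxiliary eta coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .analytic_scores import active_channel_moments
from .sde_core import (
    ActiveParams,
    Params,
    PassiveParams,
    sample_forward,
    sample_forward_passive,
    transition_moments,
)

__all__ = [
    "HierarchyParams",
    "HierarchyGrammar",
    "LeafEncoding",
    "sample_grammar",
    "sample_datum",
    "noise_leaves",
    "bp_root_posterior",
    "class_recovery_curve",
    "marginal_vs_joint_recovery",
]


@dataclass(frozen=True)
class HierarchyParams:
    """Tree depth L, branching factor s, productions per symbol m, vocabulary v."""

    L: int = 10
    s: int = 2
    m: int = 8
    v: int = 32

    def __post_init__(self) -> None:
        for name in ("L", "s", "m", "v"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.m * self.v > self.v**self.s:
            raise ValueError(
                f"infeasible grammar: m*v = {self.m * self.v} distinct productions "
                f"needed but only v^s = {self.v ** self.s} tuples exist"
            )

    @property
    def n_leaves(self) -> int:
        return self.s**self.L


@dataclass
class HierarchyGrammar:
    """Per-level production tables; ``tables[l]`` has shape (v, m, s) and maps
    a level-l symbol to its productions over level-(l+1) symbols (level 0 is
    the root, level L holds the leaves)."""

    params: HierarchyParams
    tables: list
    seed_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.params
        if len(self.tables) != p.L:
            raise ValueError("need one production table per level")
        for tab in self.tables:
            if tab.shape != (p.v, p.m, p.s):
                raise ValueError("production table shape must be (v, m, s)")


@dataclass(frozen=True)
class LeafEncoding:
    """Injective map from leaf symbols to points in R^v (one-hot by default)."""

    v: int
    matrix: np.ndarray | None = None  # (v, v); row c encodes symbol c

    def encode(self, symbols: np.ndarray) -> np.ndarray:
        if self.matrix is not None:
            return self.matrix[symbols]
        return np.eye(self.v)[symbols]


def sample_grammar(params: HierarchyParams, seed=None) -> HierarchyGrammar:
    """Draw an unambiguous random grammar: at each level, m distinct s-tuples
    per symbol, all m*v tuples distinct (sampled without replacement)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params
    tables = []
    for _ in range(p.L):
        chosen = rng.permutation(p.v**p.s)[: p.m * p.v]
        # decode tuple index into s base-v digits
        digits = np.empty((p.m * p.v, p.s), dtype=np.int64)
        rem = chosen.copy()
        for j in range(p.s - 1, -1, -1):
            digits[:, j] = rem % p.v
            rem //= p.v
        tables.append(digits.reshape(p.v, p.m, p.s))
    return HierarchyGrammar(params=p, tables=tables, seed_record={"seed": seed})


def sample_datum(
    grammar: HierarchyGrammar, root_class: int, seed=None
) -> tuple[np.ndarray, list]:
    """Expand a root symbol to the leaves with uniform rule choices.

    Returns the leaf symbol string (length s^L) and the full tree (one symbol
    array per level, root first)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = grammar.params
    symbols = np.array([root_class], dtype=np.int64)
    tree = [symbols]
    for tab in grammar.tables:
        rules = rng.integers(0, p.m, size=len(symbols))
        symbols = tab[symbols, rules].reshape(-1)
        tree.append(symbols)
    return symbols, tree


def noise_leaves(
    leaves: np.ndarray,
    encoding: LeafEncoding,
    params: Params,
    t: float,
    seed=None,
):
    """Apply the forward noising channel to one-hot encoded leaves.

    Returns ``x`` of shape (n_leaves, v) for a passive channel, or ``(x, eta)``
    for the active channel (eta0 stationary)."""
    x0 = encoding.encode(np.asarray(leaves))
    if isinstance(params, PassiveParams):
        return sample_forward_passive(params, x0, t, seed=seed)
    ens = sample_forward(params, x0, t, eta0_policy="stationary", seed=seed)
    return ens.x, ens.eta


def _leaf_loglik(
    x: np.ndarray,
    eta: np.ndarray | None,
    params: Params,
    t: float,
    marginal: bool = False,
) -> np.ndarray:
    """Per-leaf log-likelihood table (n_leaves, v) for one-hot channels,
    up to a symbol-independent constant.

    With a one-hot mean ``mu * e_c`` only coordinate c distinguishes symbols,
    so each row reduces to a linear function of (x[:, c], eta[:, c])."""
    if isinstance(params, PassiveParams):
        tm = transition_moments(params, t)
        mu, var = tm.propagator, tm.covariance
        return (mu * x - 0.5 * mu * mu) / var
    _, cov = active_channel_moments(params, t, "stationary")
    mu = np.exp(-params.k * t)
    if marginal or eta is None:
        return (mu * x - 0.5 * mu * mu) / cov[0, 0]
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    p00 = cov[1, 1] / det
    p01 = -cov[0, 1] / det
    return mu * (p00 * x + p01 * eta) - 0.5 * p00 * mu * mu


def bp_root_posterior(
    x: np.ndarray,
    eta: np.ndarray | None,
    grammar: HierarchyGrammar,
    params: Params,
    t: float,
    marginal: bool = False,
) -> np.ndarray:
    """Exact sum-product posterior over the v root classes given noised leaves.

    ``marginal=True`` ignores eta and uses the x-marginal of the active
    channel -- inference on the data degrees of freedom alone."""
    p = grammar.params
    msg = _leaf_loglik(np.asarray(x), eta, params, t, marginal=marginal)
    if msg.shape != (p.n_leaves, p.v):
        raise ValueError(f"expected {p.n_leaves} leaf vectors of dimension {p.v}")
    msg = msg - msg.max(axis=1, keepdims=True)
    for tab in reversed(grammar.tables):
        n_nodes = msg.shape[0] // p.s
        child = msg.reshape(n_nodes, p.s, p.v)
        # sum child messages along each production tuple, then average rules
        tot = child[:, 0, :][:, tab[:, :, 0]]
        for j in range(1, p.s):
            tot = tot + child[:, j, :][:, tab[:, :, j]]
        # manual log-sum-exp over rules (hot loop)
        mx = tot.max(axis=2, keepdims=True)
        msg = np.log(np.exp(tot - mx).sum(axis=2)) + mx[..., 0] - np.log(p.m)
        msg = msg - msg.max(axis=1, keepdims=True)
    post = msg[0] - logsumexp(msg[0])  # uniform root prior
    return np.exp(post)


def _argmax_random_ties(p: np.ndarray, rng: np.random.Generator) -> int:
    best = np.flatnonzero(p >= p.max() - 1e-15)
    return int(best[0] if len(best) == 1 else rng.choice(best))


def class_recovery_curve(
    grammar: HierarchyGrammar,
    processes: dict,
    t_grid,
    n_trials: int,
    seed=None,
) -> pd.DataFrame:
    """Fraction of trials in which the argmax BP posterior recovers the true
    root, per noising process and time.

    ``processes`` maps a name to either a params object or a dict with keys
    ``params`` and optional ``marginal`` (bool).  Each trial shares its datum
    across processes; noise draws are independent.  Returns a DataFrame with
    columns (t, process, fraction, se, n).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = grammar.params
    enc = LeafEncoding(v=p.v)
    norm = {}
    for name, spec in processes.items():
        if isinstance(spec, dict):
            norm[name] = (spec["params"], bool(spec.get("marginal", False)))
        else:
            norm[name] = (spec, False)
    rows = []
    for t in t_grid:
        hits = {name: 0 for name in norm}
        for _ in range(n_trials):
            root = int(rng.integers(p.v))
            leaves, _ = sample_datum(grammar, root, seed=rng)
            for name, (pp, marginal) in norm.items():
                obs = noise_leaves(leaves, enc, pp, t, seed=rng)
                if isinstance(pp, PassiveParams):
                    post = bp_root_posterior(obs, None, grammar, pp, t)
                else:
                    post = bp_root_posterior(
                        obs[0], obs[1], grammar, pp, t, marginal=marginal
                    )
                if _argmax_random_ties(post, rng) == root:
                    hits[name] += 1
        for name, h in hits.items():
            frac = h / n_trials
            rows.append(
                {
                    "t": t,
                    "process": name,
                    "fraction": frac,
                    "se": np.sqrt(max(frac * (1 - frac), 1e-12) / n_trials),
                    "n": n_trials,
                }
            )
    return pd.DataFrame(rows)


def marginal_vs_joint_recovery(
    grammar: HierarchyGrammar,
    params: ActiveParams,
    t_grid,
    n_trials: int,
    seed=None,
) -> pd.DataFrame:
    """Paired recovery fractions: joint (x, eta) vs x-marginal inference on
    identical noised draws.  Columns (t, mode, fraction, se, n)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = grammar.params
    enc = LeafEncoding(v=p.v)
    rows = []
    for t in t_grid:
        hits = {"joint": 0, "marginal": 0}
        for _ in range(n_trials):
            root = int(rng.integers(p.v))
            leaves, _ = sample_datum(grammar, root, seed=rng)
            x, eta = noise_leaves(leaves, enc, params, t, seed=rng)
            for mode, marginal in (("joint", False), ("marginal", True)):
                post = bp_root_posterior(x, eta, grammar, params, t, marginal=marginal)
                if _argmax_random_ties(post, rng) == root:
                    hits[mode] += 1
        for mode, h in hits.items():
            frac = h / n_trials
            rows.append(
                {
                    "t": t,
                    "mode": mode,
                    "fraction": frac,
                    "se": np.sqrt(max(frac * (1 - frac), 1e-12) / n_trials),
                    "n": n_trials,
                }
            )
    return pd.DataFrame(rows)
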