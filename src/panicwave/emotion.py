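"""Online layer: panic formation and pairwise emotion interaction.

Each agent i carries a panic value E_i(t) in [0, 1] formed from the global
needs and local buying pressure,

    E_i(t) = clamp(a * M(t) + b * S(t) + F_i(t), 0, 1),

where a > b are the Maslow-style weights of material (physiological) versus
safety need, and F_i = (NI_i / N_i) * Con(i) is the social influence: the
fraction of i's neighbors currently panic buying, scaled by i's conformity.

Panic then evolves through threshold-based pairwise interactions in the
spirit of bounded-confidence opinion dynamics with both assimilation and
repulsion: partners whose panic differs by less than d1 converge (step size
mu1), partners differing by more than d2 diverge (step size mu2, clamped to
[0, 1]), and pairs in the neutral band [d1, d2] are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SocialNetwork

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "NeedWeights",
    "InteractionParams",
    "EmotionState",
    "sample_conformity",
    "social_influence",
    "social_influence_all",
    "panic_value",
    "ja_interact",
    "interaction_round",
    "polarizability",
]


@dataclass(frozen=True)
class NeedWeights:
    """Weights of material (a) and safety (b) need; a + b = 1 and a > b."""

    a: float = 0.6
    b: float = 0.4

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("need weights must be positive")
        if abs(self.a + self.b - 1.0) > 1e-9:
            raise ValueError("need weights must satisfy a + b = 1")
        if not self.a > self.b:
            raise ValueError("material-need weight must exceed safety-need weight (a > b)")


@dataclass(frozen=True)
class InteractionParams:
    """Assimilation/repulsion step sizes and thresholds of the pairwise rule."""

    mu1: float = 0.2
    mu2: float = 0.2
    d1: float = 0.2
    d2: float = 0.6

    def __post_init__(self):
        if not (0.0 <= self.mu1 <= 0.5 and 0.0 <= self.mu2 <= 0.5):
            raise ValueError("step sizes mu1, mu2 must lie in [0, 0.5]")
        if not (0.0 <= self.d1 < self.d2 <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= d1 < d2 <= 1")


@dataclass
class EmotionState:
    """Per-agent panic values and conformity, both clamped to [0, 1]."""

    panic: np.ndarray
    conformity: np.ndarray

    def __post_init__(self):
        self.panic = np.asarray(self.panic, dtype=np.float64)
        self.conformity = np.asarray(self.conformity, dtype=np.float64)
        if self.panic.shape != self.conformity.shape:
            raise ValueError("panic and conformity must have the same length")
        for name, arr in (("panic", self.panic), ("conformity", self.conformity)):
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError(f"{name} values must lie in [0, 1]")


def sample_conformity(
    n: int,
    mean: float = 0.5,
    sd: float = 0.15,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Truncated-normal conformity: Normal(mean, sd) clamped to [0, 1]."""
    if n < 1:
        raise ValueError("need at least one agent")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return np.clip(gen.normal(mean, sd, size=n), 0.0, 1.0)


def social_influence_all(
    net: SocialNetwork, buying: np.ndarray, conformity: np.ndarray
) -> np.ndarray:
    """Vectorized F_i = (NI_i / N_i) * Con(i) for all agents.

    Isolated agents (degree 0) feel no social pressure and get F = 0.
    """
    buying = np.asarray(buying, dtype=np.float64)
    ni = net.adjacency @ buying
    deg = net.degrees
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(deg > 0, ni / np.maximum(deg, 1), 0.0)
    return frac * np.asarray(conformity, dtype=np.float64)


def social_influence(
    i: int, net: SocialNetwork, buying: np.ndarray, conformity: np.ndarray
) -> float:
    """Scalar social influence on agent ``i`` (reference form of F_i)."""
    nbrs = net.neighbors(i)
    if not nbrs:
        return 0.0
    buying = np.asarray(buying)
    ni = sum(bool(buying[j]) for j in nbrs)
    return ni / len(nbrs) * float(conformity[i])


def panic_value(M, S, F, weights: NeedWeights = NeedWeights()):
    """Panic E = clamp(a*M + b*S + F, 0, 1); scalar or elementwise."""
    return np.clip(weights.a * np.asarray(M) + weights.b * np.asarray(S) + np.asarray(F), 0.0, 1.0)


def ja_interact(
    ei: float, ej: float, p: InteractionParams = InteractionParams()
) -> tuple[float, float]:
    """One pairwise emotion interaction; both updates use pre-interaction values.

    Assimilation (|ei - ej| < d1) moves the pair together and conserves their
    sum; repulsion (|ei - ej| > d2) pushes them apart and is clamped to
    [0, 1]; the neutral band leaves both unchanged.
    """
    diff = ei - ej
    ad = abs(diff)
    if ad < p.d1:
        ni, nj = ei - p.mu1 * diff, ej + p.mu1 * diff
    elif ad > p.d2:
        ni, nj = ei + p.mu2 * diff, ej - p.mu2 * diff
    else:
        return float(ei), float(ej)
    return float(min(max(ni, 0.0), 1.0)), float(min(max(nj, 0.0), 1.0))


def _round_kernel_py(panic, u, v, mu1, mu2, d1, d2):
    for k in range(u.shape[0]):
        i = u[k]
        j = v[k]
        diff = panic[i] - panic[j]
        ad = abs(diff)
        if ad < d1:
            ni = panic[i] - mu1 * diff
            nj = panic[j] + mu1 * diff
        elif ad > d2:
            ni = panic[i] + mu2 * diff
            nj = panic[j] - mu2 * diff
        else:
            continue
        panic[i] = min(max(ni, 0.0), 1.0)
        panic[j] = min(max(nj, 0.0), 1.0)


_round_kernel = njit(cache=False)(_round_kernel_py) if njit is not None else _round_kernel_py


def interaction_round(
    net: SocialNetwork,
    panic: np.ndarray,
    p: InteractionParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One sweep of pairwise interactions over every edge of the network.

    Each edge fires exactly once per round, in a random order drawn from
    ``rng``; updates are asynchronous, i.e. visible to later edges in the
    same round.  Returns a new panic array; the input is not modified.
    """
    out = np.array(panic, dtype=np.float64, copy=True)
    n_edges = net.edge_count
    if n_edges == 0:
        return out
    order = rng.permutation(n_edges)
    u = np.ascontiguousarray(net.edges[order, 0])
    v = np.ascontiguousarray(net.edges[order, 1])
    _round_kernel(out, u, v, float(p.mu1), float(p.mu2), float(p.d1), float(p.d2))
    return out


def polarizability(panic: np.ndarray, threshold: float = 0.9) -> float:
    """Fraction of agents at or above the extreme-panic threshold."""
    panic = np.asarray(panic)
    if panic.size == 0:
        raise ValueError("polarizability of an empty population is undefined")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return float(np.mean(panic >= threshold))
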