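"""Model parameter bundles shared by the spread and experiments layers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .emotion import InteractionParams, NeedWeights

__all__ = ["ForgettingParams", "ModelParameters"]


@dataclass(frozen=True)
class ForgettingParams:
    """Forgetting-curve parameters of the recovery rate.

    The per-step probability that a panic buyer stops is
    ``beta(t1) = clamp(c1 - exp(-c2 * t1), 0, 1)`` where ``t1`` counts steps
    since adoption.  ``c1`` is the asymptotic forgetting level (``beta ->
    c1``); ``c2`` sets how fast the curve rises.  At adoption (``t1 = 0``)
    the rate is ``c1 - 1``, i.e. zero for ``c1 = 1``: fresh buyers do not
    quit immediately.
    """

    c1: float = 1.0
    c2: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.c1 <= 1.0:
            raise ValueError("c1 must lie in (0, 1]")
        if self.c2 <= 0:
            raise ValueError("c2 must be positive")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameterization of one simulation run.

    Defaults are the model's reference setting: need weights (0.6, 0.4),
    conformity ~ Normal(0.5, 0.15) truncated to [0, 1], 6% initially
    infected, interaction parameters mu1 = mu2 = 0.2, d1 = 0.2, d2 = 0.6,
    forgetting parameters c1 = 1, c2 = 0.01, and an extreme-panic threshold
    of 0.9 for the polarizability statistic.

    ``panic_update_mode``: with ``"recompute"`` (default) panic is reformed
    from needs and social influence every step before the interaction round;
    with ``"incremental"`` panic persists between steps and is reformed only
    at t = 0 and when the information schedule changes.
    """

    need_weights: NeedWeights = field(default_factory=NeedWeights)
    interaction: InteractionParams = field(default_factory=InteractionParams)
    forgetting: ForgettingParams = field(default_factory=ForgettingParams)
    conformity_mean: float = 0.5
    conformity_sd: float = 0.15
    initial_infected_fraction: float = 0.06
    horizon: int = 60
    replications: int = 100
    panic_update_mode: str = "recompute"
    polarizability_threshold: float = 0.9

    def __post_init__(self):
        if not 0.0 <= self.initial_infected_fraction <= 1.0:
            raise ValueError("initial_infected_fraction must lie in [0, 1]")
        if self.horizon < 0:
            raise ValueError("horizon must be nonnegative")
        if self.replications < 1:
            raise ValueError("need at least one replication")
        if self.panic_update_mode not in ("recompute", "incremental"):
            raise ValueError("panic_update_mode must be 'recompute' or 'incremental'")
        if not 0.0 <= self.polarizability_threshold <= 1.0:
            raise ValueError("polarizability_threshold must lie in [0, 1]")
        if self.conformity_sd < 0:
            raise ValueError("conformity_sd must be nonnegative")
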