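"""Offline layer: the S -> I -> R -> S panic-buying state machine.

Agents are Susceptible (not buying but receptive), Infected (currently panic
buying) or Recovered (desensitized).  Per step, synchronously:

* S -> I with probability alpha_i = th1 * (a*M + b*(1-S)) + th2 * E_i, where
  th1 = |1 - E_i| and th2 = |E_i|: the more panicked an agent, the more its
  behavior is driven by emotion rather than by a sober reading of needs.
* I -> R with probability beta(t1) = clamp(c1 - exp(-c2 * t1), 0, 1), a
  forgetting curve in the time t1 since adoption.
* R -> S with probability gamma, nonzero only on steps where the global
  material need rises or the safety need falls (fresh alarming information
  re-sensitizes desensitized agents); then gamma = (M + (1 - S)) / 2.

Infection is a spontaneous per-agent Bernoulli rather than a per-contact
event: social exposure already enters alpha through the panic value E_i,
which contains the neighborhood buying pressure F_i, and media-driven buying
does not require an infected contact.

A mean-field companion integrates the model's aggregate rate equations
(with their bilinear recovery beta*I*R and recurrence gamma*R*S terms kept
verbatim, which is nonstandard relative to textbook SIR) purely as a
diagnostic; the agent-based process is the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emotion import (
    NeedWeights,
    interaction_round,
    panic_value,
    polarizability,
    sample_conformity,
    social_influence_all,
)
from .information import InformationSchedule, material_need, safety_need
from .network import ConfigurationError, SocialNetwork
from .parameters import ForgettingParams, ModelParameters

__all__ = [
    "S",
    "I",
    "R",
    "CompartmentState",
    "ForgettingParams",
    "SimulationResult",
    "infection_rate",
    "recovery_rate",
    "recurrence_rate",
    "transition_step",
    "simulate",
    "meanfield_reference",
]

S, I, R = 0, 1, 2

RESULT_COLUMNS = [
    "step",
    "NS",
    "NI",
    "NR",
    "PS",
    "PI",
    "PR",
    "polarizability",
    "mean_panic",
]


@dataclass
class CompartmentState:
    """Per-agent compartment labels plus time-since-adoption bookkeeping.

    ``compartment`` holds S/I/R codes; ``t1`` counts whole steps since the
    agent entered I (0 at the infection step itself, meaningful only while
    infected).
    """

    compartment: np.ndarray
    t1: np.ndarray

    def __post_init__(self):
        self.compartment = np.asarray(self.compartment, dtype=np.int8)
        self.t1 = np.asarray(self.t1, dtype=np.int64)
        if self.compartment.shape != self.t1.shape:
            raise ValueError("compartment and t1 must have the same length")
        if self.compartment.size and not np.isin(self.compartment, (S, I, R)).all():
            raise ValueError("compartment labels must be S, I or R")

    @classmethod
    def initial(
        cls, n: int, infected_fraction: float, rng: np.random.Generator
    ) -> "CompartmentState":
        """All susceptible except ``round(fraction * n)`` uniform infected."""
        n_inf = int(round(infected_fraction * n))
        comp = np.full(n, S, dtype=np.int8)
        if n_inf:
            comp[rng.choice(n, size=n_inf, replace=False)] = I
        return cls(comp, np.zeros(n, dtype=np.int64))

    def counts(self) -> tuple[int, int, int]:
        return (
            int(np.count_nonzero(self.compartment == S)),
            int(np.count_nonzero(self.compartment == I)),
            int(np.count_nonzero(self.compartment == R)),
        )


def infection_rate(M, Sv, E, w: NeedWeights = NeedWeights()):
    """Per-step S -> I probability alpha; scalar or elementwise in E.

    th1 = |1 - E| weighs the needs term a*M + b*(1 - Sv) (high material need
    and a *safe* environment both favor going out to buy); th2 = |E| weighs
    raw panic.  For inputs in [0, 1] the result is a convex combination and
    stays in [0, 1].
    """
    E = np.asarray(E, dtype=np.float64)
    th1 = np.abs(1.0 - E)
    th2 = np.abs(E)
    return th1 * (w.a * np.asarray(M) + w.b * (1.0 - np.asarray(Sv))) + th2 * E


def recovery_rate(t1, f: ForgettingParams = ForgettingParams()):
    """Forgetting-curve I -> R probability beta(t1); nondecreasing in t1."""
    t1 = np.asarray(t1, dtype=np.float64)
    if np.any(t1 < 0):
        raise ValueError("t1 must be nonnegative")
    return np.clip(f.c1 - np.exp(-f.c2 * t1), 0.0, 1.0)


def recurrence_rate(M_now: float, M_prev: float, S_now: float, S_prev: float) -> float:
    """R -> S probability gamma, triggered by need increases only."""
    if M_now > M_prev or S_now < S_prev:
        return (M_now + (1.0 - S_now)) / 2.0
    return 0.0


def transition_step(
    state: CompartmentState,
    alpha,
    beta,
    gamma: float,
    rng: np.random.Generator,
) -> CompartmentState:
    """One synchronous compartment update from start-of-step labels.

    ``alpha``/``beta`` may be scalars or per-agent arrays; ``gamma`` is
    global.  Every agent draws one uniform; all transitions are evaluated
    against the pre-step compartments, so the update order within a step
    cannot matter.
    """
    comp = state.compartment
    n = comp.shape[0]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=np.float64), (n,))
    beta = np.broadcast_to(np.asarray(beta, dtype=np.float64), (n,))
    u = rng.random(n)

    new_comp = comp.copy()
    s_to_i = (comp == S) & (u < alpha)
    i_to_r = (comp == I) & (u < beta)
    r_to_s = (comp == R) & (u < gamma)
    new_comp[s_to_i] = I
    new_comp[i_to_r] = R
    new_comp[r_to_s] = S

    new_t1 = state.t1.copy()
    new_t1[(comp == I) & (new_comp == I)] += 1
    new_t1[s_to_i] = 0
    return CompartmentState(new_comp, new_t1)


@dataclass
class SimulationResult:
    """Per-step trajectory of one run: counts, proportions, emotion summaries.

    ``frame`` has one row per recorded step (t = 0 .. horizon) with columns
    ``step, NS, NI, NR, PS, PI, PR, polarizability, mean_panic``.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = set(RESULT_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"result frame missing columns: {sorted(missing)}")

    @property
    def ni(self) -> np.ndarray:
        return self.frame["NI"].to_numpy()

    @property
    def nr(self) -> np.ndarray:
        return self.frame["NR"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _expand_seed(seed) -> list[np.random.Generator]:
    """One run seed -> independent (conformity, initial-infected, dynamics) RNGs."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(3)]


def simulate(
    net: SocialNetwork,
    schedule: InformationSchedule,
    params: ModelParameters = ModelParameters(),
    seed: int | np.random.SeedSequence | None = None,
) -> SimulationResult:
    """Run the coupled emotion/behavior dynamics on ``net``.

    Per step t: read the information point and form global needs; compute
    social influence and panic (per ``params.panic_update_mode``); run one
    pairwise interaction round; record the step row; then (for t < horizon)
    compute the transition rates and apply one synchronous compartment
    update.  Rows therefore describe the state *before* that step's
    transition, and the result has ``horizon + 1`` rows.
    """
    if params.horizon < 0:
        raise ConfigurationError("horizon must be nonnegative")
    n = net.node_count
    rng_con, rng_init, rng_dyn = _expand_seed(seed)
    conformity = sample_conformity(
        n, params.conformity_mean, params.conformity_sd, rng=rng_con
    )
    state = CompartmentState.initial(n, params.initial_infected_fraction, rng_init)

    w = params.need_weights
    rows = []
    prev_needs: tuple[float, float] | None = None
    panic: np.ndarray | None = None

    for t in range(params.horizon + 1):
        point = schedule.at(t)
        M = material_need(point)
        Sv = safety_need(point)
        buying = state.compartment == I
        influence = social_influence_all(net, buying, conformity)
        needs_changed = prev_needs is None or (M, Sv) != prev_needs
        if params.panic_update_mode == "recompute" or panic is None or needs_changed:
            panic = panic_value(M, Sv, influence, w)
        panic = interaction_round(net, panic, params.interaction, rng_dyn)

        ns, ni, nr = state.counts()
        rows.append(
            (
                t,
                ns,
                ni,
                nr,
                ns / n,
                ni / n,
                nr / n,
                polarizability(panic, params.polarizability_threshold),
                float(panic.mean()),
            )
        )
        if t == params.horizon:
            break

        alpha = infection_rate(M, Sv, panic, w)
        beta = recovery_rate(state.t1, params.forgetting)
        if prev_needs is None:
            gamma = 0.0
        else:
            gamma = recurrence_rate(M, prev_needs[0], Sv, prev_needs[1])
        state = transition_step(state, alpha, beta, gamma, rng_dyn)
        prev_needs = (M, Sv)

    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return SimulationResult(frame)


def meanfield_reference(
    alpha: float,
    beta: float,
    gamma: float,
    S0: float,
    I0: float,
    R0: float,
    horizon: float,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Fixed-step RK4 integration of the aggregate rate equations.

    dS/dt = gamma*R*S - alpha*S*I, dI/dt = alpha*S*I - beta*I*R,
    dR/dt = beta*I*R - gamma*R*S, integrated verbatim (the bilinear
    recovery/recurrence terms are nonstandard; this is a constant-rate
    diagnostic, not the simulator).  S + I + R is conserved identically by
    the right-hand side.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if abs(S0 + I0 + R0 - 1.0) > 1e-9:
        raise ValueError("initial proportions must sum to 1")

    def rhs(y):
        s, i, r = y
        ds = gamma * r * s - alpha * s * i
        di = alpha * s * i - beta * i * r
        dr = beta * i * r - gamma * r * s
        return np.array([ds, di, dr])

    steps = int(round(horizon / dt))
    y = np.array([S0, I0, R0], dtype=np.float64)
    out = [(0.0, *y)]
    for k in range(steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(((k + 1) * dt, *y))
    return pd.DataFrame(out, columns=["t", "S", "I", "R"])
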