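import numpy as np
import pytest
from scipy import stats

from panicwave import (
    CompartmentState,
    ForgettingParams,
    InformationPoint,
    InformationSchedule,
    ModelParameters,
    NeedWeights,
    generate_ba_network,
    infection_rate,
    meanfield_reference,
    recovery_rate,
    recurrence_rate,
    simulate,
    transition_step,
)
from panicwave.spread import I, R, S


# -- transition rates ----------------------------------------------------


def test_infection_rate_examples():
    w = NeedWeights(0.6, 0.4)
    assert infection_rate(0.5, 0.5, 1.0, w) == pytest.approx(1.0)  # pure panic
    assert infection_rate(0.0, 1.0, 0.0, w) == pytest.approx(0.0)
    assert infection_rate(1.0, 0.0, 0.0, w) == pytest.approx(1.0)


def test_infection_rate_weights_sum_to_one_and_bounded():
    E = np.linspace(0, 1, 21)
    th1, th2 = np.abs(1 - E), np.abs(E)
    assert np.allclose(th1 + th2, 1.0)
    for M in (0.0, 0.3, 1.0):
        for Sv in (0.0, 0.7, 1.0):
            alpha = infection_rate(M, Sv, E)
            assert (alpha >= 0).all() and (alpha <= 1).all()


def test_recovery_rate_forgetting_curve():
    f = ForgettingParams(c1=1.0, c2=0.01)
    assert recovery_rate(0, f) == 0.0  # fresh buyers never quit instantly
    assert recovery_rate(100, f) == pytest.approx(1 - np.exp(-1))
    assert recovery_rate(10**6, f) == pytest.approx(1.0)
    t1 = np.arange(0, 500)
    beta = recovery_rate(t1, f)
    assert (np.diff(beta) >= 0).all()
    assert (beta >= 0).all() and (beta <= 1).all()
    with pytest.raises(ValueError):
        recovery_rate(-1, f)


def test_recurrence_rate_cases():
    assert recurrence_rate(0.5, 0.5, 0.5, 0.5) == 0.0  # static needs
    assert recurrence_rate(0.8, 0.5, 0.3, 0.3) == pytest.approx(0.75)
    assert recurrence_rate(0.0, 0.0, 1.0, 1.1) == pytest.approx(0.0)  # boundary
    assert recurrence_rate(0.2, 0.3, 0.5, 0.5) == 0.0  # need fell: no trigger


def test_forgetting_params_validation():
    with pytest.raises(ValueError):
        ForgettingParams(c1=0.0)
    with pytest.raises(ValueError):
        ForgettingParams(c2=-0.1)


# -- synchronous transitions ---------------------------------------------


def test_all_zero_rates_absorbing(rng):
    state = CompartmentState(np.array([S, I, R]), np.array([0, 4, 0]))
    new = transition_step(state, 0.0, 0.0, 0.0, rng)
    assert np.array_equal(new.compartment, state.compartment)
    assert new.t1[1] == 5  # time-infected keeps ticking while in I


def test_certain_infection(rng):
    state = CompartmentState(np.full(100, S), np.zeros(100))
    new = transition_step(state, 1.0, 0.0, 0.0, rng)
    assert (new.compartment == I).all()
    assert (new.t1 == 0).all()  # reset at adoption


def test_t1_bookkeeping_over_cycle(rng):
    state = CompartmentState(np.array([I]), np.array([7]))
    state = transition_step(state, 0.0, 1.0, 0.0, rng)  # I -> R
    assert state.compartment[0] == R
    state = transition_step(state, 0.0, 0.0, 1.0, rng)  # R -> S
    state = transition_step(state, 1.0, 0.0, 0.0, rng)  # S -> I, t1 restarts
    assert state.compartment[0] == I and state.t1[0] == 0


def test_new_infections_match_binomial_oracle():
    rng = np.random.default_rng(2024)
    counts = []
    for _ in range(200):
        state = CompartmentState(np.full(1000, S), np.zeros(1000))
        new = transition_step(state, 0.3, 0.0, 0.0, rng)
        counts.append(int((new.compartment == I).sum()))
    sigma = np.sqrt(1000 * 0.3 * 0.7)
    assert abs(np.mean(counts) - 300) < 3 * sigma


def test_three_agent_outcomes_match_exact_enumeration():
    """One synchronous step is three independent Bernoulli trials."""
    alpha, beta, gamma = 0.3, 0.4, 0.5
    rng = np.random.default_rng(99)
    observed = np.zeros(8)
    reps = 10_000
    for _ in range(reps):
        state = CompartmentState(np.array([S, I, R]), np.zeros(3))
        new = transition_step(
            state, np.array([alpha, 0, 0]), np.array([0, beta, 0]), gamma, rng
        )
        code = (
            (new.compartment[0] == I)
            + 2 * (new.compartment[1] == R)
            + 4 * (new.compartment[2] == S)
        )
        observed[code] += 1
    expected = np.array(
        [
            (pa * pb * pg)
            for pg in (1 - gamma, gamma)
            for pb in (1 - beta, beta)
            for pa in (1 - alpha, alpha)
        ]
    )
    chi2 = stats.chisquare(observed, expected * reps)
    assert chi2.pvalue > 1e-3


# -- full simulation -----------------------------------------------------


def test_horizon_zero_records_only_initial_row():
    net = generate_ba_network(1000, 3, seed=0)
    params = ModelParameters(horizon=0, replications=1)
    res = simulate(net, InformationSchedule.constant(InformationPoint(im_neg=1)), params, seed=0)
    assert len(res.frame) == 1
    assert res.frame["NI"].iloc[0] == round(0.06 * 1000)


def test_conservation_every_step():
    net = generate_ba_network(300, 3, seed=1)
    params = ModelParameters(horizon=40, replications=1)
    res = simulate(net, InformationSchedule.constant(InformationPoint(im_neg=0.8)), params, seed=3)
    frame = res.frame
    assert (frame["NS"] + frame["NI"] + frame["NR"] == 300).all()
    assert np.allclose(frame["PS"] + frame["PI"] + frame["PR"], 1.0)


def test_static_needs_eventually_absorb_all_buyers():
    """With an unchanging signal, forgetting extinguishes panic buying."""
    params = ModelParameters(horizon=70, replications=1)
    sched = InformationSchedule.constant(InformationPoint(im_neg=0.6, is_neg=0.6))
    for seed in range(3):
        net = generate_ba_network(200, 3, seed=seed)
        res = simulate(net, sched, params, seed=seed)
        assert res.frame["NI"].iloc[-1] == 0


def test_simulation_is_deterministic_given_seed():
    net = generate_ba_network(200, 3, seed=4)
    sched = InformationSchedule.constant(InformationPoint(im_neg=0.5, is_neg=0.5))
    params = ModelParameters(horizon=20, replications=1)
    a = simulate(net, sched, params, seed=11)
    b = simulate(net, sched, params, seed=11)
    assert a.frame.equals(b.frame)


def test_incremental_mode_runs_and_conserves():
    net = generate_ba_network(150, 3, seed=2)
    params = ModelParameters(horizon=15, replications=1, panic_update_mode="incremental")
    sched = InformationSchedule(
        ((0, InformationPoint(im_neg=0.8)), (5, InformationPoint(im_pos=0.8)))
    )
    res = simulate(net, sched, params, seed=0)
    frame = res.frame
    assert (frame["NS"] + frame["NI"] + frame["NR"] == 150).all()
    assert frame["mean_panic"].between(0, 1).all()


# -- mean-field diagnostic ----------------------------------------------


def test_meanfield_constant_cases():
    out = meanfield_reference(0.0, 0.0, 0.0, 0.5, 0.3, 0.2, horizon=5)
    assert np.allclose(out[["S", "I", "R"]].iloc[-1], [0.5, 0.3, 0.2])
    out = meanfield_reference(0.9, 0.3, 0.0, 0.9, 0.0, 0.1, horizon=5)
    # no infected and no recurrence: nothing moves
    assert np.allclose(out[["S", "I", "R"]].iloc[-1], [0.9, 0.0, 0.1])


def test_meanfield_conserves_total():
    out = meanfield_reference(0.8, 0.3, 0.2, 0.94, 0.06, 0.0, horizon=20, dt=0.01)
    total = out[["S", "I", "R"]].sum(axis=1)
    assert np.abs(total - 1.0).max() < 1e-6
    with pytest.raises(ValueError):
        meanfield_reference(0.1, 0.1, 0.1, 1.0, 0.0, 0.0, horizon=1, dt=0.0)
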