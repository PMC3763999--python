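"""Unit and property tests for the reaction-diffusion core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phototax as px
from phototax.core_model import ConfigError, DomainError, StabilityError


# ---------------------------------------------------------------------------
# mobility / eps_rate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "S, expected",
    [(0.0, 0.0), (1.0, 0.5), (1e6, 1.0 - 1e-6)],
)
def test_mobility_saturating_form(S, expected):
    assert px.mobility(S) == pytest.approx(expected, rel=1e-9)


def test_mobility_rejects_negative_eps():
    with pytest.raises(DomainError):
        px.mobility(np.array([0.1, -0.2]))


def test_mobility_monotone_bounded():
    S = np.linspace(0, 100, 1000)
    M = px.mobility(S)
    assert np.all(np.diff(M) >= 0)
    assert np.all((M >= 0) & (M < 1))


def test_eps_rate_production_and_decay():
    C = np.full((4, 4), 0.5)
    assert np.allclose(px.eps_rate(C, np.zeros((4, 4))), 0.5)
    # steady state S = C * tau
    assert np.allclose(px.eps_rate(C, np.full((4, 4), 1.0), tau=2.0), 0.0)
    # pure exponential decay without cells
    out = px.eps_rate(np.zeros((4, 4)), np.full((4, 4), 3.0), tau=1.0)
    assert np.allclose(out, -3.0)


def test_eps_rate_rejects_bad_tau():
    C = np.zeros((3, 3))
    with pytest.raises(ConfigError):
        px.eps_rate(C, C, tau=-1.0)


# ---------------------------------------------------------------------------
# cell_rate: conservation, trivial cases, 1D oracle
# ---------------------------------------------------------------------------

def test_cell_rate_zero_for_uniform_unbiased(small_grid):
    C = np.full(small_grid.shape, 0.7)
    S = np.full(small_grid.shape, 1.3)
    rate = px.cell_rate(C, S, (0.0, 0.0), small_grid)
    assert np.allclose(rate, 0.0, atol=1e-14)


def test_cell_rate_conserves_mass_for_arbitrary_fields(small_grid):
    rng = np.random.default_rng(3)
    C = rng.uniform(0, 2, small_grid.shape)
    S = rng.uniform(0, 3, small_grid.shape)
    for bvec in [(0.0, 2.0), (1.5, -0.5), (-2.0, 0.0)]:
        rate = px.cell_rate(C, S, bvec, small_grid)
        total = rate.sum() * small_grid.cell_area
        scale = np.abs(rate).sum() * small_grid.cell_area
        assert abs(total) <= 1e-12 * max(scale, 1.0)


def oracle_rate_1d(C, S, beta, dx):
    """Independent 1D finite-volume rate with zero-flux ends.

    Written as an explicit per-face loop: diffusive flux with the mean
    face mobility plus upwind advection of M*C toward +y.
    """
    n = len(C)
    M = S / (1.0 + S)
    J = np.zeros(n + 1)
    for i in range(1, n):
        Mf = 0.5 * (M[i - 1] + M[i])
        J[i] = -Mf * (C[i] - C[i - 1]) / dx
        if beta > 0:
            J[i] += beta * M[i - 1] * C[i - 1]
        elif beta < 0:
            J[i] += beta * M[i] * C[i]
    return -(J[1:] - J[:-1]) / dx


def test_cell_rate_matches_1d_oracle_on_x_invariant_fields(small_grid):
    rng = np.random.default_rng(11)
    col_C = rng.uniform(0, 1, small_grid.ny)
    col_S = rng.uniform(0, 2, small_grid.ny)
    C = np.tile(col_C[:, None], (1, small_grid.nx))
    S = np.tile(col_S[:, None], (1, small_grid.nx))
    rate2d = px.cell_rate(C, S, (0.0, 2.0), small_grid)
    expected = oracle_rate_1d(col_C, col_S, 2.0, small_grid.dx)
    for col in range(small_grid.nx):
        np.testing.assert_allclose(rate2d[:, col], expected, rtol=1e-10, atol=1e-14)


def test_simulate_matches_1d_oracle_at_t10(small_grid):
    """x-invariant initial conditions stay x-invariant and follow the 1D system."""
    rng = np.random.default_rng(4)
    col_C = rng.uniform(0.1, 0.8, small_grid.ny)
    C0 = np.tile(col_C[:, None], (1, small_grid.nx))
    params = px.ModelParams(cbar=0.5, beta=1.5)
    dt = 0.01
    res = px.simulate(params, small_grid, C0, t_end=10.0, dt=dt, early_stop=False)
    # independent brute-force forward Euler of the 1D reduction
    c = col_C.copy()
    s = np.zeros_like(c)
    for _ in range(1000):
        dc = oracle_rate_1d(c, s, 1.5, small_grid.dx)
        s = s + dt * c
        c = c + dt * dc
    final = res.final
    assert final.t == pytest.approx(10.0)
    for col in range(small_grid.nx):
        np.testing.assert_allclose(final.C[:, col], c, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(final.S[:, col], s, rtol=1e-8, atol=1e-12)


def test_cell_rate_rejects_non_finite(small_grid):
    C = np.ones(small_grid.shape)
    C[0, 0] = np.nan
    with pytest.raises(StabilityError):
        px.cell_rate(C, np.ones(small_grid.shape), (0, 1), small_grid)


# ---------------------------------------------------------------------------
# step / simulate
# ---------------------------------------------------------------------------

def test_uniform_field_closed_form(small_grid):
    """Uniform C with beta=0: S(n dt) = C * n * dt exactly, C unchanged."""
    params = px.ModelParams(cbar=0.5, beta=0.0)
    state = px.FieldState(np.full(small_grid.shape, 0.5), np.zeros(small_grid.shape), 0.0)
    for _ in range(100):
        state = px.step(state, params, small_grid, dt=0.01)
    assert np.allclose(state.C, 0.5, rtol=0, atol=0)
    # forward sums of 0.5*0.01 accumulate exactly in binary here
    assert np.allclose(state.S, 0.5, rtol=1e-12)


def test_uniform_decay_approaches_steady_state(small_grid):
    """With decay, uniform S follows the Euler recursion toward C*tau."""
    tau, c, dt = 2.0, 0.5, 0.01
    params = px.ModelParams(cbar=c, beta=0.0, tau=tau)
    state = px.FieldState(np.full(small_grid.shape, c), np.zeros(small_grid.shape), 0.0)
    n = 4000
    for _ in range(n):
        state = px.step(state, params, small_grid, dt=dt)
    expected = c * tau * (1.0 - (1.0 - dt / tau) ** n)
    assert np.allclose(state.S, expected, rtol=1e-10)
    assert abs(state.S.max() - c * tau) <= dt * c / 2 + c * tau * (1 - dt / tau) ** n


def test_mass_conserved_over_fingering_run(small_fingering_run, small_grid):
    m0 = px.total_mass(small_fingering_run.initial.C, small_grid)
    for snap in small_fingering_run.snapshots:
        m = px.total_mass(snap.C, small_grid)
        assert abs(m - m0) / m0 <= 1e-10


def test_positivity_every_snapshot(small_fingering_run):
    for snap in small_fingering_run.snapshots:
        assert snap.C.min() >= 0
        assert snap.S.min() >= 0


def test_eps_monotone_without_decay(small_fingering_run):
    prev = small_fingering_run.snapshots[0].S
    for snap in small_fingering_run.snapshots[1:]:
        assert np.all(snap.S >= prev - 1e-12)
        prev = snap.S


def test_mirror_symmetry_commutes_with_simulation(small_grid):
    rng = np.random.default_rng(9)
    C0 = np.zeros(small_grid.shape)
    C0[:12, :] = rng.uniform(0, 1, (12, small_grid.nx))
    params = px.ModelParams(cbar=0.5, beta=2.0)
    res = px.simulate(params, small_grid, C0, t_end=5.0, dt=0.01, early_stop=False)
    res_m = px.simulate(params, small_grid, C0[:, ::-1], t_end=5.0, dt=0.01, early_stop=False)
    np.testing.assert_array_equal(res.final.C[:, ::-1], res_m.final.C)
    np.testing.assert_array_equal(res.final.S[:, ::-1], res_m.final.S)


def test_step_matches_kernel_sequence(small_grid):
    """The numpy reference stepper and the fused kernel agree step for step."""
    rng = np.random.default_rng(2)
    C0 = np.zeros(small_grid.shape)
    C0[:12, :] = rng.uniform(0, 1, (12, small_grid.nx))
    params = px.ModelParams(cbar=0.5, beta=2.0, tau=5.0)
    n, dt = 200, 0.005
    state = px.FieldState(C0.copy(), np.zeros(small_grid.shape), 0.0)
    for _ in range(n):
        state = px.step(state, params, small_grid, dt=dt)
    res = px.simulate(
        params, small_grid, C0, t_end=n * dt, dt=dt, stride=n * dt, early_stop=False
    )
    np.testing.assert_allclose(res.final.C, state.C, rtol=1e-13, atol=1e-15)
    np.testing.assert_allclose(res.final.S, state.S, rtol=1e-13, atol=1e-15)


def test_step_instability_raises(small_grid):
    rng = np.random.default_rng(0)
    state = px.FieldState(
        rng.uniform(0, 5, small_grid.shape), rng.uniform(0, 50, small_grid.shape), 0.0
    )
    params = px.ModelParams(cbar=1.0, beta=0.0)
    with pytest.raises(StabilityError):
        s = state
        for _ in range(200):  # dt far above the diffusive limit blows up
            s = px.step(s, params, small_grid, dt=0.5)


def test_simulate_bit_identical_reruns(small_grid, fingering_params):
    C0, mask = px.make_deposition(small_grid, px.DepositionSpec(cbar=0.5, seed=3))
    kwargs = dict(t_end=4.0, dt=0.01, deposition_mask=mask, seed=3, early_stop=False)
    a = px.simulate(fingering_params, small_grid, C0, **kwargs)
    b = px.simulate(fingering_params, small_grid, C0, **kwargs)
    assert len(a.snapshots) == len(b.snapshots)
    for sa, sb in zip(a.snapshots, b.snapshots):
        np.testing.assert_array_equal(sa.C, sb.C)
        np.testing.assert_array_equal(sa.S, sb.S)


def test_simulate_snapshot_times_and_validation(small_grid, fingering_params):
    C0 = np.zeros(small_grid.shape)
    C0[:10, :] = 0.5
    res = px.simulate(
        fingering_params, small_grid, C0, t_end=3.0, dt=0.01, stride=1.0, early_stop=False
    )
    np.testing.assert_allclose(res.times, [0, 1, 2, 3], atol=1e-9)
    with pytest.raises(ConfigError):
        px.simulate(fingering_params, small_grid, C0, t_end=-1.0)
    with pytest.raises(DomainError):
        px.simulate(fingering_params, small_grid, -C0 - 1.0)


def test_bias_schedule_validation_and_lookup():
    sched = px.BiasSchedule(((0.0, (0.0, 1.0)), (5.0, (1.0, 0.0))))
    assert sched.direction_at(0.0) == (0.0, 1.0)
    assert sched.direction_at(4.99) == (0.0, 1.0)
    assert sched.direction_at(5.0) == (1.0, 0.0)
    with pytest.raises(ConfigError):
        px.BiasSchedule(((1.0, (0.0, 1.0)),))  # must start at t=0
    with pytest.raises(ConfigError):
        px.BiasSchedule(((0.0, (0.0, 2.0)),))  # not a unit vector
    with pytest.raises(ConfigError):
        px.BiasSchedule(((0.0, (0.0, 1.0)), (0.0, (1.0, 0.0))))  # not increasing


# ---------------------------------------------------------------------------
# total_mass / stability_limit / unit conversion
# ---------------------------------------------------------------------------

def test_total_mass_uniform_and_zero(small_grid):
    c0 = 0.3
    assert px.total_mass(np.full(small_grid.shape, c0), small_grid) == pytest.approx(
        c0 * small_grid.nx * small_grid.ny * small_grid.cell_area
    )
    assert px.total_mass(np.zeros(small_grid.shape), small_grid) == 0.0


def test_total_mass_of_reference_deposition():
    """Random deposition over the bottom 20% of the full grid: expectation
    cbar * nx * (0.2 ny) * dx^2 = 1620 at cbar=0.5, within sampling error."""
    grid = px.GridSpec()  # 360 x 720, dx=0.25
    C0, _ = px.make_deposition(grid, px.DepositionSpec(cbar=0.5, seed=123))
    assert px.total_mass(C0, grid) == pytest.approx(1620.0, rel=0.02)


@pytest.mark.parametrize(
    "beta, dx, expected",
    [(2.0, 0.25, 0.0078125), (0.0, 0.25, 0.0078125), (0.0, 1.0, 0.125)],
)
def test_stability_limit_formula(beta, dx, expected):
    params = px.ModelParams(cbar=0.5, beta=beta)
    grid = px.GridSpec(nx=8, ny=8, dx=dx)
    assert px.stability_limit(params, grid) == pytest.approx(expected)


def test_unit_conversion_round_trip_and_reference_scale():
    scales = px.PhysicalScales(m0=4.0, ks=2.0, sigma=1.5)
    assert scales.length == pytest.approx(math.sqrt(2.0))
    for kind in ("length", "time", "concentration", "speed"):
        x = 3.7
        assert px.from_physical(px.to_physical(x, kind, scales), kind, scales) == pytest.approx(x)
    # T = 2000 s makes 300 natural time units one 600,000 s experiment
    ref = px.PhysicalScales(m0=1.0, ks=1.0 / 2000.0, sigma=1.0)
    assert px.to_physical(300.0, "time", ref) == pytest.approx(600_000.0)
    # lambda = 1 when m0 == ks
    assert px.to_physical(1.0, "length", px.PhysicalScales(3.0, 3.0, 1.0)) == pytest.approx(1.0)
    with pytest.raises(ConfigError):
        px.to_physical(1.0, "volume", scales)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    beta=st.floats(0.0, 4.0),
    c_hi=st.floats(0.1, 2.0),
)
def test_rate_conservation_property(seed, beta, c_hi):
    """Domain-summed cell rate vanishes for any admissible fields and bias."""
    grid = px.GridSpec(nx=12, ny=16, dx=0.5)
    rng = np.random.default_rng(seed)
    C = rng.uniform(0, c_hi, grid.shape)
    S = rng.uniform(0, 3, grid.shape)
    angle = rng.uniform(0, 2 * np.pi)
    rate = px.cell_rate(C, S, (beta * np.cos(angle), beta * np.sin(angle)), grid)
    scale = np.abs(rate).sum() + 1.0
    assert abs(rate.sum()) / scale <= 1e-12


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_step_preserves_positivity_property(seed):
    """At the recommended dt, forward Euler never goes negative."""
    grid = px.GridSpec(nx=10, ny=12, dx=0.25)
    params = px.ModelParams(cbar=1.0, beta=3.0)
    rng = np.random.default_rng(seed)
    state = px.FieldState(rng.uniform(0, 2, grid.shape), rng.uniform(0, 4, grid.shape), 0.0)
    dt = px.stability_limit(params, grid)
    for _ in range(50):
        state = px.step(state, params, grid, dt=dt)
    assert state.C.min() >= 0
    assert state.S.min() >= 0
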