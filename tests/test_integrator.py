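"""Brownian-dynamics engine: noise scaling, deterministic drift,
Einstein diffusion, Boltzmann sampling, finite-extensibility rejection,
reproducibility."""

import numpy as np
import pytest

from npcbd import fixtures, forcefield, units
from npcbd.integrator import (IntegratorConfig, SimState, bd_step,
                              brownian_displacement, equilibrate,
                              ottinger_reject, run_simulation, _run_chunks)


def _flat(structure, **kw):
    return forcefield.flatten(structure, **kw)


# ---------------------------------------------------------------------------
# noise term
# ---------------------------------------------------------------------------

def test_brownian_displacement_variance_and_mean():
    """D = 50 um^2/s over one 0.1 ns step: per-component variance
    0.01 nm^2 (std 0.1 nm); mean zero within 4 standard errors."""
    rng = np.random.default_rng(0)
    draws = np.array([brownian_displacement(50.0, 1.0, rng) for _ in range(20000)])
    var = draws.var(axis=0)
    assert np.allclose(var, 0.01, rtol=0.05)
    se = np.sqrt(0.01 / len(draws))
    assert np.abs(draws.mean(axis=0)).max() < 4 * se


def test_brownian_displacement_replays_with_fixed_seed():
    a = brownian_displacement(50.0, 1.0, np.random.default_rng(42))
    b = brownian_displacement(50.0, 1.0, np.random.default_rng(42))
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# single steps
# ---------------------------------------------------------------------------

def test_zero_force_no_noise_leaves_positions_unchanged():
    s = fixtures.free_bead(3)
    fs = _flat(s)
    state = SimState(0, fs.positions.copy())
    out = bd_step(state, np.zeros_like(fs.positions), fs,
                  IntegratorConfig(dt=1.0), noise=False)
    assert np.array_equal(out.positions, fs.positions)
    assert out.step == 1


def test_constant_force_gives_exact_drift():
    """Displacement is exactly F * D * dt / kT per component."""
    s = fixtures.free_bead(1, radius=0.9)
    fs = _flat(s)
    F = np.array([[2.0, -1.0]])
    cfg = IntegratorConfig(dt=2.0)
    state = SimState(0, fs.positions.copy())
    out = bd_step(state, F, fs, cfg, noise=False)
    expected = fs.positions + F * fs.D_red[:, None] * cfg.dt
    assert np.allclose(out.positions, expected, atol=1e-14)


def test_immobile_beads_never_move():
    s = fixtures.harmonic_well()
    fs = _flat(s)
    state = SimState(0, fs.positions.copy() + [[0.0, 0.0], [3.0, 0.0]])
    F = forcefield.total_forces(state.positions, fs)
    out = bd_step(state, F, fs, IntegratorConfig(dt=1.0))
    assert np.array_equal(out.positions[0], state.positions[0])
    assert not np.array_equal(out.positions[1], state.positions[1])


def test_nonfinite_force_raises_with_diagnostics():
    s = fixtures.free_bead(2)
    fs = _flat(s)
    F = np.zeros_like(fs.positions)
    F[1, 0] = np.nan
    with pytest.raises(FloatingPointError, match="bead"):
        bd_step(SimState(7, fs.positions.copy()), F, fs, IntegratorConfig())


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

def test_rejection_passes_relaxed_chain_through():
    s = fixtures.single_wlc_chain()
    fs = _flat(s)
    prev = fs.positions
    proposed = prev + 0.01
    out = ottinger_reject(proposed, prev, fs)
    assert np.array_equal(out, proposed)


def test_rejection_reverts_overstretching_move():
    """Two-bead segment near the contour length: a separating move is
    rejected and the extension stays put."""
    s = fixtures.single_wlc_chain(n_segments=1, segment=10.0,
                                  initial_extension=0.985)
    fs = _flat(s)
    prev = fs.positions
    proposed = prev.copy()
    proposed[1, 0] += 0.1  # would reach 9.95 = 0.995 L_s
    out = ottinger_reject(proposed, prev, fs, f_max=0.99)
    assert np.array_equal(out[1], prev[1])


def test_rejection_rejects_invalid_previous_state():
    s = fixtures.single_wlc_chain(n_segments=1, initial_extension=1.02)
    fs = _flat(s)
    with pytest.raises(RuntimeError):
        ottinger_reject(fs.positions.copy(), fs.positions, fs)


def test_long_run_never_reaches_contour_length():
    """Equilibrium run of a tethered WLC: extension < 0.99 L_s at every
    sampled step (kernel invariant monitor at stride 1)."""
    s = fixtures.single_wlc_chain()
    fs = _flat(s)
    pos = fs.positions.copy()
    cfg = IntegratorConfig(dt=1.0, sample_stride=1)
    out = _run_chunks(pos, fs, s.frame, cfg, 100_000, seed_base=9,
                      detect_events=False)
    assert out["max_wlc_fraction"] < 0.99
    assert out["max_wlc_fraction"] > 0.3  # the chain does explore


# ---------------------------------------------------------------------------
# statistical physics of the integrator
# ---------------------------------------------------------------------------

def test_free_diffusion_msd_matches_einstein_relation():
    """<dr^2> = 4 D t in 2D for an ensemble of free beads."""
    n = 400
    s = fixtures.free_bead(n, radius=0.9, spacing=200.0)
    fs = _flat(s)
    pos = fs.positions.copy()
    start = pos.copy()
    cfg = IntegratorConfig(dt=1.0, chunk_steps=2000)
    nsteps = 10_000
    out = _run_chunks(pos, fs, s.frame, cfg, nsteps, seed_base=17,
                      detect_events=False)
    disp2 = ((pos - start) ** 2).sum(axis=1)
    msd = disp2.mean()
    expected = 4.0 * fs.D_red[0] * nsteps * cfg.dt
    se = disp2.std(ddof=1) / np.sqrt(n)
    assert abs(msd - expected) < 3 * se


def test_harmonic_well_samples_boltzmann_variance():
    """Positional variance in a k = 1 kT/nm^2 well equals kT/k = 1 nm^2
    per dimension within 5%."""
    s = fixtures.harmonic_well(k_s=1.0)
    fs = _flat(s)
    pos = fs.positions.copy()
    cfg = IntegratorConfig(dt=1.0, chunk_steps=250)
    samples = []
    out = _run_chunks(pos, fs, s.frame, cfg, 1_000_000, seed_base=23,
                      detect_events=False,
                      observers=[lambda step, p: samples.append(p[1].copy())])
    xy = np.array(samples[200:])  # discard relaxation (~200 steps each)
    var = xy.var(axis=0)
    assert np.allclose(var, 1.0, rtol=0.05)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def test_zero_steps_returns_initial_state_only():
    s = fixtures.mini_npc(seed=1)
    from npcbd.cargo import make_cargo
    cfg = IntegratorConfig(dt=2.0, max_steps=0)
    rec = run_simulation(s, make_cargo(8.0, 8), cfg,
                         cargo_position=np.array([0.0, 40.0]))
    assert rec.steps == 0
    assert rec.outcome == "timed_out"


def test_identical_seed_gives_bit_identical_records():
    s = fixtures.mini_npc(seed=1)
    from npcbd.cargo import make_cargo
    cg = make_cargo(8.0, 8)
    cfg = IntegratorConfig(dt=2.0, max_steps=5_000, seed=31, sample_stride=50)
    start = np.array([0.0, 40.0])
    r1 = run_simulation(s, cg, cfg, cargo_position=start)
    r2 = run_simulation(s, cg, cfg, cargo_position=start)
    assert np.array_equal(r1.track, r2.track)
    assert np.array_equal(r1.final_positions, r2.final_positions)
    cfg2 = IntegratorConfig(dt=2.0, max_steps=5_000, seed=32, sample_stride=50)
    r3 = run_simulation(s, cg, cfg2, cargo_position=start)
    assert not np.array_equal(r1.final_positions, r3.final_positions)


def test_trajectory_independent_of_chunking():
    s = fixtures.mini_npc(seed=1)
    from npcbd.cargo import make_cargo
    cg = make_cargo(8.0, 0)
    start = np.array([0.0, 40.0])
    recs = []
    for chunk in (1000, 3517):
        cfg = IntegratorConfig(dt=2.0, max_steps=6_000, seed=5,
                               sample_stride=100, chunk_steps=chunk)
        recs.append(run_simulation(s, cg, cfg, cargo_position=start))
    assert np.array_equal(recs[0].final_positions, recs[1].final_positions)


def test_kernel_drift_matches_reference_forces():
    """One noiseless kernel-equivalent step equals the reference
    total_forces drift: the two force paths are the same physics."""
    s = fixtures.mini_npc(seed=2)
    fs = _flat(s)
    state = SimState(0, fs.positions.copy())
    F = forcefield.total_forces(state.positions, fs)
    cfg = IntegratorConfig(dt=0.5)
    out = bd_step(state, F, fs, cfg, noise=False)
    drift = np.linalg.norm(out.positions - state.positions, axis=1)
    assert drift[fs.mobile].max() > 0  # grafted chains are not at rest
    # anchors stay put
    assert drift[~fs.mobile].max() == 0.0


def test_time_cap_limits_simulated_time():
    s = fixtures.mini_npc(seed=1)
    from npcbd.cargo import make_cargo
    cfg = IntegratorConfig(dt=2.0, max_steps=10**7, sample_stride=100)
    rec = run_simulation(s, make_cargo(8.0, 0), cfg,
                         cargo_position=np.array([0.0, 40.0]),
                         max_time_ms=2e-4)  # 1000 steps at dt=2
    assert rec.steps * cfg.dt <= units.ms_to_reduced_time(2e-4) + 1e-9
    assert rec.steps > 0


def test_equilibrate_moves_chains_not_anchors():
    s = fixtures.mini_npc(seed=1)
    before = s.positions()
    equilibrate(s, IntegratorConfig(dt=1.0, seed=3), 2000)
    after = s.positions()
    moved = np.linalg.norm(after - before, axis=1)
    anchors = [b.id for b in s.beads if not b.mobile]
    fg = [b.id for b in s.beads if b.group.startswith("fg")]
    assert moved[anchors].max() == 0.0
    assert moved[fg].mean() > 0.5
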