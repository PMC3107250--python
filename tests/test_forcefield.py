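"""Potentials: analytic values, gradient consistency, cutoff
continuity, interaction rules, neighbor-list vs brute-force assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcbd import _kernels, forcefield
from npcbd.forcefield import (ExtensibilityError, HydrophobicRule,
                              InteractionRuleSet, RepulsiveRule,
                              cosine_bending, harmonic, hydrophobic,
                              soft_repulsive, wlc_force)

from conftest import brute_force_pairs


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------

def test_harmonic_equilibrium_and_quadratic_value():
    assert harmonic(5.0, 3.0, 5.0) == (0.0, 0.0)
    e, f = harmonic(6.0, 2.0, 5.0)
    assert e == pytest.approx(1.0)
    assert f == pytest.approx(-2.0)  # attractive beyond rest length


@given(st.floats(0.1, 10.0), st.floats(0.5, 20.0), st.floats(0.1, 30.0))
@settings(max_examples=50, deadline=None)
def test_harmonic_force_is_negative_gradient(k, r0, r):
    h = 1e-6
    num = -(harmonic(r + h, k, r0).energy - harmonic(r - h, k, r0).energy) / (2 * h)
    assert harmonic(r, k, r0).force == pytest.approx(num, abs=1e-5)


def test_cosine_bending_reference_values():
    assert cosine_bending(1.2, 100.0, 1.2).energy == 0.0
    # half-turn from equilibrium at the scaffold stiffness
    assert cosine_bending(math.pi, 100.0, 0.0).energy == pytest.approx(200.0)


def test_cosine_bending_harmonic_small_angle_limit():
    k, t0 = 7.0, 1.0
    for d in (0.02, 0.05, 0.1):
        e = cosine_bending(t0 + d, k, t0).energy
        harm = 0.5 * k * d * d
        assert abs(e - harm) / e < 1e-3


@given(st.floats(0.05, 3.1), st.floats(0.1, 100.0), st.floats(0.1, 3.1))
@settings(max_examples=50, deadline=None)
def test_cosine_bending_torque_is_negative_gradient(theta, k, t0):
    h = 1e-6
    num = -(cosine_bending(theta + h, k, t0).energy -
            cosine_bending(theta - h, k, t0).energy) / (2 * h)
    assert cosine_bending(theta, k, t0).force == pytest.approx(num, abs=1e-4)


def test_wlc_force_zero_at_rest_and_half_extension_value():
    assert wlc_force(0.0, 10.0, 0.43) == pytest.approx(0.0)
    # x = L/2: (1/l_p)(1 - 1/4 + 1/2)
    assert wlc_force(5.0, 10.0, 0.43) == pytest.approx(1.25 / 0.43, rel=1e-9)


def test_wlc_force_diverges_monotonically_toward_contour():
    ext = np.linspace(0.0, 9.99, 200)
    f = np.array([wlc_force(x, 10.0, 0.43) for x in ext])
    assert np.all(np.diff(f) > 0)
    assert wlc_force(9.999, 10.0, 0.43) > 1e4
    with pytest.raises(ExtensibilityError):
        wlc_force(10.0, 10.0, 0.43)


def test_hydrophobic_reference_values_and_cutoff():
    kap = HydrophobicRule(epsilon=2.0, xi=1.5)
    assert hydrophobic(10.0, kap) == (0.0, 0.0)
    assert hydrophobic(12.0, kap) == (0.0, 0.0)
    e0 = hydrophobic(0.0, kap).energy
    assert e0 == pytest.approx(-2.0 + 2.0 * math.exp(-10 / 1.5), rel=1e-9)
    assert e0 == pytest.approx(-1.997, abs=5e-4)


def test_kap_fg_always_stronger_than_fg_fg():
    """Transport receptors are collectively more hydrophobic: the kap-FG
    well is deeper than FG-FG at every separation inside the cutoff."""
    kap = HydrophobicRule(epsilon=2.0, xi=1.5)
    ff = HydrophobicRule(epsilon=1.5, xi=1.0)
    for r in np.linspace(0, 9.99, 100):
        assert abs(hydrophobic(r, kap).energy) >= abs(hydrophobic(r, ff).energy)


def test_soft_repulsive_reference_values():
    rep = RepulsiveRule()
    assert soft_repulsive(1.35, rep) == (0.0, 0.0)
    assert soft_repulsive(0.0, rep).energy == pytest.approx(
        100.0 * (1.0 - math.exp(-1.35)), rel=1e-9)
    assert soft_repulsive(0.0, rep).energy == pytest.approx(74.1, abs=0.1)
    assert math.isfinite(soft_repulsive(0.0, rep).energy)


def test_soft_repulsive_monotone_nonincreasing():
    rep = RepulsiveRule()
    r = np.linspace(0, 2.0, 100)
    e = np.array([soft_repulsive(x, rep).energy for x in r])
    assert np.all(np.diff(e) <= 1e-12)


@pytest.mark.parametrize("rule,cut", [
    (HydrophobicRule(epsilon=2.0, xi=1.5), 10.0),
    (HydrophobicRule(epsilon=1.5, xi=1.0), 10.0),
])
def test_energy_continuity_at_cutoffs(rule, cut):
    """Shifted potentials vanish continuously at their cutoff."""
    for d in (1e-3, 1e-6, 1e-9):
        assert abs(hydrophobic(cut - d, rule).energy) < 3 * d
    assert abs(soft_repulsive(1.35 - 1e-9, RepulsiveRule()).energy) < 1e-6


@given(st.floats(0.05, 9.9))
@settings(max_examples=40, deadline=None)
def test_nonbonded_forces_are_negative_gradients(r):
    h = 1e-6
    for fn, rule in ((hydrophobic, HydrophobicRule(epsilon=2.0, xi=1.5)),
                     (soft_repulsive, RepulsiveRule(cutoff=10.0))):
        num = -(fn(r + h, rule).energy - fn(r - h, rule).energy) / (2 * h)
        assert fn(r, rule).force == pytest.approx(num, rel=1e-5, abs=1e-7)


def test_hydrophobic_parameter_ranges_enforced():
    with pytest.raises(ValueError):
        HydrophobicRule(epsilon=0.5, xi=1.0)
    with pytest.raises(ValueError):
        HydrophobicRule(epsilon=2.0, xi=3.0)


# ---------------------------------------------------------------------------
# assembled forces
# ---------------------------------------------------------------------------

def _mini_flat(mini_structure, cargo=None):
    from npcbd.cargo import make_cargo
    fs = forcefield.flatten(mini_structure, cargo)
    if cargo is not None:
        fs.positions[fs.cargo_index] = [0.0, mini_structure.frame.y_entry + 10.0]
    return fs


def test_total_force_is_negative_gradient_of_total_energy():
    """System-level check on a tethered chain + spring + nonbonded mix."""
    from npcbd import fixtures
    s = fixtures.single_wlc_chain()
    rng = np.random.default_rng(5)
    fs = forcefield.flatten(s)
    pos = fs.positions + rng.normal(0, 0.5, fs.positions.shape)
    F = forcefield.total_forces(pos, fs)
    h = 1e-6
    for i in range(fs.n):
        for c in range(2):
            pp = pos.copy(); pp[i, c] += h
            pm = pos.copy(); pm[i, c] -= h
            num = -(forcefield.total_energy(pp, fs) -
                    forcefield.total_energy(pm, fs)) / (2 * h)
            assert F[i, c] == pytest.approx(num, rel=1e-5, abs=1e-5)


def test_internal_forces_sum_to_zero(mini_structure):
    """Newton's third law over all beads including wall reactions and
    the cargo with its spot arc."""
    from npcbd.cargo import make_cargo
    cargo = make_cargo(8.0, 8)
    fs = forcefield.flatten(mini_structure, cargo)
    pos = fs.positions.copy()
    pos[fs.cargo_index] = [0.0, mini_structure.frame.y_chan_top + 5.0]
    F = forcefield.total_forces(pos, fs)
    assert np.abs(F.sum(axis=0)).max() < 1e-9


def test_kernel_force_assembly_matches_reference(mini_structure):
    """The numba per-class Verlet-list evaluation agrees with the
    brute-force reference assembly to 1e-10."""
    from npcbd.cargo import make_cargo
    cargo = make_cargo(8.0, 8)
    fs = forcefield.flatten(mini_structure, cargo)
    pos = fs.positions.copy()
    pos[fs.cargo_index] = [0.0, mini_structure.frame.y_chan_top + 6.0]
    pairs = brute_force_pairs(fs, pos)
    F_ref = forcefield.total_forces(pos, fs, pairs=pairs)

    n = fs.n
    cap = 64 * n + 1024
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    r = fs.rules
    npairs = _kernels.build_pairs(pos, fs.offsets, fs.group.astype(np.int8),
                                  fs.excl, r.fg_fg.cutoff,
                                  r.repulsion.cutoff, 2.0, pi, pj)
    assert npairs > 0
    fg_idx = np.where(fs.is_fg)[0].astype(np.int64)
    F_kernel = np.zeros_like(pos)
    ok = _kernels.compute_forces(
        pos, F_kernel, fs.offsets, fs.group.astype(np.int8),
        fs.bond_i, fs.bond_j, fs.bond_k, fs.bond_r0,
        fs.ang_i, fs.ang_j, fs.ang_k, fs.ang_kt, fs.ang_t0,
        fs.wlc_i, fs.wlc_j, fs.wlc_Ls, fs.l_p,
        pi, pj, npairs,
        r.fg_fg.epsilon, r.fg_fg.xi, r.fg_fg.cutoff,
        r.kap_fg.epsilon, r.kap_fg.xi, r.kap_fg.cutoff,
        r.repulsion.epsilon_rep, r.repulsion.sigma, r.repulsion.cutoff,
        fs.cargo_index, fs.spot_offsets, fg_idx, len(fg_idx))
    assert ok
    assert np.abs(F_kernel - F_ref).max() < 1e-10


def test_removing_binding_spots_zeroes_kap_terms_only(mini_structure):
    """Inert cargo: kap-FG forces vanish, FG-FG terms unchanged."""
    from npcbd.cargo import make_cargo
    pos_y = mini_structure.frame.y_chan_top + 6.0
    fs_a = forcefield.flatten(mini_structure, make_cargo(8.0, 8))
    fs_i = forcefield.flatten(mini_structure, make_cargo(8.0, 0))
    pa = fs_a.positions.copy(); pa[fs_a.cargo_index] = [0.0, pos_y]
    pi_ = fs_i.positions.copy(); pi_[fs_i.cargo_index] = [0.0, pos_y]
    Fa = forcefield.total_forces(pa, fs_a)
    Fi = forcefield.total_forces(pi_, fs_i)
    # the difference is exactly the kap-FG contribution on FG beads/cargo
    diff = np.abs(Fa - Fi)
    assert diff.max() > 0  # active cargo does interact here
    # FG-FG cohesion is identical in both systems: forces on central FG
    # beads far from the cargo are unchanged
    far = np.where(fs_a.is_central_fg &
                   (np.linalg.norm(pa - pa[fs_a.cargo_index], axis=1) > 25))[0]
    assert len(far) > 0
    assert np.abs(Fa[far] - Fi[far]).max() < 1e-12


def test_peripheral_fg_beads_have_no_mutual_cohesion():
    """Two isolated peripheral FG beads 3 nm apart feel only repulsion
    (zero at that range), while central beads attract."""
    from npcbd import fixtures
    s = fixtures.free_bead(2, radius=0.9, spacing=3.0)
    fs = forcefield.flatten(s)
    # both beads are scaffold in the fixture; reclassify
    for g, expect_attract in ((3, False), (2, True)):
        fs.group[:] = g
        F = forcefield.total_forces(fs.positions, fs)
        fx = F[0, 0]
        if expect_attract:
            assert fx > 0  # pulled toward the other bead (+x)
        else:
            assert fx == pytest.approx(0.0, abs=1e-12)
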