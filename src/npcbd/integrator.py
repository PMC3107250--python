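"""Explicit overdamped Langevin (Brownian dynamics) integration.

Each mobile bead advances per component as

    x_i(t+dt) = x_i(t) + F_i D_i dt / kT + dx_B,
    dx_B ~ Normal(0, 2 D_i dt),

in reduced units (kT = 1, length nm, time 0.1 ns).  Finite extensibility
of the WLC segments is enforced by a per-bead rejection in the spirit of
Oettinger's algorithm: any bead whose move pushes an adjacent segment to
``f_max`` of its contour length has that move reverted.  The rigid NE
slab and the simulation box are enforced the same way.

The default time step is 0.1 reduced units (0.01 ns), the shortest
resolvable kap-FG bond lifetime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, forcefield, units


@dataclass
class IntegratorConfig:
    """Run controls for the Brownian-dynamics engine.

    ``dt`` is in reduced time units (0.1 ns); the default 0.1 equals the
    0.01 ns simulation time step.  ``f_max`` is the rejection threshold
    as a fraction of the segment contour length.
    """

    dt: float = 0.1
    temperature: float = units.T_DEFAULT
    viscosity: float = units.VISCOSITY_CP
    seed: int = 0
    f_max: float = 0.99
    max_steps: int = 10_000_000
    rebuild_every: int = 50
    skin: float = 2.0
    sample_stride: int = 200
    chunk_steps: int = 10_000
    #: geometric kap-FG bond (contact) criterion, nm; of the order of the
    #: interaction well width 2*xi, deliberately far below the 10 nm
    #: force cutoff so bonds stay transient
    contact_radius: float = 3.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.f_max < 1.0):
            raise ValueError("f_max must lie in (0, 1)")


@dataclass
class SimState:
    """Mutable integration state: step counter, positions, RNG."""

    step: int
    positions: np.ndarray
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))


# re-exported parameterization helpers (Stokes drag / Einstein relation)
stokes_drag = units.stokes_drag
diffusion_from_drag = units.diffusion_from_drag


def brownian_displacement(D_um2_s: float, dt: float, rng: np.random.Generator,
                          size: int = 2) -> np.ndarray:
    """Random displacement (nm) of one bead over one step.

    Each Cartesian component is i.i.d. Normal(0, 2 D dt) with D converted
    from um^2/s to nm^2 per reduced time and dt in reduced time.
    """
    if D_um2_s <= 0:
        raise ValueError("diffusion coefficient must be positive")
    std = math.sqrt(2.0 * units.diffusion_to_reduced(D_um2_s) * dt)
    return rng.normal(0.0, std, size=size)


def ottinger_reject(proposed: np.ndarray, previous: np.ndarray,
                    fs: forcefield.FlatSystem, f_max: float = 0.99,
                    max_iter: int = 8) -> np.ndarray:
    """Per-bead rejection of moves that overstretch a WLC segment.

    Beads adjacent to any segment at >= ``f_max`` of its contour length
    in the proposed state revert to their previous positions; the check
    iterates because a partial revert can re-stretch another segment.
    Returns the accepted positions (a new array).
    """
    for w, (i, j) in enumerate(zip(fs.wlc_i, fs.wlc_j)):
        if np.linalg.norm(previous[j] - previous[i]) >= fs.wlc_Ls[w]:
            raise RuntimeError("previous state already violates extensibility")
    pos = proposed.copy()
    for _ in range(max_iter):
        revert = np.zeros(fs.n, bool)
        for w, (i, j) in enumerate(zip(fs.wlc_i, fs.wlc_j)):
            if np.linalg.norm(pos[j] - pos[i]) >= f_max * fs.wlc_Ls[w]:
                revert[i] = revert[j] = True
        if not revert.any():
            return pos
        revert &= fs.mobile
        pos[revert] = previous[revert]
    pos[fs.mobile] = previous[fs.mobile]
    return pos


def _wall_ok(pos: np.ndarray, fs: forcefield.FlatSystem) -> np.ndarray:
    """Boolean mask of beads NOT violating the NE slab / box boundaries."""
    ok = np.ones(fs.n, bool)
    for i in range(fs.n):
        x, y = pos[i]
        off = fs.offsets[i]
        if abs(x) + off > fs.x_box or y + off > fs.y_top or y - off < fs.y_bot:
            ok[i] = False
            continue
        ddx = max(fs.x_ne - abs(x), 0.0)
        ddy = max(fs.y_ne_bot - y, y - fs.y_ne_top, 0.0)
        dist = math.hypot(ddx, ddy)
        if (off > 0 and dist < off) or (off == 0 and dist == 0.0):
            ok[i] = False
    return ok


def bd_step(state: SimState, forces: np.ndarray, fs: forcefield.FlatSystem,
            config: IntegratorConfig, noise: bool = True) -> SimState:
    """One explicit overdamped step (reference implementation).

    The numba kernel performs the identical update in the run loop; this
    path exists for unit-level physics checks and tiny systems.
    """
    if not np.all(np.isfinite(forces)):
        bad = np.where(~np.isfinite(forces).all(axis=1))[0]
        raise FloatingPointError(
            f"non-finite force on bead(s) {bad.tolist()} at step {state.step}")
    prev = state.positions
    pos = prev.copy()
    dt = config.dt
    drift = forces * fs.D_red[:, None] * dt
    if noise:
        amp = np.sqrt(2.0 * fs.D_red * dt)
        noise_xy = state.rng.standard_normal(prev.shape) * amp[:, None]
    else:
        noise_xy = 0.0
    pos[fs.mobile] = (prev + drift + noise_xy)[fs.mobile]
    pos = ottinger_reject(pos, prev, fs, config.f_max)
    bad = ~_wall_ok(pos, fs) & fs.mobile
    pos[bad] = prev[bad]
    return SimState(step=state.step + 1, positions=pos, rng=state.rng)


def equilibrate(structure, config: IntegratorConfig, n_steps: int,
                rules: forcefield.InteractionRuleSet | None = None,
                seed: int | None = None) -> None:
    """Relax the FG layer for ``n_steps`` before introducing cargo.

    Updates bead positions in place.
    """
    if n_steps <= 0:
        return
    fs = forcefield.flatten(structure, cargo=None, rules=rules)
    pos = fs.positions.copy()
    base = config.seed if seed is None else seed
    _run_chunks(pos, fs, structure.frame, config, n_steps, base + 7919,
                detect_events=False)
    for b in structure.beads:
        b.position = pos[b.id].copy()


def _kernel_args(fs: forcefield.FlatSystem):
    r = fs.rules
    fg_idx = np.where(fs.is_fg)[0].astype(np.int64)
    return fs, fg_idx, (
        r.fg_fg.epsilon, r.fg_fg.xi, r.fg_fg.cutoff,
        r.kap_fg.epsilon, r.kap_fg.xi, r.kap_fg.cutoff,
        r.repulsion.epsilon_rep, r.repulsion.sigma, r.repulsion.cutoff,
    )


def _run_chunks(pos, fs, frame, config, max_steps, seed_base,
                detect_events=True, max_time_reduced=None, observers=()):
    """Drive the numba kernel in chunks; returns the raw bookkeeping."""
    fs_, fg_idx, nb = _kernel_args(fs)
    n_spots = len(fs.spot_offsets)
    n_fg = len(fg_idx)
    runlen = np.zeros((max(n_spots, 1), max(n_fg, 1)), np.int64)
    fg_slot = np.full(fs.n, -1, np.int64)
    fg_slot[fg_idx] = np.arange(n_fg)
    act_sp = np.zeros(4096, np.int64)
    act_slot = np.zeros(4096, np.int64)
    episodes = np.zeros(500_000, np.int64)
    acc = np.zeros(8, np.int64)
    facc = np.zeros(2)
    tracks, engaged = [], []
    t_start = -1
    t_end = -1
    total_steps = 0
    status = _kernels.STATUS_OK
    rng = np.random.default_rng(seed_base)
    amp = np.sqrt(2.0 * fs.D_red * config.dt)
    y_chan_bot = frame.y_chan_bot if frame else 0.0
    y_exit = frame.y_exit if frame else 0.0
    cargo_index = fs.cargo_index if detect_events else -1
    while total_steps < max_steps:
        n_steps = min(config.chunk_steps, max_steps - total_steps)
        if max_time_reduced is not None:
            n_steps = min(n_steps,
                          int(max_time_reduced / config.dt) - total_steps)
            if n_steps <= 0:
                break
        cap = n_steps // config.sample_stride + 4
        track = np.zeros((cap, 3))
        etrack = np.zeros(cap, np.int64)
        noise = rng.standard_normal((n_steps, fs.n, 2))
        status, done, t_start, t_end, n_track = _kernels.run_chunk(
            pos, fs.mobile, fs.D_red, fs.offsets, fs.group.astype(np.int8),
            fs.bond_i, fs.bond_j, fs.bond_k, fs.bond_r0,
            fs.ang_i, fs.ang_j, fs.ang_k, fs.ang_kt, fs.ang_t0,
            fs.wlc_i, fs.wlc_j, fs.wlc_Ls, fs.l_p,
            fs.excl, *nb,
            cargo_index, fs.spot_offsets, fg_idx, fg_slot,
            fs.is_filament_fg,
            fs.x_ne, fs.y_ne_top, fs.y_ne_bot, fs.x_box, fs.y_top, fs.y_bot,
            y_chan_bot, y_exit, fs.cargo_radius,
            config.dt, config.f_max, n_steps, noise, amp,
            config.rebuild_every, config.skin, config.contact_radius,
            total_steps, t_start, config.sample_stride,
            runlen, act_sp, act_slot, track, etrack, episodes, acc, facc)
        if status == _kernels.STATUS_FAULT:
            raise FloatingPointError(
                f"integration fault near step {total_steps + done}")
        tracks.append(track[:n_track])
        engaged.append(etrack[:n_track])
        total_steps += done
        for obs in observers:
            obs(total_steps, pos)
        if status == _kernels.STATUS_LOADED:
            break
    track = (np.concatenate(tracks) if tracks else np.zeros((0, 3)))
    etrack = (np.concatenate(engaged) if engaged else np.zeros(0, np.int64))
    return {
        "status": status, "steps": total_steps, "t_start": t_start,
        "t_end": t_end, "track": track, "engaged": etrack,
        "episodes": episodes[:acc[5]].copy(), "acc": acc.copy(),
        "max_wlc_fraction": facc[0],
    }


def run_simulation(structure, cargo=None, config: IntegratorConfig | None = None,
                   rules: forcefield.InteractionRuleSet | None = None,
                   cargo_position=None, equilibration_steps: int = 0,
                   max_time_ms: float | None = None, observers=()):
    """Run one transport (or relaxation) simulation to completion.

    Loops force evaluation -> Langevin step -> rejection -> bookkeeping
    until the cargo is loaded into the basket, ``config.max_steps`` is
    reached, or the simulated-time cap expires.  Fully reproducible from
    (config, seed).  Returns a :class:`npcbd.cargo.TransportRecord`.
    """
    from .cargo import TransportRecord

    if config is None:
        config = IntegratorConfig()
    if equilibration_steps:
        equilibrate(structure, config, equilibration_steps, rules)
    if cargo is not None and cargo_position is None:
        from .cargo import place_cargo_at_entry
        cargo_position = place_cargo_at_entry(structure, cargo)
    fs = forcefield.flatten(structure, cargo, rules, cargo_position)
    pos = fs.positions.copy()
    max_time_red = (units.ms_to_reduced_time(max_time_ms)
                    if max_time_ms is not None else None)
    out = _run_chunks(pos, fs, structure.frame, config, config.max_steps,
                      config.seed, detect_events=cargo is not None,
                      max_time_reduced=max_time_red, observers=observers)
    dt = config.dt
    track = out["track"]
    return TransportRecord(
        cargo=cargo, dt=dt, sample_stride=config.sample_stride,
        steps=out["steps"],
        times=track[:, 0] * dt if len(track) else np.zeros(0),
        track=track[:, 1:3].copy() if len(track) else np.zeros((0, 2)),
        engaged_spots=out["engaged"],
        t_start=(out["t_start"] * dt if out["t_start"] >= 0 else None),
        t_end=(out["t_end"] * dt if out["t_end"] >= 0 else None),
        episode_steps=out["episodes"],
        contact_acc=out["acc"],
        max_wlc_fraction=out["max_wlc_fraction"],
        outcome=("completed" if out["status"] == _kernels.STATUS_LOADED
                 else "timed_out"),
        frame=structure.frame,
        final_positions=pos,
    )
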