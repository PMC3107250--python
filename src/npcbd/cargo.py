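"""Cargo-complex definition and the import-transport protocol.

The cargo-complex (NLS-cargo + kap-beta) is a rigid sphere carrying a
"hydrophobic arc with limited capacity": eight equally spaced binding
spots on a semicircular arc of its surface, all with the same kap-FG
affinity.  A cargo with zero spots is inert: it feels only the soft
steric repulsion and probes the selectivity barrier.

Transport timing follows the import protocol: the run starts with the
cargo near the cytoplasmic entry, ``t_start`` is the first kap-FG
contact with a cytoplasmic-filament FG motif, and ``t_end`` is the first
moment the whole sphere is loaded inside the nuclear basket, where
RanGTP release is taken to be instantaneous and the run stops.  The
first-passage time is ``t_end - t_start``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import forcefield, geometry, units
from .integrator import IntegratorConfig, run_simulation


class PlacementError(RuntimeError):
    """Cargo could not be placed outside the structure."""


@dataclass
class Cargo:
    """A rigid sphere with an arc of hydrophobic binding spots."""

    diameter: float  # nm
    n_binding_spots: int = 8
    spot_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    kap_fg_rule: forcefield.HydrophobicRule = field(
        default_factory=lambda: forcefield.HydrophobicRule(epsilon=2.0, xi=1.5))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def active(self) -> bool:
        return self.n_binding_spots > 0

    @property
    def drag(self) -> float:
        return units.stokes_drag(self.radius)

    @property
    def diffusion(self) -> float:
        """Stokes-Einstein diffusion coefficient, um^2/s."""
        return units.diffusion_from_drag(self.drag)


def make_cargo(diameter: float, n_spots: int = 8,
               arc_center_deg: float = 0.0) -> Cargo:
    """Build a cargo with ``n_spots`` binding spots equally spaced over a
    180-degree arc centered on ``arc_center_deg`` (0 = +x direction).

    ``n_spots = 0`` yields an inert cargo.  The arc is body-fixed; the
    sphere does not rotate.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if n_spots < 0:
        raise ValueError("spot count must be nonnegative")
    R = diameter / 2.0
    if n_spots == 0:
        spots = np.zeros((0, 2))
    elif n_spots == 1:
        spots = np.array([[R, 0.0]])
    else:
        c = math.radians(arc_center_deg)
        angles = c + np.linspace(-math.pi / 2, math.pi / 2, n_spots)
        spots = R * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    return Cargo(diameter=diameter, n_binding_spots=n_spots,
                 spot_positions=spots)


@dataclass
class TransportRecord:
    """One run's down-sampled cargo track, event times and contact
    bookkeeping.  Times are in reduced units (0.1 ns) unless suffixed."""

    cargo: Cargo | None
    dt: float
    sample_stride: int
    steps: int
    times: np.ndarray  # sampled, reduced time
    track: np.ndarray  # (n, 2) cargo x, y
    engaged_spots: np.ndarray  # engaged-spot count at each sample
    t_start: float | None
    t_end: float | None
    episode_steps: np.ndarray  # recorded bond-episode lengths, in steps
    contact_acc: np.ndarray  # kernel accumulators, see _kernels.run_chunk
    max_wlc_fraction: float
    outcome: str  # "completed" | "timed_out"
    frame: object = None
    final_positions: np.ndarray | None = None

    @property
    def completed(self) -> bool:
        return self.outcome == "completed"

    @property
    def fpt_reduced(self) -> float | None:
        """First-passage time in reduced units, or None if incomplete."""
        if self.t_end is None:
            return None
        start = self.t_start if self.t_start is not None else 0.0
        return self.t_end - start

    @property
    def fpt_ms(self) -> float | None:
        t = self.fpt_reduced
        return None if t is None else units.reduced_time_to_ms(t)

    @property
    def times_ms(self) -> np.ndarray:
        return units.reduced_time_to_ms(self.times)

    def mean_occupancy(self) -> float:
        """Mean simultaneously engaged binding spots over engaged steps."""
        if self.cargo is None or not self.cargo.active:
            raise ValueError("occupancy is undefined for inert cargo")
        engaged_steps = int(self.contact_acc[0])
        if engaged_steps == 0:
            return float("nan")
        return float(self.contact_acc[1]) / engaged_steps

    def bond_lifetime_summary(self) -> dict:
        """Summary of kap-FG bond episode lifetimes in ns."""
        step_ns = self.dt * units.TIME_UNIT_NS
        n = int(self.contact_acc[2])
        if n == 0:
            return {"n": 0, "mean_ns": float("nan"), "max_ns": float("nan")}
        return {
            "n": n,
            "mean_ns": float(self.contact_acc[3]) / n * step_ns,
            "max_ns": float(self.contact_acc[4]) * step_ns,
        }


def place_cargo_at_entry(structure: geometry.NPCStructure, cargo: Cargo,
                         standoff: float | None = None) -> np.ndarray:
    """Initial cargo position: centered on the pore axis, beyond the
    filament tips and outside the kap-FG cutoff of every FG bead.

    ``standoff`` defaults to one cargo diameter beyond the filament
    tips; the position is then raised, if needed, until the nearest FG
    bead is beyond the 10 nm interaction cutoff so that ``t_start`` is
    detected dynamically.  Deterministic: randomness enters only through
    the dynamics.
    """
    frame = structure.frame
    if standoff is None:
        standoff = cargo.diameter
    y = frame.y_entry + standoff + cargo.radius
    cutoff = cargo.kap_fg_rule.cutoff
    fg = np.array([b.position for b in structure.beads
                   if b.group in ("fg_central", "fg_peripheral")])
    pos = np.array([0.0, y])
    if len(fg):
        for _ in range(200):
            d = np.linalg.norm(fg - pos, axis=1).min() - cargo.radius
            if d > cutoff:
                break
            pos[1] += 2.0
        else:
            raise PlacementError("could not clear the FG cloud at the entry")
    if pos[1] + cargo.radius > frame.y_top:
        raise PlacementError(
            f"standoff places the cargo outside the box (y={pos[1]:.1f})")
    scaff = np.array([b.position for b in structure.beads
                      if b.group == "scaffold"])
    if len(scaff) and np.linalg.norm(scaff - pos, axis=1).min() < cargo.radius:
        raise PlacementError("standoff places the cargo inside the structure")
    return pos


def detect_events(times: np.ndarray, positions: np.ndarray,
                  structure: geometry.NPCStructure, cargo: Cargo,
                  cutoff: float | None = None):
    """Event times from a (scripted or recorded) cargo trajectory.

    ``t_start``: first time any binding spot lies within the kap-FG
    cutoff of a cytoplasmic-filament FG motif (motif positions taken
    from the current structure state).  ``t_end``: first time the whole
    sphere is inside the basket (surface fully past the nuclear-ring
    plane and above the distal-ring plane).  Returns (t_start, t_end),
    either possibly None.  The simulation kernel applies the same rules
    per step; this offline form serves scripted trajectories.
    """
    frame = structure.frame
    if cutoff is None:
        cutoff = cargo.kap_fg_rule.cutoff
    fil_fg = [b_id for c in structure.chains if c.region == "filament"
              for b_id in c.motif_ids]
    fil_pos = np.array([structure.beads[i].position for i in fil_fg]) \
        if fil_fg else np.zeros((0, 2))
    t_start = t_end = None
    R = cargo.radius
    for t, p in zip(times, positions):
        if t_start is None and len(fil_pos) and cargo.active:
            spots = p + cargo.spot_positions
            d = np.linalg.norm(fil_pos[None, :, :] - spots[:, None, :], axis=-1)
            if d.min() < cutoff:
                t_start = t
        if t_end is None:
            if (p[1] + R < frame.y_chan_bot) and (p[1] - R > frame.y_exit):
                t_end = t
                break
    return t_start, t_end


def delete_cytoplasmic_filaments(structure: geometry.NPCStructure
                                 ) -> geometry.NPCStructure:
    """NPC without cytoplasmic filaments or their grafted FG chains."""
    return geometry.remove_filaments(structure)


@dataclass
class BatchResult:
    """Aggregate of independent transport runs."""

    records: list
    failures: list

    @property
    def completed(self) -> list:
        return [r for r in self.records if r.completed]

    @property
    def fpt_ms(self) -> np.ndarray:
        return np.array([r.fpt_ms for r in self.completed])

    @property
    def success_fraction(self) -> float:
        return len(self.completed) / max(1, len(self.records) + len(self.failures))

    def fpt_sample(self):
        from .fpt import FPTSample
        return FPTSample.from_times(self.fpt_ms)


def run_batch(n_runs: int, structure: geometry.NPCStructure, cargo_spec,
              config: IntegratorConfig | None = None,
              rules: forcefield.InteractionRuleSet | None = None,
              seeds=None, equilibration_steps: int = 0,
              max_time_ms: float | None = None,
              standoff: float | None = None) -> BatchResult:
    """Run ``n_runs`` independent seeded transport simulations.

    The FG layer is relaxed once (``equilibration_steps``), the cargo is
    placed at the entry, and each run then evolves with its own noise
    seed from the common relaxed state.  Individual run faults are
    recorded, not fatal.  ``cargo_spec`` is a Cargo or a
    (diameter, n_spots) tuple.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if config is None:
        config = IntegratorConfig()
    cargo = (cargo_spec if isinstance(cargo_spec, Cargo)
             else make_cargo(*cargo_spec))
    if seeds is None:
        seeds = [config.seed + 1000 * k for k in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    if equilibration_steps:
        from .integrator import equilibrate
        equilibrate(structure, config, equilibration_steps, rules)
    start = place_cargo_at_entry(structure, cargo, standoff)
    records, failures = [], []
    for seed in seeds:
        run_cfg = IntegratorConfig(**{**config.__dict__, "seed": int(seed)})
        try:
            rec = run_simulation(structure, cargo, run_cfg, rules,
                                 cargo_position=start,
                                 max_time_ms=max_time_ms)
            records.append(rec)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((int(seed), repr(exc)))
    return BatchResult(records=records, failures=failures)
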