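"""Potential energies, forces and interaction rules.

Five interactions act between beads, all in reduced units (energy kT,
length nm):

* harmonic springs along the elastic scaffold and the pom anchors,
* cosine bending ``E = k_theta (1 - cos(theta - theta0))`` on scaffold
  and WLC triples,
* the Marko-Siggia wormlike-chain tension on FG segments,
* a long-range hydrophobic attraction ``E = -eps exp(-r/xi)``
  (cutoff-shifted, cutoff 10 nm) between cohesive FG motifs and between
  kap binding spots and FG motifs,
* a soft short-range repulsion ``E = eps_rep exp(-r/sigma)``
  (cutoff-shifted, cutoff 1.35 nm) between all nonbonded beads, finite
  at contact so the large Brownian time step stays stable.

Scalar force conventions: radial force = -dE/dr along the pair
separation, so negative values are attractive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class EnergyForce(NamedTuple):
    energy: float  # kT
    force: float  # kT/nm (radial, -dE/dr) or kT/rad for bending


@dataclass
class HydrophobicRule:
    """Exponential hydrophobic attraction with strength eps (kT) and
    characteristic length xi (nm), truncated and shifted at the cutoff."""

    epsilon: float
    xi: float
    cutoff: float = 10.0

    def __post_init__(self):
        if not (1.5 <= self.epsilon <= 10.0):
            raise ValueError("hydrophobic strength must lie in [1.5, 10] kT")
        if not (1.0 <= self.xi <= 2.0):
            raise ValueError("characteristic length must lie in [1, 2] nm")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class RepulsiveRule:
    """Soft exponential repulsion, finite at zero separation."""

    epsilon_rep: float = 100.0
    sigma: float = 1.0
    cutoff: float = 1.35

    def __post_init__(self):
        if self.epsilon_rep <= 0 or self.sigma <= 0 or self.cutoff <= 0:
            raise ValueError("repulsive parameters must be positive")


@dataclass
class InteractionRuleSet:
    """Which nonbonded rule applies to which bead-class pair.

    FG-FG cohesion acts only among central-channel FG beads; kap-FG acts
    between cargo binding spots and every FG bead; the soft repulsion
    acts between all nonbonded pairs including the cargo surface.
    """

    fg_fg: HydrophobicRule = field(
        default_factory=lambda: HydrophobicRule(epsilon=1.5, xi=1.0))
    kap_fg: HydrophobicRule = field(
        default_factory=lambda: HydrophobicRule(epsilon=2.0, xi=1.5))
    repulsion: RepulsiveRule = field(default_factory=RepulsiveRule)


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------

def harmonic(r: float, k_s: float, r0: float) -> EnergyForce:
    """Harmonic spring energy and radial force; attractive for r > r0."""
    if r < 0:
        raise ValueError("separation must be nonnegative")
    dr = r - r0
    return EnergyForce(0.5 * k_s * dr * dr, -k_s * dr)


def cosine_bending(theta: float, k_theta: float, theta0: float) -> EnergyForce:
    """Cosine bending energy and torque -dE/dtheta at angle theta.

    In the small-deflection limit this reduces to the harmonic form
    ``1/2 k_theta (theta - theta0)^2``.
    """
    if not (0.0 <= theta <= math.pi + 1e-12):
        raise ValueError("theta must lie in [0, pi]")
    d = theta - theta0
    return EnergyForce(k_theta * (1.0 - math.cos(d)), -k_theta * math.sin(d))


def wlc_force(extension: float, L_s: float, l_p: float) -> float:
    """Marko-Siggia interpolated WLC tension (kT/nm), restoring.

    F = (kT/l_p) [ 1/(4(1-x/L)^2) - 1/4 + x/L ].  Diverges as the
    extension approaches the segment contour length; callers must keep
    extensions strictly below L_s (the integrator's rejection step).
    """
    if extension < 0:
        raise ValueError("extension must be nonnegative")
    if extension >= L_s:
        raise ExtensibilityError(
            f"WLC extension {extension:.4f} nm >= contour length {L_s} nm")
    x = extension / L_s
    return (1.0 / l_p) * (0.25 / (1.0 - x) ** 2 - 0.25 + x)


class ExtensibilityError(RuntimeError):
    """A WLC segment reached or exceeded its contour length."""


def hydrophobic(r: float, rule: HydrophobicRule) -> EnergyForce:
    """Cutoff-shifted exponential hydrophobic attraction.

    E(r) = -eps exp(-r/xi) + eps exp(-cutoff/xi) for r < cutoff, else 0;
    continuous at the cutoff and attractive everywhere inside it.
    """
    if r < 0:
        raise ValueError("separation must be nonnegative")
    if r >= rule.cutoff:
        return EnergyForce(0.0, 0.0)
    shift = rule.epsilon * math.exp(-rule.cutoff / rule.xi)
    e = -rule.epsilon * math.exp(-r / rule.xi) + shift
    f = -(rule.epsilon / rule.xi) * math.exp(-r / rule.xi)
    return EnergyForce(e, f)


def soft_repulsive(r: float, rule: RepulsiveRule) -> EnergyForce:
    """Cutoff-shifted soft exponential repulsion, finite at r = 0."""
    if r < 0:
        raise ValueError("separation must be nonnegative")
    if r >= rule.cutoff:
        return EnergyForce(0.0, 0.0)
    shift = rule.epsilon_rep * math.exp(-rule.cutoff / rule.sigma)
    e = rule.epsilon_rep * math.exp(-r / rule.sigma) - shift
    f = (rule.epsilon_rep / rule.sigma) * math.exp(-r / rule.sigma)
    return EnergyForce(e, f)


def wlc_bending_constant(l_p: float, L_s: float) -> float:
    """Bending constant of the discrete WLC, k_theta = kT l_p / L_s."""
    if l_p <= 0 or L_s <= 0:
        raise ValueError("persistence and contour lengths must be positive")
    return l_p / L_s


# ---------------------------------------------------------------------------
# flattened system for force assembly
# ---------------------------------------------------------------------------

GROUP_CODE = {"pom_anchor": 0, "scaffold": 1, "fg_central": 2,
              "fg_peripheral": 3, "cargo": 4}


@dataclass
class FlatSystem:
    """Array representation of an NPCStructure (+ optional cargo) used by
    the force routines and the simulation kernel."""

    positions: np.ndarray  # (N,2) nm
    mobile: np.ndarray  # (N,) bool
    D_red: np.ndarray  # (N,) nm^2 per reduced time
    offsets: np.ndarray  # (N,) nm, surface offset (cargo radius, else 0)
    group: np.ndarray  # (N,) int8
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_k: np.ndarray  # kT/nm^2
    bond_r0: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_kt: np.ndarray
    ang_t0: np.ndarray
    wlc_i: np.ndarray
    wlc_j: np.ndarray
    wlc_Ls: np.ndarray
    l_p: float
    excl: np.ndarray  # sorted i8 keys i*N+j with i<j
    rules: InteractionRuleSet
    cargo_index: int = -1
    spot_offsets: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    cargo_radius: float = 0.0
    # rigid boundaries: NE slab {|x| >= x_ne, y_ne_bot <= y <= y_ne_top}
    # and the rectangular simulation box
    x_ne: float = np.inf
    y_ne_top: float = 0.0
    y_ne_bot: float = 0.0
    x_box: float = np.inf
    y_top: float = np.inf
    y_bot: float = -np.inf
    is_filament_fg: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def is_fg(self) -> np.ndarray:
        return (self.group == 2) | (self.group == 3)

    @property
    def is_central_fg(self) -> np.ndarray:
        return self.group == 2

    def pair_key(self, i: int, j: int) -> int:
        a, b = (i, j) if i < j else (j, i)
        return a * self.n + b

    def excluded(self, i: int, j: int) -> bool:
        return np.searchsorted(self.excl, self.pair_key(i, j)) < len(self.excl) and \
            self.excl[np.searchsorted(self.excl, self.pair_key(i, j))] == self.pair_key(i, j)


def flatten(structure, cargo=None, rules: InteractionRuleSet | None = None,
            cargo_position=None) -> FlatSystem:
    """Flatten an NPCStructure (and optional cargo) into arrays.

    The cargo, if given, is appended as one extra mobile bead whose
    nonbonded separations are measured center-to-surface.
    """
    from . import units

    if rules is None:
        rules = InteractionRuleSet()
    beads = structure.beads
    n_struct = len(beads)
    n = n_struct + (1 if cargo is not None else 0)

    positions = np.zeros((n, 2))
    mobile = np.zeros(n, bool)
    D_red = np.zeros(n)
    offsets = np.zeros(n)
    group = np.zeros(n, np.int8)
    for b in beads:
        positions[b.id] = b.position
        mobile[b.id] = b.mobile
        D_red[b.id] = units.diffusion_to_reduced(b.diffusion)
        group[b.id] = GROUP_CODE[b.group]

    filament_fg = np.zeros(n, bool)
    for c in structure.chains:
        if c.region == "filament":
            filament_fg[c.motif_ids] = True

    cargo_index = -1
    spot_offsets = np.zeros((0, 2))
    cargo_radius = 0.0
    if cargo is not None:
        cargo_index = n_struct
        cargo_radius = cargo.radius
        positions[cargo_index] = (cargo_position if cargo_position is not None
                                  else np.zeros(2))
        mobile[cargo_index] = True
        D_red[cargo_index] = units.diffusion_to_reduced(cargo.diffusion)
        offsets[cargo_index] = cargo.radius
        group[cargo_index] = GROUP_CODE["cargo"]
        spot_offsets = np.asarray(cargo.spot_positions, float).reshape(-1, 2)

    bond_i = np.array([b.bead_i for b in structure.bonds], np.int64)
    bond_j = np.array([b.bead_j for b in structure.bonds], np.int64)
    bond_k = np.array([b.k_s for b in structure.bonds])
    bond_r0 = np.array([b.r0 for b in structure.bonds])
    ang_i = np.array([a.bead_i for a in structure.angles], np.int64)
    ang_j = np.array([a.bead_j for a in structure.angles], np.int64)
    ang_k = np.array([a.bead_k for a in structure.angles], np.int64)
    ang_kt = np.array([a.k_theta for a in structure.angles])
    ang_t0 = np.array([a.theta0 for a in structure.angles])

    wlc_i, wlc_j, wlc_Ls = [], [], []
    fg_ang_i, fg_ang_j, fg_ang_k, fg_kt, fg_t0 = [], [], [], [], []
    l_p = structure.chains[0].persistence if structure.chains else 0.43
    for c in structure.chains:
        ids = c.bead_ids
        for a, b in zip(ids[:-1], ids[1:]):
            wlc_i.append(a)
            wlc_j.append(b)
            wlc_Ls.append(c.segment_contour)
        kt = wlc_bending_constant(c.persistence, c.segment_contour)
        for a, b, cc in zip(ids[:-2], ids[1:-1], ids[2:]):
            fg_ang_i.append(a)
            fg_ang_j.append(b)
            fg_ang_k.append(cc)
            fg_kt.append(kt)
            fg_t0.append(math.pi)  # straight chain is the WLC ground state
    if fg_ang_i:
        ang_i = np.concatenate([ang_i, np.array(fg_ang_i, np.int64)])
        ang_j = np.concatenate([ang_j, np.array(fg_ang_j, np.int64)])
        ang_k = np.concatenate([ang_k, np.array(fg_ang_k, np.int64)])
        ang_kt = np.concatenate([ang_kt, np.array(fg_kt)])
        ang_t0 = np.concatenate([ang_t0, np.array(fg_t0)])

    keys = set()
    for a, b in zip(bond_i, bond_j):
        a, b = (a, b) if a < b else (b, a)
        keys.add(int(a) * n + int(b))
    for a, b in zip(wlc_i, wlc_j):
        a, b = (a, b) if a < b else (b, a)
        keys.add(int(a) * n + int(b))
    excl = np.array(sorted(keys), np.int64)

    frame = structure.frame
    fs = FlatSystem(
        positions=positions, mobile=mobile, D_red=D_red, offsets=offsets,
        group=group,
        bond_i=bond_i, bond_j=bond_j, bond_k=bond_k, bond_r0=bond_r0,
        ang_i=ang_i, ang_j=ang_j, ang_k=ang_k, ang_kt=ang_kt, ang_t0=ang_t0,
        wlc_i=np.array(wlc_i, np.int64), wlc_j=np.array(wlc_j, np.int64),
        wlc_Ls=np.array(wlc_Ls), l_p=l_p, excl=excl, rules=rules,
        cargo_index=cargo_index, spot_offsets=spot_offsets,
        cargo_radius=cargo_radius, is_filament_fg=filament_fg)
    if frame is not None:
        fs.x_ne = frame.x_ne
        fs.y_ne_top = frame.y_chan_top
        fs.y_ne_bot = frame.y_chan_bot
        fs.x_box = frame.x_box
        fs.y_top = frame.y_top
        fs.y_bot = frame.y_bot
    return fs


# ---------------------------------------------------------------------------
# force and energy assembly (reference numpy implementation)
# ---------------------------------------------------------------------------

def nonbonded_pairs(fs: FlatSystem, positions: np.ndarray,
                    cutoff: float | None = None) -> np.ndarray:
    """All nonbonded candidate pairs (i<j) within ``cutoff`` of each other
    (surface-to-surface), exclusions removed.  O(N^2); the simulation
    kernel maintains an equivalent cell-free Verlet list."""
    n = fs.n
    if cutoff is None:
        cutoff = max(fs.rules.fg_fg.cutoff, fs.rules.kap_fg.cutoff,
                     fs.rules.repulsion.cutoff)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    d_eff = d - fs.offsets[:, None] - fs.offsets[None, :]
    ii, jj = np.where(np.triu(d_eff < cutoff, k=1))
    keys = ii.astype(np.int64) * n + jj
    if len(fs.excl):
        pos = np.clip(np.searchsorted(fs.excl, keys), 0, len(fs.excl) - 1)
        keep = fs.excl[pos] != keys
    else:
        keep = np.ones(len(keys), bool)
    return np.stack([ii[keep], jj[keep]], axis=1)


def _pair_terms(fs: FlatSystem, i: int, j: int, r_eff: float):
    """Sum of nonbonded scalar terms for pair (i, j): (energy, force)."""
    e = f = 0.0
    r = max(r_eff, 0.0)
    ef = soft_repulsive(r, fs.rules.repulsion)
    e += ef.energy
    f += ef.force
    if fs.group[i] == 2 and fs.group[j] == 2:  # cohesive FG-FG
        ef = hydrophobic(r, fs.rules.fg_fg)
        e += ef.energy
        f += ef.force
    return e, f


def total_forces(positions: np.ndarray, fs: FlatSystem,
                 pairs: np.ndarray | None = None) -> np.ndarray:
    """Per-bead total conservative forces (kT/nm), Newton-third-law exact.

    Bonded terms (springs, bending, WLC) plus nonbonded terms over the
    supplied pair list (or a freshly computed one).  This is the clear
    reference path; the numba kernel reimplements it for the run loop.
    """
    F = np.zeros_like(positions)
    # harmonic bonds (incl. pom springs)
    for i, j, k, r0 in zip(fs.bond_i, fs.bond_j, fs.bond_k, fs.bond_r0):
        dv = positions[j] - positions[i]
        r = float(np.linalg.norm(dv))
        if r < 1e-12:
            continue
        fmag = harmonic(r, k, r0).force  # -dE/dr
        u = dv / r
        F[i] -= fmag * u
        F[j] += fmag * u
    # angles
    for i, j, k, kt, t0 in zip(fs.ang_i, fs.ang_j, fs.ang_k, fs.ang_kt, fs.ang_t0):
        u = positions[i] - positions[j]
        v = positions[k] - positions[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            raise ValueError(f"degenerate angle {i}-{j}-{k}: overlapping beads")
        c = float(np.dot(u, v) / (nu * nv))
        c = max(-1.0, min(1.0, c))
        if t0 == math.pi:
            # sin(theta - pi)/sin(theta) = -1: no trig needed
            g = -kt
        else:
            theta = math.acos(c)
            s = math.sqrt(max(1.0 - c * c, 1e-24))
            g = kt * math.sin(theta - t0) / s
        dci = (v / nv - c * u / nu) / nu
        dck = (u / nu - c * v / nv) / nv
        F[i] += g * dci
        F[k] += g * dck
        F[j] -= g * (dci + dck)
    # WLC tensions
    for i, j, Ls in zip(fs.wlc_i, fs.wlc_j, fs.wlc_Ls):
        dv = positions[j] - positions[i]
        r = float(np.linalg.norm(dv))
        if r < 1e-12:
            continue
        t = wlc_force(r, Ls, fs.l_p)  # positive tension
        u = dv / r
        F[i] += t * u
        F[j] -= t * u
    # nonbonded
    if pairs is None:
        pairs = nonbonded_pairs(fs, positions)
    for i, j in pairs:
        dv = positions[j] - positions[i]
        r = float(np.linalg.norm(dv))
        if r < 1e-12:
            continue
        r_eff = r - fs.offsets[i] - fs.offsets[j]
        _, fmag = _pair_terms(fs, i, j, r_eff)
        u = dv / r
        F[i] -= fmag * u
        F[j] += fmag * u
    # kap binding spots x FG beads
    if fs.cargo_index >= 0 and len(fs.spot_offsets):
        ci = fs.cargo_index
        fg_idx = np.where(fs.is_fg)[0]
        for off in fs.spot_offsets:
            spot = positions[ci] + off
            for j in fg_idx:
                dv = positions[j] - spot
                r = float(np.linalg.norm(dv))
                if r < 1e-12 or r >= fs.rules.kap_fg.cutoff:
                    continue
                fmag = hydrophobic(r, fs.rules.kap_fg).force
                u = dv / r
                F[ci] -= fmag * u
                F[j] += fmag * u
    return F


def total_energy(positions: np.ndarray, fs: FlatSystem,
                 pairs: np.ndarray | None = None) -> float:
    """Total potential energy (kT) consistent with :func:`total_forces`.

    The WLC contribution uses the integral of the Marko-Siggia tension.
    """
    E = 0.0
    for i, j, k, r0 in zip(fs.bond_i, fs.bond_j, fs.bond_k, fs.bond_r0):
        r = float(np.linalg.norm(positions[j] - positions[i]))
        E += harmonic(r, k, r0).energy
    for i, j, k, kt, t0 in zip(fs.ang_i, fs.ang_j, fs.ang_k, fs.ang_kt, fs.ang_t0):
        u = positions[i] - positions[j]
        v = positions[k] - positions[j]
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        E += cosine_bending(math.acos(max(-1.0, min(1.0, c))), kt, t0).energy
    for i, j, Ls in zip(fs.wlc_i, fs.wlc_j, fs.wlc_Ls):
        r = float(np.linalg.norm(positions[j] - positions[i]))
        x = r / Ls
        # integral of the Marko-Siggia tension from 0 to r
        E += (Ls / fs.l_p) * (0.25 / (1.0 - x) - 0.25 - 0.25 * x + 0.5 * x * x)
    if pairs is None:
        pairs = nonbonded_pairs(fs, positions)
    for i, j in pairs:
        r = float(np.linalg.norm(positions[j] - positions[i]))
        r_eff = max(r - fs.offsets[i] - fs.offsets[j], 0.0)
        e, _ = _pair_terms(fs, i, j, r_eff)
        E += e
    if fs.cargo_index >= 0 and len(fs.spot_offsets):
        ci = fs.cargo_index
        fg_idx = np.where(fs.is_fg)[0]
        for off in fs.spot_offsets:
            spot = positions[ci] + off
            for j in fg_idx:
                r = float(np.linalg.norm(positions[j] - spot))
                E += hydrophobic(r, fs.rules.kap_fg).energy
    return E
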