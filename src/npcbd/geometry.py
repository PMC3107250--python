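"""Discretized two-spoke NPC geometry.

The model lives in a 2D cross-sectional plane containing two opposing
spokes of the pore.  The y axis is the pore (transport) axis with the
cytoplasm at positive y; x is the transverse coordinate measured from the
pore axis.  The nuclear envelope (NE) is a rigid slab pierced by the
channel; pom springs anchor the elastic channel wall to it.

Subunits, from cytoplasm to nucleus:

* cytoplasmic filaments (length ``filament_length``) rising from the
  cytoplasmic ring,
* an hourglass central channel of length ``channel_length`` whose radius
  narrows from ``channel_end_diameter/2`` at the rings to
  ``channel_min_diameter/2`` at mid-channel,
* a nuclear basket: two rods converging from the nuclear ring onto a
  distal ring of diameter ``distal_ring_diameter``.

The cytoplasmic-entry plane is the filament tip and the exit plane is the
distal ring, so the default transport span is
``filament_length + channel_length + basket_length`` = 160 nm.

FG-repeat domains are grafted onto the scaffold as discrete wormlike
chains: short cohesive chains (50 nm contour) in the central channel,
long noncohesive chains (200 nm) on the filaments and the basket.  Each
WLC segment endpoint carries one FG-motif bead; the default build holds
exactly 720 motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import units

GROUPS = ("pom_anchor", "scaffold", "fg_central", "fg_peripheral", "cargo")
REGIONS = ("filament", "channel", "basket", "anchor")


class ConfigurationError(ValueError):
    """Raised when a geometry configuration cannot be realized."""


@dataclass
class GeometryConfig:
    """Dimensions and discretization of the two-spoke NPC model.

    All lengths in nm.  ``transport_span`` must equal
    ``filament_length + channel_length + basket_length``; it is the
    distance between the cytoplasmic entry plane (filament tips) and the
    basket exit plane (distal ring) used by the free-diffusion baseline.
    """

    channel_min_diameter: float = 50.0
    channel_end_diameter: float = 70.0
    channel_length: float = 60.0
    filament_length: float = 35.0
    basket_length: float = 65.0
    distal_ring_diameter: float = 40.0
    transport_span: float = 160.0
    scaffold_bead_spacing: float = 10.0
    scaffold_bead_radius: float = 3.0
    fg_bead_radius: float = 0.9
    n_spokes: int = 2
    fg_total_motifs: int = 720
    fg_central_contour: float = 50.0
    fg_peripheral_contour: float = 200.0
    fg_segment_length: float = 10.0
    #: fraction of motifs assigned to (filament, channel, basket) regions
    fg_region_split: tuple = (1 / 3, 1 / 3, 1 / 3)
    #: NE inner face offset beyond the channel end radius (pom rest length)
    ne_offset: float = 10.0
    #: extra simulation-box margin beyond the NE inner face
    box_margin: float = 25.0
    simulation_dimensionality: int = 2

    def validate(self) -> None:
        if self.simulation_dimensionality != 2:
            raise ConfigurationError("only the 2D cross-sectional model is supported")
        if self.n_spokes != 2:
            raise ConfigurationError("the cross-sectional model has exactly two spokes")
        for name in (
            "channel_min_diameter",
            "channel_end_diameter",
            "channel_length",
            "filament_length",
            "basket_length",
            "distal_ring_diameter",
            "scaffold_bead_spacing",
            "fg_central_contour",
            "fg_peripheral_contour",
            "fg_segment_length",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        span = self.filament_length + self.channel_length + self.basket_length
        if abs(span - self.transport_span) > 1e-9:
            raise ConfigurationError(
                f"transport_span={self.transport_span} nm does not match "
                f"filament+channel+basket={span} nm"
            )
        if self.channel_end_diameter < self.channel_min_diameter:
            raise ConfigurationError("channel_end_diameter < channel_min_diameter")
        if abs(sum(self.fg_region_split) - 1.0) > 1e-9:
            raise ConfigurationError("fg_region_split must sum to 1")


@dataclass
class Bead:
    """A lumped mass point: the universal dynamic unit of the model.

    The hydrodynamic radius equals the geometric radius; drag follows
    Stokes' law and diffusion the Einstein relation.
    """

    id: int
    position: np.ndarray
    radius: float  # nm
    group: str
    mobile: bool = True
    region: str = "channel"
    lumped_mass: float = 0.0  # kg
    drag: float = 0.0  # kg/s
    diffusion: float = 0.0  # um^2/s

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"unknown bead group {self.group!r}")
        if self.radius <= 0:
            raise ValueError("bead radius must be positive")
        if self.lumped_mass == 0.0:
            rho = units.PROTEIN_DENSITY * 1e3  # kg/m^3
            self.lumped_mass = 4.0 / 3.0 * math.pi * (self.radius * 1e-9) ** 3 * rho
        if self.drag == 0.0:
            self.drag = units.stokes_drag(self.radius)
        if self.diffusion == 0.0:
            self.diffusion = units.diffusion_from_drag(self.drag)


@dataclass
class BondSpring:
    """Harmonic bond: E = 1/2 k_s (r - r0)^2."""

    bead_i: int
    bead_j: int
    k_s: float  # kT/nm^2
    r0: float  # nm

    def __post_init__(self):
        if self.k_s <= 0 or self.r0 <= 0:
            raise ValueError("spring constant and rest length must be positive")


@dataclass
class AngleBend:
    """Cosine bending term E = k_theta (1 - cos(theta - theta0)) at bead_j."""

    bead_i: int
    bead_j: int
    bead_k: int
    k_theta: float  # kT
    theta0: float  # rad

    def __post_init__(self):
        if self.k_theta <= 0:
            raise ValueError("bending constant must be positive")
        if not (0.0 < self.theta0 <= math.pi + 1e-12):
            raise ValueError("theta0 must lie in (0, pi]")


@dataclass
class WLCChain:
    """A grafted discrete wormlike chain; bead_ids[0] is the scaffold graft bead."""

    bead_ids: list
    segment_contour: float  # nm, per segment
    persistence: float  # nm
    cohesive: bool
    region: str = "channel"
    spoke: int = 0

    @property
    def motif_ids(self) -> list:
        return self.bead_ids[1:]

    @property
    def n_segments(self) -> int:
        return len(self.bead_ids) - 1


@dataclass
class ScaffoldMaterial:
    """Elastic parameters of the NPC backbone.

    ``E_young`` (kPa) sets the linear spring constants through
    k_s = E*A/r0; ``k_bend_scaffold`` (kT) is the minimum bending
    stiffness keeping subunits assembled during transport.
    """

    E_young: float = 17.0  # kPa
    k_bend_scaffold: float = 100.0  # kT
    cross_section_area: float = 100.0  # nm^2


@dataclass
class Frame:
    """Derived planes and boundaries of the built geometry (nm)."""

    y_entry: float  # cytoplasmic entry plane (filament tips)
    y_chan_top: float  # cytoplasmic channel mouth
    y_chan_mid: float
    y_chan_bot: float  # nuclear ring plane
    y_exit: float  # distal-ring (basket exit) plane
    r_min: float
    r_end: float
    x_ne: float  # NE inner face
    x_box: float
    y_top: float
    y_bot: float


@dataclass
class NPCStructure:
    """The assembled topology: beads, bonds, angles, chains, boundaries."""

    config: GeometryConfig
    material: ScaffoldMaterial
    beads: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    chains: list = field(default_factory=list)
    pom_bond_indices: list = field(default_factory=list)
    frame: Frame | None = None

    # -- convenience accessors -------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    def n_fg_motifs(self) -> int:
        return sum(len(c.motif_ids) for c in self.chains)

    def beads_in_group(self, group: str) -> list:
        return [b.id for b in self.beads if b.group == group]

    def scaffold_beads_in_region(self, region: str) -> list:
        return [b.id for b in self.beads if b.group == "scaffold" and b.region == region]

    def check_invariants(self) -> None:
        """Raise if a structural invariant is violated."""
        in_bond = set()
        for b in self.bonds:
            in_bond.update((b.bead_i, b.bead_j))
        for c in self.chains:
            in_bond.update(c.bead_ids)
        for bead in self.beads:
            if bead.mobile and bead.id not in in_bond:
                raise ConfigurationError(f"mobile bead {bead.id} is unconnected")
            D_zeta = bead.diffusion * 1e-12 * bead.drag
            if not math.isclose(D_zeta, units.KT_J, rel_tol=1e-9):
                raise ConfigurationError(f"bead {bead.id} violates D*zeta = kT")


# ---------------------------------------------------------------------------
# parameterization helpers
# ---------------------------------------------------------------------------

def spring_constant_from_modulus(
    E_young: float, cross_section_area: float, r0: float, temperature: float = units.T_DEFAULT
) -> float:
    """Spring constant k_s = E*A/r0 in reduced units (kT/nm^2).

    ``E_young`` in kPa, ``cross_section_area`` in nm^2, ``r0`` in nm.
    """
    if E_young <= 0 or cross_section_area <= 0 or r0 <= 0:
        raise ValueError("all arguments must be positive")
    k_N_per_m = E_young * 1e3 * cross_section_area * 1e-18 / (r0 * 1e-9)
    # N/m -> J/nm^2 -> kT/nm^2
    return k_N_per_m * 1e-18 / units.kT_joules(temperature)


def lumped_bead_radius(mass_kg: float, density_g_cm3: float = units.PROTEIN_DENSITY) -> float:
    """Geometric (= hydrodynamic) radius in nm of a sphere of the given
    lumped mass at the average protein density."""
    if mass_kg <= 0 or density_g_cm3 <= 0:
        raise ValueError("mass and density must be positive")
    rho = density_g_cm3 * 1e3  # kg/m^3
    r_m = (3.0 * mass_kg / (4.0 * math.pi * rho)) ** (1.0 / 3.0)
    return r_m * 1e9


# ---------------------------------------------------------------------------
# scaffold construction
# ---------------------------------------------------------------------------

def _channel_radius(y: float, config: GeometryConfig) -> float:
    """Hourglass wall radius at axial position y (0 >= y >= -channel_length)."""
    r_min = config.channel_min_diameter / 2.0
    r_end = config.channel_end_diameter / 2.0
    half = config.channel_length / 2.0
    u = (y + half) / half  # 0 at mid-channel, +-1 at the rings
    return r_min + (r_end - r_min) * u * u


def _polyline_points(points: np.ndarray) -> np.ndarray:
    return np.asarray(points, dtype=float)


def build_scaffold(
    config: GeometryConfig, material: ScaffoldMaterial | None = None
) -> NPCStructure:
    """Build the elastic two-spoke scaffold (no FG chains yet).

    The structure is built at rest: every bond at its rest length and
    every angle at its as-built equilibrium, so the net conservative
    force on each bead is zero in the as-built configuration.
    """
    if material is None:
        material = ScaffoldMaterial()
    config.validate()
    if material.E_young <= 0:
        raise ConfigurationError("Young's modulus must be positive")
    sp = config.scaffold_bead_spacing
    smallest = min(config.filament_length, config.channel_length, config.basket_length)
    if sp > smallest:
        raise ConfigurationError(
            f"bead spacing {sp} nm exceeds the smallest subunit dimension {smallest} nm"
        )

    Lc = config.channel_length
    r_end = config.channel_end_diameter / 2.0
    r_d = config.distal_ring_diameter / 2.0
    y_exit = -Lc - config.basket_length
    x_ne = r_end + config.ne_offset
    frame = Frame(
        y_entry=config.filament_length,
        y_chan_top=0.0,
        y_chan_mid=-Lc / 2.0,
        y_chan_bot=-Lc,
        y_exit=y_exit,
        r_min=config.channel_min_diameter / 2.0,
        r_end=r_end,
        x_ne=x_ne,
        x_box=x_ne + config.box_margin,
        y_top=config.filament_length + 2.0 * config.box_margin,
        y_bot=y_exit - 1.5 * config.box_margin,
    )

    structure = NPCStructure(config=config, material=material, frame=frame)
    beads = structure.beads

    def add_bead(pos, radius, group, mobile, region) -> int:
        b = Bead(id=len(beads), position=np.asarray(pos, float), radius=radius,
                 group=group, mobile=mobile, region=region)
        beads.append(b)
        return b.id

    def n_segments(length: float) -> int:
        return max(1, round(length / sp))

    distal_ids = []
    for spoke, s in enumerate((+1.0, -1.0)):
        spoke_ids = []
        spoke_regions = []
        # cytoplasmic filament: tip down to the cytoplasmic ring
        n_f = n_segments(config.filament_length)
        for k in range(n_f):
            y = config.filament_length * (1.0 - k / n_f)
            spoke_ids.append(add_bead((s * r_end, y), config.scaffold_bead_radius,
                                      "scaffold", True, "filament"))
            spoke_regions.append("filament")
        # channel wall: cytoplasmic ring (y=0) to nuclear ring (y=-Lc)
        n_c = n_segments(Lc)
        channel_ids = []
        for k in range(n_c + 1):
            y = -Lc * k / n_c
            i = add_bead((s * _channel_radius(y, config), y),
                         config.scaffold_bead_radius, "scaffold", True, "channel")
            spoke_ids.append(i)
            spoke_regions.append("channel")
            channel_ids.append(i)
        # basket rod: nuclear ring to the distal ring
        p0 = np.array([s * r_end, -Lc])
        p1 = np.array([s * r_d, y_exit])
        n_b = n_segments(float(np.linalg.norm(p1 - p0)))
        for k in range(1, n_b + 1):
            p = p0 + (p1 - p0) * k / n_b
            spoke_ids.append(add_bead(p, config.scaffold_bead_radius,
                                      "scaffold", True, "basket"))
            spoke_regions.append("basket")

        # bonds and angles along the spoke polyline, at rest as built
        for a, b in zip(spoke_ids[:-1], spoke_ids[1:]):
            r0 = float(np.linalg.norm(beads[a].position - beads[b].position))
            k_s = spring_constant_from_modulus(
                material.E_young, material.cross_section_area, r0)
            structure.bonds.append(BondSpring(a, b, k_s, r0))
        for a, b, c in zip(spoke_ids[:-2], spoke_ids[1:-1], spoke_ids[2:]):
            v1 = beads[a].position - beads[b].position
            v2 = beads[c].position - beads[b].position
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta0 = math.acos(max(-1.0, min(1.0, cosang)))
            structure.angles.append(
                AngleBend(a, b, c, material.k_bend_scaffold, theta0))

        # pom springs: each channel-wall bead anchored to the rigid NE face
        for i in channel_ids:
            pos = beads[i].position
            anchor = add_bead((s * x_ne, pos[1]), config.scaffold_bead_radius,
                              "pom_anchor", False, "anchor")
            r0 = float(abs(s * x_ne - pos[0]))
            k_s = spring_constant_from_modulus(
                material.E_young, material.cross_section_area, r0)
            structure.bonds.append(BondSpring(i, anchor, k_s, r0))
            structure.pom_bond_indices.append(len(structure.bonds) - 1)

        distal_ids.append(spoke_ids[-1])

    # distal-ring closure between the two rod ends
    a, b = distal_ids
    r0 = float(np.linalg.norm(beads[a].position - beads[b].position))
    k_s = spring_constant_from_modulus(
        material.E_young, material.cross_section_area, r0)
    structure.bonds.append(BondSpring(a, b, k_s, r0))

    return structure


# ---------------------------------------------------------------------------
# FG-chain grafting
# ---------------------------------------------------------------------------

def _chain_plan(config: GeometryConfig):
    """Per-region chain counts realizing exactly fg_total_motifs motifs.

    Returns a list of (region, contour, n_chains_per_spoke, motifs_per_chain).
    """
    plans = []
    contours = {"filament": config.fg_peripheral_contour,
                "channel": config.fg_central_contour,
                "basket": config.fg_peripheral_contour}
    total = 0
    for region, frac in zip(("filament", "channel", "basket"), config.fg_region_split):
        contour = contours[region]
        per_chain = round(contour / config.fg_segment_length)
        if per_chain < 1:
            raise ConfigurationError(
                f"{region}: segment length {config.fg_segment_length} nm exceeds "
                f"the chain contour {contour} nm")
        motifs = config.fg_total_motifs * frac
        n_chains = round(motifs / per_chain)
        per_spoke, rem = divmod(n_chains, config.n_spokes)
        if rem or per_spoke < 1:
            raise ConfigurationError(
                f"{region}: cannot split {n_chains} chains over "
                f"{config.n_spokes} spokes")
        plans.append((region, contour, per_spoke, per_chain))
        total += per_spoke * config.n_spokes * per_chain
    if total != config.fg_total_motifs:
        raise ConfigurationError(
            f"requested {config.fg_total_motifs} FG motifs but the chain plan "
            f"realizes {total}; adjust fg_total_motifs or the discretization")
    return plans


def graft_fg_chains(
    structure: NPCStructure,
    config: GeometryConfig | None = None,
    l_p: float = 0.43,
    seed: int = 0,
) -> NPCStructure:
    """Attach discrete WLC FG-repeat chains to the scaffold (in place).

    Chains are discretized into ``contour/segment_length`` segments with
    one FG-motif bead per segment endpoint; initial conformations are
    seeded self-avoiding random walks at 80% segment extension.  Central
    (channel) chains are cohesive; filament and basket chains are not.
    """
    if config is None:
        config = structure.config
    if config.fg_segment_length < 10.0 * l_p:
        raise ConfigurationError(
            f"WLC discretization requires segment length >= 10 persistence "
            f"lengths ({10 * l_p:.2f} nm); got {config.fg_segment_length} nm")
    rng = np.random.default_rng(seed)
    plans = _chain_plan(config)
    frame = structure.frame
    beads = structure.beads

    def blocked(p) -> bool:
        if abs(p[0]) > frame.x_box or p[1] > frame.y_top or p[1] < frame.y_bot:
            return True
        return (abs(p[0]) >= frame.x_ne
                and frame.y_chan_bot <= p[1] <= frame.y_chan_top)

    for region, contour, per_spoke, per_chain in plans:
        cohesive = region == "channel"
        group = "fg_central" if cohesive else "fg_peripheral"
        for s_idx, s in enumerate((+1.0, -1.0)):
            sites = [i for i in structure.scaffold_beads_in_region(region)
                     if (beads[i].position[0] > 0) == (s > 0)]
            if not sites:
                raise ConfigurationError(f"no graft sites in region {region}")
            for c in range(per_spoke):
                graft = sites[(c * len(sites)) // per_spoke]
                ids = [graft]
                prev = beads[graft].position.copy()
                # bias the walk off the scaffold: channel chains point
                # inward, peripheral chains away from the structure
                if region == "channel":
                    direction = np.array([-s, 0.0])
                elif region == "filament":
                    direction = np.array([0.0, 1.0])
                else:
                    direction = np.array([0.0, -1.0])
                step = 0.8 * config.fg_segment_length
                placed = [prev]
                for _ in range(per_chain):
                    for _try in range(25):
                        ang = math.atan2(direction[1], direction[0])
                        ang += rng.uniform(-2.2, 2.2)
                        cand = prev + step * np.array([math.cos(ang), math.sin(ang)])
                        if blocked(cand):
                            continue
                        if any(np.linalg.norm(cand - q) < 1.0 for q in placed[:-1]):
                            continue
                        break
                    else:
                        cand = prev + step * direction
                    b = Bead(id=len(beads), position=cand,
                             radius=config.fg_bead_radius, group=group,
                             mobile=True, region=region)
                    beads.append(b)
                    ids.append(b.id)
                    direction = (cand - prev) / max(1e-12, np.linalg.norm(cand - prev))
                    placed.append(cand)
                    prev = cand
                structure.chains.append(WLCChain(
                    bead_ids=ids, segment_contour=config.fg_segment_length,
                    persistence=l_p, cohesive=cohesive, region=region, spoke=s_idx))
    assert structure.n_fg_motifs() == config.fg_total_motifs
    return structure


def build_npc(config: GeometryConfig | None = None,
              material: ScaffoldMaterial | None = None,
              l_p: float = 0.43, seed: int = 0) -> NPCStructure:
    """Build the full default NPC: scaffold plus grafted FG chains."""
    if config is None:
        config = GeometryConfig()
    structure = build_scaffold(config, material)
    return graft_fg_chains(structure, config, l_p=l_p, seed=seed)


# ---------------------------------------------------------------------------
# structure surgery
# ---------------------------------------------------------------------------

def remove_filaments(structure: NPCStructure) -> NPCStructure:
    """Return a copy without cytoplasmic filaments or their FG chains.

    Filament scaffold beads, their bonds and angles, and every chain
    grafted on a filament bead are dropped; channel and basket subunits
    are untouched and bead ids are compacted.
    """
    import warnings

    fil_beads = set(structure.scaffold_beads_in_region("filament"))
    if not fil_beads:
        warnings.warn("structure has no cytoplasmic filaments; returning a copy")
    drop = set(fil_beads)
    kept_chains = []
    for c in structure.chains:
        if c.bead_ids[0] in fil_beads:
            drop.update(c.motif_ids)
        else:
            kept_chains.append(c)

    keep = [b.id for b in structure.beads if b.id not in drop]
    remap = {old: new for new, old in enumerate(keep)}

    new = NPCStructure(config=structure.config, material=structure.material,
                       frame=structure.frame)
    for old in keep:
        b = structure.beads[old]
        new.beads.append(replace(b, id=remap[old], position=b.position.copy()))
    for b in structure.bonds:
        if b.bead_i in drop or b.bead_j in drop:
            continue
        new.bonds.append(BondSpring(remap[b.bead_i], remap[b.bead_j], b.k_s, b.r0))
    # recompute pom indices by membership
    anchors = {b.id for b in new.beads if b.group == "pom_anchor"}
    new.pom_bond_indices = [k for k, b in enumerate(new.bonds)
                            if b.bead_i in anchors or b.bead_j in anchors]
    for a in structure.angles:
        if a.bead_i in drop or a.bead_j in drop or a.bead_k in drop:
            continue
        new.angles.append(AngleBend(remap[a.bead_i], remap[a.bead_j],
                                    remap[a.bead_k], a.k_theta, a.theta0))
    for c in kept_chains:
        new.chains.append(WLCChain(
            bead_ids=[remap[i] for i in c.bead_ids],
            segment_contour=c.segment_contour, persistence=c.persistence,
            cohesive=c.cohesive, region=c.region, spoke=c.spoke))
    return new
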