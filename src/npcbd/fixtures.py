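"""Named miniature systems for tests, demos and physics validation.

Every fixture builds deterministically and runs in seconds:

* ``free_bead`` — n non-interacting beads in a huge box (diffusion and
  noise-scaling checks),
* ``harmonic_well`` — one bead tethered to a fixed anchor by a zero-rest
  harmonic spring (Boltzmann-sampling check),
* ``single_wlc_chain`` — one tethered discrete WLC, 5 segments x 10 nm,
  l_p 0.43 nm (finite-extensibility check),
* ``mini_npc`` — a shortened NPC (60 nm span, 120 FG motifs) with the
  full interaction set: the desk-scale surrogate for transport runs.
"""

from __future__ import annotations

import numpy as np

from . import geometry, units
from .forcefield import InteractionRuleSet
from .geometry import (Bead, BondSpring, Frame, GeometryConfig, NPCStructure,
                       ScaffoldMaterial, WLCChain)

FIXTURES = ("free_bead", "harmonic_well", "single_wlc_chain", "mini_npc")

_BIG = 1e6


def _open_frame() -> Frame:
    return Frame(y_entry=0.0, y_chan_top=_BIG, y_chan_mid=0.0,
                 y_chan_bot=-_BIG, y_exit=-2 * _BIG, r_min=_BIG, r_end=_BIG,
                 x_ne=2 * _BIG, x_box=_BIG, y_top=_BIG, y_bot=-_BIG)


def _bare_structure() -> NPCStructure:
    cfg = GeometryConfig()
    return NPCStructure(config=cfg, material=ScaffoldMaterial(),
                        frame=_open_frame())


def free_bead(n: int = 1, radius: float = 0.9, spacing: float = 100.0
              ) -> NPCStructure:
    """n isolated beads on a wide grid; no bonds, no walls in reach.

    The default radius gives the FG-bead diffusion coefficient of
    50 um^2/s; interactions are irrelevant at 100 nm spacing.
    """
    s = _bare_structure()
    side = int(np.ceil(np.sqrt(n)))
    for k in range(n):
        pos = (spacing * (k % side), spacing * (k // side))
        s.beads.append(Bead(id=k, position=np.array(pos, float),
                            radius=radius, group="scaffold", mobile=True))
    # free beads are deliberately unconnected; skip the connectivity check
    return s


def harmonic_well(k_s: float = 1.0, radius: float = 0.9) -> NPCStructure:
    """One mobile bead tied to a fixed anchor: E = 1/2 k_s r^2 per run.

    The rest length is (effectively) zero so positional variance per
    dimension must equal kT/k_s = 1/k_s nm^2 in reduced units.
    """
    s = _bare_structure()
    s.beads.append(Bead(id=0, position=np.zeros(2), radius=radius,
                        group="pom_anchor", mobile=False))
    s.beads.append(Bead(id=1, position=np.zeros(2), radius=radius,
                        group="scaffold", mobile=True))
    # tiny rest length: BondSpring requires r0 > 0; 1e-9 nm is zero in practice
    s.bonds.append(BondSpring(0, 1, k_s, 1e-9))
    return s


def single_wlc_chain(n_segments: int = 5, segment: float = 10.0,
                     l_p: float = 0.43, initial_extension: float = 0.8
                     ) -> NPCStructure:
    """A tethered discrete WLC dangling from a fixed graft bead."""
    s = _bare_structure()
    s.beads.append(Bead(id=0, position=np.zeros(2), radius=0.9,
                        group="pom_anchor", mobile=False))
    ids = [0]
    for k in range(1, n_segments + 1):
        s.beads.append(Bead(id=k,
                            position=np.array([initial_extension * segment * k, 0.0]),
                            radius=0.9, group="fg_peripheral", mobile=True))
        ids.append(k)
    s.chains.append(WLCChain(bead_ids=ids, segment_contour=segment,
                             persistence=l_p, cohesive=False,
                             region="filament"))
    return s


def mini_npc_config() -> GeometryConfig:
    """Geometry of the desk-scale surrogate NPC (60 nm transport span).

    Scaled for geometric similarity with the full pore: the peripheral
    chain contour is ~2x the mouth diameter and the cargo/channel
    diameter ratio is preserved, so the FG brush at the mouth remains an
    effective entry barrier at the reduced scale.
    """
    return GeometryConfig(
        channel_min_diameter=26.0, channel_end_diameter=32.0,
        channel_length=24.0, filament_length=16.0, basket_length=20.0,
        distal_ring_diameter=16.0, transport_span=60.0,
        scaffold_bead_spacing=8.0, fg_total_motifs=144,
        fg_central_contour=20.0, fg_peripheral_contour=60.0,
        fg_segment_length=10.0, ne_offset=8.0, box_margin=25.0)


def mini_npc(seed: int = 0, l_p: float = 0.43) -> NPCStructure:
    """Shortened two-spoke NPC with grafted FG chains."""
    return geometry.build_npc(mini_npc_config(), l_p=l_p, seed=seed)


def make_fixture(name: str, **overrides):
    """Build a named fixture; unknown names raise with the known list."""
    builders = {"free_bead": free_bead, "harmonic_well": harmonic_well,
                "single_wlc_chain": single_wlc_chain, "mini_npc": mini_npc}
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return builders[name](**overrides)


def default_rules() -> InteractionRuleSet:
    return InteractionRuleSet()
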