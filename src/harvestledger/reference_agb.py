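"""Harvest-derived reference above-ground biomass (dry mass).

Reference AGB is the weighed green mass converted to dry mass with the
mass-weighted green-to-dry mass ratio, plus a partial correction for wood
lost as chainsaw swarf. Each manageable stem section costs one kerf,
modelled as a cylinder of the section's representative diameter and the
measured mean cut width; the crown is deliberately left uncorrected, so
the correction is a lower bound on true losses.

A geometric cross-check converts stem section length/diameter records to
green mass via Smalian's formula (length times mean end cross-sectional
area) and the green woody tissue density; Smalian's formula overestimates
the volume of any tapered (conical-frustum) section, which is why weighed
reference mass is preferred over geometry-derived mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .density import DensityEstimate
from .errors import DomainError, EstimationError
from .harvest_data import CROWN, STEM, HarvestTree, Section

logger = logging.getLogger(__name__)

#: Mean chainsaw kerf width (m) measured with calipers in the field
#: campaign; ~60 % thicker than the chain loop itself.
DEFAULT_CUT_WIDTH = 0.0084


@dataclass
class ReferenceAGB:
    """Reference dry mass of one tree with its swarf bookkeeping (kg)."""

    tree_id: str
    agb_ref: float
    pool_dry_mass: dict[str, float] = field(default_factory=dict)
    swarf_correction: float = 0.0
    swarf_fraction: float = 0.0          # % of uncorrected AGB
    crown_mass_ratio: float = 0.0        # crown dry mass / AGB_ref

    @property
    def stem_mass_ratio(self) -> float:
        return 1.0 - self.crown_mass_ratio


def pool_dry_mass(pool_green_mass: float, ratio: float) -> float:
    """Convert a weighed pool green mass to dry mass: green / ratio."""
    if ratio < 1.0:
        raise DomainError(f"g2d mass ratio {ratio} < 1")
    if pool_green_mass < 0:
        raise DomainError("green mass must be >= 0")
    return pool_green_mass / ratio


def swarf_cut_volume(section_diameter: float,
                     cut_width: float = DEFAULT_CUT_WIDTH) -> float:
    """Green volume (m3) of one chainsaw kerf, as a cylinder slice."""
    if not section_diameter > 0:
        raise DomainError("section diameter must be > 0")
    if cut_width < 0:
        raise DomainError("cut width must be >= 0")
    return math.pi * (section_diameter / 2.0) ** 2 * cut_width


def swarf_dry_mass(cut_volumes: Sequence[float], green_density: float,
                   ratio: float) -> float:
    """Dry mass (kg) lost in kerfs of the given green volumes.

    ``green_density`` is the green woody tissue density, i.e. basic density
    times the g2d mass ratio; dividing back by the ratio makes the lost dry
    mass exactly ``sum(V) * basic_density``.
    """
    if ratio < 1.0:
        raise DomainError(f"g2d mass ratio {ratio} < 1")
    if green_density < 0:
        raise DomainError("green density must be >= 0")
    return sum(cut_volumes) * green_density / ratio


def stem_cut_volumes(tree: HarvestTree,
                     cut_width: float = DEFAULT_CUT_WIDTH,
                     extra_cuts: int = 0) -> list[float]:
    """Kerf volumes for the stem: one cut per stem section by default.

    Whether N sections imply N or N-1 physical cuts is a field-protocol
    detail; ``extra_cuts`` (may be negative) drops or repeats the last
    section's kerf accordingly.
    """
    volumes = []
    for s in tree.stem_sections():
        d = s.representative_diameter()
        if d is None:
            logger.warning("tree %s: stem section without diameters skipped "
                           "in swarf estimate", tree.tree_id)
            continue
        volumes.append(swarf_cut_volume(d, cut_width))
    if volumes and extra_cuts:
        if extra_cuts > 0:
            volumes.extend([volumes[-1]] * extra_cuts)
        else:
            volumes = volumes[:max(0, len(volumes) + extra_cuts)]
    return volumes


def reference_agb(tree: HarvestTree, density: DensityEstimate,
                  cut_width: float = DEFAULT_CUT_WIDTH,
                  extra_cuts: int = 0) -> ReferenceAGB:
    """Assemble the reference AGB of one tree.

    ``density`` must be a mass-weighted estimate carrying both the basic
    density and the g2d mass ratio. The swarf correction is assigned to the
    stem pool, so the crown mass ratio uses uncorrected crown dry mass over
    corrected total.
    """
    ratio = density.g2d_mass_ratio
    if ratio is None:
        raise EstimationError("reference AGB needs a g2d mass ratio")
    pools = {pool: pool_dry_mass(m, ratio)
             for pool, m in tree.pool_green_mass.items()}

    volumes = stem_cut_volumes(tree, cut_width, extra_cuts)
    if not volumes:
        logger.warning("tree %s: no stem sections with diameters; swarf "
                       "correction set to 0", tree.tree_id)
        swarf = 0.0
    else:
        swarf = swarf_dry_mass(volumes, density.green_density, ratio)

    uncorrected = sum(pools.values())
    agb = uncorrected + swarf
    crown = pools.get(CROWN, 0.0)
    return ReferenceAGB(
        tree_id=tree.tree_id,
        agb_ref=agb,
        pool_dry_mass=pools,
        swarf_correction=swarf,
        swarf_fraction=100.0 * swarf / uncorrected if uncorrected > 0 else 0.0,
        crown_mass_ratio=crown / agb if agb > 0 else 0.0,
    )


def smalian_section_volume(length: float, d1: float, d2: float) -> float:
    """Smalian's formula: V = L (A1 + A2) / 2 with Ai = pi (di/2)^2.

    Exact for cylinders and paraboloids; for a conical frustum it
    overestimates (arithmetic vs full mean of the end areas).
    """
    if not (length > 0 and d1 >= 0 and d2 >= 0) or (d1 == 0 and d2 == 0):
        raise DomainError("smalian volume needs positive dimensions")
    a1 = math.pi * (d1 / 2.0) ** 2
    a2 = math.pi * (d2 / 2.0) ** 2
    return length * (a1 + a2) / 2.0


def frustum_volume(length: float, d1: float, d2: float) -> float:
    """True volume of a conical frustum with end diameters d1, d2."""
    if not (length > 0 and d1 >= 0 and d2 >= 0):
        raise DomainError("frustum volume needs positive dimensions")
    r1, r2 = d1 / 2.0, d2 / 2.0
    return math.pi * length / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)


def geometric_stem_mass_error(tree: HarvestTree,
                              green_density: float) -> float:
    """Percentage error of Smalian-derived stem green mass vs weighed mass.

    Positive values mean geometry overestimates the weighed stem mass.
    Sections lacking length or either diameter are excluded (their weighed
    mass too), with a logged coverage warning.
    """
    if not green_density > 0:
        raise DomainError("green density must be > 0")
    geo = 0.0
    weighed = 0.0
    skipped = 0
    for s in tree.stem_sections():
        if (s.length is None or s.end_diameter_1 is None
                or s.end_diameter_2 is None):
            skipped += 1
            continue
        geo += smalian_section_volume(s.length, s.end_diameter_1,
                                      s.end_diameter_2) * green_density
        weighed += s.green_mass
    if skipped:
        logger.warning("tree %s: %d stem section(s) lacked geometry and were "
                       "excluded from the Smalian check", tree.tree_id, skipped)
    if not weighed > 0:
        raise EstimationError(
            f"tree {tree.tree_id}: no weighed stem mass with geometry")
    return 100.0 * (geo - weighed) / weighed
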