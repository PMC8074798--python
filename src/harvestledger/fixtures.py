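"""Published values from a four-tree destructive harvest campaign.

These are the tree-level aggregates reported for four large tropical
rainforest trees (T1-T4) harvested in an old-growth terra-firme stand at
Caxiuana National Forest, eastern Amazonia, together with the performance
of the two non-destructive estimators evaluated against them (terrestrial
lidar QSM volume x density, and pan-tropical allometry). Only tree-level
aggregates were published, so the fixtures carry no per-section or
per-subsample detail.

The campaign reports masses in kg, densities in kg m-3, D in m and H in m.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CampaignTree:
    """Tree-level aggregates for one harvested tree."""

    tree_id: str
    species: str
    latitude: float
    longitude: float
    stem_diameter_m: float
    diameter_protocol: str
    height_m: float
    above_ground_green_mass: float          # kg
    agb_ref: float                          # kg dry, incl. swarf correction
    density_mass_weighted: float            # kg m-3
    density_stem: float                     # kg m-3
    density_literature: float               # kg m-3
    g2d_mass_ratio: float
    g2d_volume_ratio: float
    swarf_correction: float                 # kg dry
    stem_mass_fraction_harvest: float       # fraction of AGB_ref in the stem
    stem_mass_fraction_lidar: float         # fraction of lidar AGB_est in stem
    crown_to_tree_height_ratio: float
    crown_aspect_ratio: float


@dataclass(frozen=True)
class CampaignEstimate:
    """Published non-destructive AGB estimates for one tree (kg)."""

    tree_id: str
    agb_ref: float
    agb_lidar: float
    agb_allometric: float


def four_tree_fixture() -> list[CampaignTree]:
    """The harvested-tree aggregates, in campaign order T1-T4."""
    return [
        CampaignTree("T1", "Inga alba", -1.79851, -51.43463, 0.647, "above_buttress",
                     29.8, 6808.2, 3960.1, 567.6, 574.6, 586.1, 1.731, 1.169,
                     27.7, 0.48, 0.48, 0.55, 1.15),
        CampaignTree("T2", "Hymenaea courbaril", -1.79832, -51.43479, 1.179,
                     "above_buttress", 46.2, 29511.0, 18584.2, 768.9, 786.7,
                     792.4, 1.617, 1.126, 330.2, 0.58, 0.62, 0.40, 1.63),
        CampaignTree("T3", "Tachigali paniculata var. alba", -1.79914, -51.43451,
                     0.905, "above_buttress", 34.9, 13697.5, 8392.6, 639.0,
                     655.1, 554.5, 1.643, 1.137, 58.1, 0.38, 0.42, 0.54, 1.18),
        CampaignTree("T4", "Trattinnickia burserifolia", -1.79550, -51.43433,
                     0.697, "dbh", 35.2, 8988.6, 5521.1, 567.0, 561.9, 460.0,
                     1.640, 1.113, 41.0, 0.41, 0.47, 0.56, 1.44),
    ]


def four_tree_estimates_fixture() -> list[CampaignEstimate]:
    """Published reference and estimated AGB per tree (kg)."""
    return [
        CampaignEstimate("T1", 3960.1, 3673.8, 3644.9),
        CampaignEstimate("T2", 18584.2, 18414.5, 24261.0),
        CampaignEstimate("T3", 8392.6, 8604.6, 9190.9),
        CampaignEstimate("T4", 5521.1, 5485.1, 4953.7),
    ]


#: Maximum intra-tree subsample density difference per tree (kg m-3),
#: as reported from the disc profiles.
MAX_INTRA_TREE_DENSITY_DIFFERENCE = {"T1": 40.0, "T2": 79.0, "T3": 166.0,
                                     "T4": 156.0}

#: Percentage error of Smalian-formula geometric stem green mass vs the
#: weighed stem green mass, per tree.
GEOMETRIC_STEM_MASS_ERROR_PCT = {"T1": -1.0, "T2": 7.0, "T3": 11.0, "T4": 11.0}
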