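"""Green-to-dry ratios and above-ground basic woody tissue density.

The quantity that converts a green (water-saturated) woody volume into a
dry mass is the *basic* density, dry mass over green volume. A whole-tree
value must average over all woody tissues and over the substantial
intra-tree variation of their density with height and radius. Three
estimation approaches are implemented:

``mass_weighted``
    Subsample-mean basic density per pool (stem, crown), weighted by each
    pool's weighed green mass. This most closely tracks the definition and
    is the reference approach.
``stem``
    Mean of the two outer subsamples of the breast-height stem disc,
    mimicking a non-destructive increment-borer core.
``literature``
    Mean of species-level entries in a wood-density reference table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (ConfigurationError, DensityLookupError, DomainError,
                     EstimationError)
from .harvest_data import (CROWN, STEM, Disc, HarvestTree, Subsample)

logger = logging.getLogger(__name__)

MASS_WEIGHTED = "mass_weighted"
STEM_APPROACH = "stem"
LITERATURE = "literature"
APPROACHES = (MASS_WEIGHTED, STEM_APPROACH, LITERATURE)

#: Sanity band for whole-tree basic density (kg m-3); values outside it
#: almost certainly indicate a unit error upstream.
DENSITY_SANITY_BAND = (50.0, 1500.0)

#: g cm-3 -> kg m-3
_G_CM3_TO_KG_M3 = 1000.0


@dataclass
class DensityEstimate:
    """A whole-tree above-ground basic woody tissue density (kg m-3)."""

    tree_id: str
    approach: str
    basic_density: float
    g2d_mass_ratio: float | None = None
    g2d_volume_ratio: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        lo, hi = DENSITY_SANITY_BAND
        if not lo < self.basic_density < hi:
            raise DomainError(
                f"tree {self.tree_id}: basic density {self.basic_density:.1f} "
                f"kg m-3 outside sanity band ({lo}, {hi})"
            )
        for r in (self.g2d_mass_ratio, self.g2d_volume_ratio):
            if r is not None and r < 1.0:
                raise DomainError(
                    f"tree {self.tree_id}: green-to-dry ratio {r} < 1"
                )

    @property
    def green_density(self) -> float:
        """Green woody tissue density = basic density x g2d mass ratio."""
        if self.g2d_mass_ratio is None:
            raise EstimationError("green density requires a g2d mass ratio")
        return self.basic_density * self.g2d_mass_ratio


@dataclass
class DensityProfile:
    """Per-disc-location density summaries plus the tree-level spread."""

    tree_id: str
    locations: dict[str, dict[str, float]] = field(default_factory=dict)
    max_pairwise_difference: float = 0.0


def subsample_basic_density(s: Subsample) -> float:
    """Basic density of one subsample in kg m-3 (dry g / green cm3 x 1000)."""
    if s.green_volume is None:
        raise DomainError("green volume not measured and not imputed")
    if not s.green_volume > 0:
        raise DomainError("green volume must be > 0")
    return s.dry_mass / s.green_volume * _G_CM3_TO_KG_M3


def g2d_mass_ratio(green_mass: float, dry_mass: float) -> float:
    """Green-to-dry mass ratio; >1 encodes moisture content."""
    if not (green_mass > 0 and dry_mass > 0):
        raise DomainError("masses must be > 0")
    ratio = green_mass / dry_mass
    if ratio < 1.0:
        logger.warning("green mass below dry mass (ratio %.3f): physically "
                       "odd but not fatal", ratio)
    return ratio


def g2d_volume_ratio(green_volume: float, dry_volume: float) -> float:
    """Green-to-dry volume ratio; >1 encodes drying shrinkage."""
    if not (green_volume > 0 and dry_volume > 0):
        raise DomainError("volumes must be > 0")
    return green_volume / dry_volume


def moisture_content(ratio: float) -> float:
    """Water fraction of green mass implied by a g2d mass ratio: 1 - 1/ratio."""
    if ratio < 1.0:
        raise DomainError(f"g2d mass ratio {ratio} < 1")
    return 1.0 - 1.0 / ratio


def impute_green_volume(dry_volume: float, mean_g2d_volume_ratio: float) -> float:
    """Reconstruct a green volume from dry volume and a mean swelling ratio."""
    if not dry_volume > 0:
        raise DomainError("dry volume must be > 0")
    if mean_g2d_volume_ratio < 1.0:
        raise DomainError("g2d volume ratio must be >= 1")
    return dry_volume * mean_g2d_volume_ratio


def impute_missing_green_volumes(tree: HarvestTree,
                                 fallback_ratio: float | None = None) -> int:
    """Fill missing subsample green volumes in place.

    The reference swelling ratio is the mean g2d volume ratio over all
    subsamples of the same tree that measured both volumes; if the tree has
    none, ``fallback_ratio`` (e.g. a campaign-level mean) is used with a
    logged warning. Returns the number of imputed subsamples.
    """
    measured = [g2d_volume_ratio(s.green_volume, s.dry_volume)
                for d in tree.discs for s in d.subsamples
                if s.green_volume is not None]
    if measured:
        ratio = sum(measured) / len(measured)
    elif fallback_ratio is not None:
        logger.warning("tree %s: no measured green volumes; imputing with "
                       "campaign-level ratio %.3f", tree.tree_id, fallback_ratio)
        ratio = fallback_ratio
    else:
        missing = any(s.green_volume is None
                      for d in tree.discs for s in d.subsamples)
        if not missing:
            return 0
        raise ConfigurationError(
            f"tree {tree.tree_id}: green volumes missing and no reference "
            "subsamples or fallback ratio available"
        )
    n = 0
    for d in tree.discs:
        for s in d.subsamples:
            if s.green_volume is None:
                s.green_volume = impute_green_volume(s.dry_volume, ratio)
                s.imputed_green_volume = True
                n += 1
    return n


def pool_mean(values: Sequence[float], pool: str = "") -> float:
    """Unweighted arithmetic mean of a per-subsample statistic over a pool."""
    if len(values) == 0:
        raise EstimationError(f"no subsamples in pool {pool!r}")
    return float(sum(values)) / len(values)


def mass_weighted_estimate(pool_means: Mapping[str, float],
                           pool_green_mass: Mapping[str, float]) -> float:
    """Green-mass-weighted combination of pool-level means.

    ``sum_i m_i x_i / sum_i m_i`` over the pools present in both maps.
    """
    if set(pool_means) != set(pool_green_mass):
        raise EstimationError(
            f"pool keys differ: {sorted(pool_means)} vs "
            f"{sorted(pool_green_mass)}"
        )
    total = float(sum(pool_green_mass.values()))
    if not total > 0:
        raise DomainError("total pool green mass must be > 0")
    if any(m < 0 for m in pool_green_mass.values()):
        raise DomainError("pool green masses must be >= 0")
    return sum(pool_means[p] * pool_green_mass[p] for p in pool_means) / total


def _pool_subsample_stat(tree: HarvestTree, stat) -> dict[str, float]:
    out: dict[str, float] = {}
    for pool in tree.pool_green_mass:
        values = [stat(s) for d in tree.discs_in_pool(pool)
                  for s in d.subsamples]
        out[pool] = pool_mean(values, pool)
    return out


def mass_weighted_density(tree: HarvestTree) -> DensityEstimate:
    """The mass-weighted whole-tree density and green-to-dry ratios."""
    masses = tree.pool_green_mass
    rho = mass_weighted_estimate(
        _pool_subsample_stat(tree, subsample_basic_density), masses)
    qm = mass_weighted_estimate(
        _pool_subsample_stat(tree, lambda s: g2d_mass_ratio(s.green_mass,
                                                            s.dry_mass)),
        masses)
    qv = mass_weighted_estimate(
        _pool_subsample_stat(
            tree, lambda s: g2d_volume_ratio(s.green_volume, s.dry_volume)),
        masses)
    return DensityEstimate(tree.tree_id, MASS_WEIGHTED, rho, qm, qv,
                           provenance="pool subsample means weighted by "
                                      "pool green mass")


def stem_estimate(tree: HarvestTree) -> DensityEstimate:
    """Increment-borer mimic: mean of the two outer subsamples at 1.3 m."""
    disc = tree.disc_by_class("SD1")
    if disc is None:
        raise EstimationError(
            f"tree {tree.tree_id}: no breast-height (SD1) stem disc")
    if len(disc.subsamples) < 2:
        raise EstimationError(
            f"tree {tree.tree_id}: SD1 disc needs >= 2 subsamples")
    outer = [disc.subsamples[0], disc.subsamples[-1]]
    rho = pool_mean([subsample_basic_density(s) for s in outer], "SD1 outer")
    return DensityEstimate(tree.tree_id, STEM_APPROACH, rho,
                           provenance="mean of the two outer SD1 subsamples")


def literature_estimate(species: str, density_db: pd.DataFrame,
                        tree_id: str = "") -> DensityEstimate:
    """Mean of species-level matches in a wood-density reference table.

    Matching is exact on the species string after case folding and
    whitespace normalisation; there is deliberately no genus fallback.
    """
    def norm(s: str) -> str:
        return " ".join(str(s).split()).casefold()

    target = norm(species)
    matches = density_db[density_db["species"].map(norm) == target]
    if matches.empty:
        raise DensityLookupError(
            f"species {species!r} not found in density table")
    rho = float(matches["basic_density_kg_m3"].mean())
    return DensityEstimate(tree_id or species, LITERATURE, rho,
                           provenance=f"mean of {len(matches)} species-level "
                                      "entries")


def estimate_density(tree: HarvestTree, approach: str,
                     density_db: pd.DataFrame | None = None) -> DensityEstimate:
    """Dispatch to one of the three estimation approaches."""
    if approach == MASS_WEIGHTED:
        return mass_weighted_density(tree)
    if approach == STEM_APPROACH:
        return stem_estimate(tree)
    if approach == LITERATURE:
        if density_db is None:
            raise ConfigurationError(
                "literature approach requires a density table")
        return literature_estimate(tree.species, density_db, tree.tree_id)
    raise ConfigurationError(f"unknown density approach {approach!r}")


def density_profile(tree: HarvestTree) -> DensityProfile:
    """Per-location density summaries and the tree-level max difference."""
    profile = DensityProfile(tree.tree_id)
    all_values: list[float] = []
    for disc in tree.discs:
        values = [subsample_basic_density(s) for s in disc.subsamples]
        all_values.extend(values)
        loc = profile.locations.setdefault(
            disc.location_class,
            {"mean": 0.0, "min": math.inf, "max": -math.inf, "n": 0})
        n_old = loc["n"]
        loc["mean"] = (loc["mean"] * n_old + sum(values)) / (n_old + len(values))
        loc["min"] = min(loc["min"], min(values))
        loc["max"] = max(loc["max"], max(values))
        loc["n"] = n_old + len(values)
    if all_values:
        profile.max_pairwise_difference = max(all_values) - min(all_values)
    return profile


def percent_difference(a: float, b: float, form: str = "symmetric") -> float:
    """Percentage difference between two positive values.

    The default symmetric form divides by the mean of the two values,
    ``100 |a-b| / ((a+b)/2)``; ``form='relative'`` divides by ``a``.
    """
    if not (a > 0 and b > 0):
        raise DomainError("percent difference requires positive inputs")
    if form == "symmetric":
        return 100.0 * abs(a - b) / ((a + b) / 2.0)
    if form == "relative":
        return 100.0 * abs(a - b) / a
    raise ConfigurationError(f"unknown percent-difference form {form!r}")
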