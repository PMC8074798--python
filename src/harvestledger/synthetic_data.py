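"""Synthetic trees with known ground truth for every pipeline stage.

The generator emulates a destructive harvest campaign on large tropical
trees: a vertically tapering stem (stacked conical frusta) up to a first
fork, a recursive branching crown (orders 1-3), a woody-tissue basic
density field varying linearly with relative height and radius, weighing
of stem sections and crown sacks on a crane scale with finite division,
chainsaw-kerf swarf removal, the disc/subsample laboratory protocol
(four stem discs, branch-order discs, outer/inner blocks), and a QSM whose
total volume carries a multiplicative, size-independent lognormal error.

Defaults are calibrated to the published four-tree campaign: stem diameter
0.6-1.2 m, height ~30-46 m, whole-tree basic density 560-770 kg m-3,
green-to-dry mass ratio 1.60-1.75, crown mass fraction 0.42-0.62, scale
division 0.1 kg, kerf width 8.4 mm. Every stochastic choice flows from a
single integer seed through per-tree substreams, so cohorts are
reproducible and insensitive to generation order.

Swarf is modelled with the tree-level mass-weighted density (not the local
density at each cut), which makes the harvest bookkeeping exactly
self-consistent: with all noise terms at zero, the pipeline's
reference AGB reproduces the generator's true dry mass to machine
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import density as density_mod
from .agb_estimators import (AllometricModel, DEFAULT_ALLOMETRIC_MODEL,
                             QSMModel, allometric_agb, qsm_agb)
from .density import mass_weighted_density
from .errors import ConfigurationError
from .harvest_data import (CROWN, Disc, HarvestTree, INNER, OUTER, STEM,
                           Section, Subsample)
from .reference_agb import swarf_cut_volume

__all__ = [
    "SyntheticConfig", "SyntheticTruth", "SyntheticTree", "noiseless",
    "generate_tree", "generate_cohort", "truth_table", "recovery_experiment",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic campaign.

    Lengths in m, masses in kg, densities in kg m-3 unless noted.
    """

    n_trees: int = 4
    d_range: tuple[float, float] = (0.6, 1.2)       # diameter at 1.3 m
    height_coeff: float = 40.0                       # H = c D^e (m)
    height_exp: float = 0.40
    taper_exp: float = 1.5                           # stem taper curvature
    stem_top_radius_frac: float = 0.55               # r(top)/r(base)
    crown_base_frac_range: tuple[float, float] = (0.44, 0.60)
    crown_mass_fraction_range: tuple[float, float] = (0.42, 0.62)
    n_first_order_range: tuple[int, int] = (3, 5)
    branch_length_factor_range: tuple[float, float] = (0.9, 1.2)
    branch_child_length_ratio: float = 0.55
    branch_child_radius_ratio: float = 0.75
    branch_tip_radius_frac: float = 0.25
    branch_zenith_range_deg: tuple[float, float] = (30.0, 70.0)
    children_per_branch: int = 2
    max_branch_order: int = 3
    segment_length: float = 0.6                      # crown frustum length
    # density field: rho(h, r) = rho0 (1 + a h/H + b r/R) + noise
    rho0_range: tuple[float, float] = (560.0, 770.0)
    vertical_gradient_range: tuple[float, float] = (-0.10, 0.10)
    radial_gradient_range: tuple[float, float] = (-0.10, 0.10)
    density_noise_sd: float = 15.0                   # subsample noise
    g2d_mass_ratio_range: tuple[float, float] = (1.60, 1.75)
    g2d_mass_noise_sd: float = 0.02                  # per-subsample
    g2d_volume_ratio_range: tuple[float, float] = (1.10, 1.17)
    # harvest protocol
    section_length_range: tuple[float, float] = (0.15, 0.54)
    stump_height: float = 1.0
    crown_section_max_mass: float = 400.0            # crane-scale bound, kg
    scale_division: float = 0.1                      # kg
    cut_width: float = 0.0084
    subsample_size: float = 0.15                     # along the major axis
    subsample_volume_cm3: float = 375.0              # 150 x 50 x 50 mm
    max_subsamples_per_disc: int = 9
    green_volume_missing_frac: float = 0.0
    # estimator error models
    qsm_volume_error_sd: float = 0.04                # lognormal sigma
    qsm_omission_radius: float = 0.005               # m
    allometric_residual_sd: float = 0.30             # log scale
    literature_density_offset: float = 0.0           # fractional

    def validate(self) -> None:
        positive = {
            "n_trees": self.n_trees, "height_coeff": self.height_coeff,
            "height_exp": self.height_exp, "taper_exp": self.taper_exp,
            "segment_length": self.segment_length,
            "stump_height": self.stump_height,
            "crown_section_max_mass": self.crown_section_max_mass,
            "subsample_size": self.subsample_size,
            "subsample_volume_cm3": self.subsample_volume_cm3,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ConfigurationError(f"{name} must be > 0 (got {v})")
        nonneg = {
            "density_noise_sd": self.density_noise_sd,
            "g2d_mass_noise_sd": self.g2d_mass_noise_sd,
            "scale_division": self.scale_division,
            "cut_width": self.cut_width,
            "qsm_volume_error_sd": self.qsm_volume_error_sd,
            "qsm_omission_radius": self.qsm_omission_radius,
            "allometric_residual_sd": self.allometric_residual_sd,
            "green_volume_missing_frac": self.green_volume_missing_frac,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0 (got {v})")
        for name, rng_ in (("d_range", self.d_range),
                           ("crown_base_frac_range", self.crown_base_frac_range),
                           ("crown_mass_fraction_range",
                            self.crown_mass_fraction_range),
                           ("g2d_mass_ratio_range", self.g2d_mass_ratio_range),
                           ("g2d_volume_ratio_range",
                            self.g2d_volume_ratio_range),
                           ("section_length_range", self.section_length_range)):
            if not rng_[0] <= rng_[1]:
                raise ConfigurationError(f"{name} must be ordered (got {rng_})")
        if self.g2d_mass_ratio_range[0] < 1 or self.g2d_volume_ratio_range[0] < 1:
            raise ConfigurationError("green-to-dry ratios must be > 1")
        if not 0 < self.stem_top_radius_frac < 1:
            raise ConfigurationError("stem_top_radius_frac must be in (0, 1)")
        if self.max_branch_order < 1:
            raise ConfigurationError("max_branch_order must be >= 1")


def noiseless(config: SyntheticConfig | None = None) -> SyntheticConfig:
    """A copy of ``config`` with every noise source switched off."""
    base = config or SyntheticConfig()
    return replace(base, density_noise_sd=0.0, g2d_mass_noise_sd=0.0,
                   scale_division=0.0, qsm_volume_error_sd=0.0,
                   qsm_omission_radius=0.0, allometric_residual_sd=0.0,
                   green_volume_missing_frac=0.0)


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic tree (kg, m, m3, kg m-3)."""

    tree_id: str
    d_m: float
    tree_height: float
    green_volume: float
    stem_volume: float
    crown_volume: float
    dry_mass: float
    stem_dry_mass: float
    crown_dry_mass: float
    green_mass: float
    stem_green_mass: float
    crown_green_mass: float
    g2d_mass_ratio: float
    g2d_volume_ratio: float
    rho0: float
    vertical_gradient: float
    radial_gradient: float
    pool_weighted_density: float    # estimand of the mass-weighted approach
    volumetric_density: float       # dry mass over green volume
    swarf_dry_mass: float
    swarf_green_mass: float
    crown_mass_fraction: float      # dry-mass basis
    crown_base_height: float
    crown_major_axis: float
    qsm_volume: float               # realized, incl. volume error/omission


@dataclass
class SyntheticTree:
    """One generated dataset: harvest records, QSM and ground truth."""

    tree: HarvestTree
    qsm: QSMModel
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    start: np.ndarray
    end: np.ndarray
    r1: float
    r2: float
    order: int
    branch_id: int
    parent_branch: int
    root1: int  # id of the ancestor first-order branch (-1 for the stem)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def volume(self) -> float:
        r1, r2 = self.r1, self.r2
        return math.pi * self.length / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)

    def mean_z(self) -> float:
        """Volume-weighted mean z of the frustum (z linear along the axis)."""
        d = self.r2 - self.r1
        num = self.r1 ** 2 / 2.0 + 2.0 * self.r1 * d / 3.0 + d * d / 4.0
        den = self.r1 ** 2 + self.r1 * d + d * d / 3.0
        tbar = num / den if den > 0 else 0.5
        return float(self.start[2] + tbar * (self.end[2] - self.start[2]))


#: Cross-sectional mean of relative radius r/R over a disc (2/3 for a
#: uniform disc), used to integrate the radial density gradient per segment.
_RADIAL_MEAN = 2.0 / 3.0


def _mean_density(seg: _Segment, rho0: float, a: float, b: float,
                  h_ref: float) -> float:
    return rho0 * (1.0 + a * seg.mean_z() / h_ref + b * _RADIAL_MEAN)


def _point_density(z: float, r_rel: float, rho0: float, a: float, b: float,
                   h_ref: float) -> float:
    return rho0 * (1.0 + a * z / h_ref + b * r_rel)


def _tilted_direction(parent_dir: np.ndarray, angle: float,
                      azimuth: float) -> np.ndarray:
    """Rotate ``parent_dir`` by ``angle`` about a perpendicular axis."""
    d = parent_dir / np.linalg.norm(parent_dir)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    perp = math.cos(azimuth) * u + math.sin(azimuth) * v
    out = math.cos(angle) * d + math.sin(angle) * perp
    return out / np.linalg.norm(out)


def _round_to_division(mass: float, division: float) -> float:
    if division <= 0:
        return mass
    return round(mass / division) * division


class _TreeBuilder:
    """Builds one synthetic tree from a config and an RNG substream."""

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator,
                 tree_id: str, species: str):
        self.cfg = config
        self.rng = rng
        self.tree_id = tree_id
        self.species = species
        self.segments: list[_Segment] = []
        self.branches: dict[int, dict] = {}
        self._next_branch = 1

    # -- architecture ------------------------------------------------------

    def build(self) -> SyntheticTree:
        cfg, rng = self.cfg, self.rng
        self.d = float(rng.uniform(*cfg.d_range))
        self.h_nominal = cfg.height_coeff * self.d ** cfg.height_exp
        self.fork_height = float(
            rng.uniform(*cfg.crown_base_frac_range)) * self.h_nominal
        self.rho0 = float(rng.uniform(*cfg.rho0_range))
        self.grad_a = float(rng.uniform(*cfg.vertical_gradient_range))
        self.grad_b = float(rng.uniform(*cfg.radial_gradient_range))
        self.qm = float(rng.uniform(*cfg.g2d_mass_ratio_range))
        self.qv = float(rng.uniform(*cfg.g2d_volume_ratio_range))
        crown_fraction = float(rng.uniform(*cfg.crown_mass_fraction_range))

        section_bounds = self._stem_section_bounds()
        stem_segments = self._build_stem(section_bounds)
        self._build_crown()
        self._scale_crown_to_fraction(crown_fraction)
        return self._assemble(stem_segments, section_bounds)

    def _stem_radius(self, h: float) -> float:
        cfg = self.cfg
        shape = 1.0 - (1.0 - cfg.stem_top_radius_frac) * (
            h / self.fork_height) ** cfg.taper_exp
        shape_bh = 1.0 - (1.0 - cfg.stem_top_radius_frac) * (
            1.3 / self.fork_height) ** cfg.taper_exp
        return (self.d / 2.0) / shape_bh * shape

    def _stem_section_bounds(self) -> list[float]:
        cfg = self.cfg
        bounds = [0.0, cfg.stump_height]
        h = cfg.stump_height
        while h < self.fork_height - cfg.section_length_range[0]:
            h = min(h + float(self.rng.uniform(*cfg.section_length_range)),
                    self.fork_height)
            bounds.append(h)
        if bounds[-1] < self.fork_height:
            bounds[-1] = self.fork_height
        return bounds

    def _build_stem(self, bounds: Sequence[float]) -> list[_Segment]:
        segs = []
        for h1, h2 in zip(bounds[:-1], bounds[1:]):
            seg = _Segment(np.array([0.0, 0.0, h1]), np.array([0.0, 0.0, h2]),
                           self._stem_radius(h1), self._stem_radius(h2),
                           order=0, branch_id=0, parent_branch=-1, root1=-1)
            segs.append(seg)
        self.segments.extend(segs)
        return segs

    def _build_crown(self) -> None:
        cfg, rng = self.cfg, self.rng
        lo, hi = cfg.n_first_order_range
        n1 = int(rng.integers(lo, hi + 1))
        r_top = self._stem_radius(self.fork_height)
        base = np.array([0.0, 0.0, self.fork_height])
        for j in range(n1):
            azimuth = 2.0 * math.pi * j / n1 + rng.uniform(-0.3, 0.3)
            zenith = math.radians(rng.uniform(*cfg.branch_zenith_range_deg))
            direction = np.array([
                math.sin(zenith) * math.cos(azimuth),
                math.sin(zenith) * math.sin(azimuth),
                math.cos(zenith),
            ])
            length = float(rng.uniform(*cfg.branch_length_factor_range)) * (
                self.h_nominal - self.fork_height)
            r_base = 1.1 * r_top / math.sqrt(n1)
            bid = self._add_branch(base, direction, length, r_base, order=1,
                                   parent=0, root1=None)
            self.branches[bid]["root1"] = bid

    def _add_branch(self, start: np.ndarray, direction: np.ndarray,
                    length: float, r_base: float, order: int, parent: int,
                    root1: int | None) -> int:
        cfg, rng = self.cfg, self.rng
        bid = self._next_branch
        self._next_branch += 1
        r_tip = cfg.branch_tip_radius_frac * r_base
        self.branches[bid] = {"start": start, "dir": direction,
                              "length": length, "r_base": r_base,
                              "r_tip": r_tip, "order": order,
                              "parent": parent, "root1": root1}
        n_seg = max(1, round(length / cfg.segment_length))
        for k in range(n_seg):
            t1, t2 = k / n_seg, (k + 1) / n_seg
            seg = _Segment(
                start + direction * (t1 * length),
                start + direction * (t2 * length),
                r_base + (r_tip - r_base) * t1,
                r_base + (r_tip - r_base) * t2,
                order=order, branch_id=bid, parent_branch=parent,
                root1=root1 if root1 is not None else bid,
            )
            self.segments.append(seg)
        if order < cfg.max_branch_order:
            fractions = np.linspace(0.35, 0.75, cfg.children_per_branch)
            for f in fractions:
                child_start = start + direction * (f * length)
                r_here = r_base + (r_tip - r_base) * f
                child_dir = _tilted_direction(
                    direction, math.radians(rng.uniform(25.0, 50.0)),
                    rng.uniform(0.0, 2.0 * math.pi))
                self._add_branch(
                    child_start, child_dir,
                    cfg.branch_child_length_ratio * length,
                    cfg.branch_child_radius_ratio * r_here,
                    order=order + 1, parent=bid,
                    root1=root1 if root1 is not None else bid)
        return bid

    def _scale_crown_to_fraction(self, fraction: float) -> None:
        """Scale branch radii so the crown holds ``fraction`` of dry mass."""
        stem_dry = sum(s.volume * self._seg_density(s)
                       for s in self.segments if s.order == 0)
        crown_dry = sum(s.volume * self._seg_density(s)
                        for s in self.segments if s.order >= 1)
        s2 = fraction * stem_dry / ((1.0 - fraction) * crown_dry)
        s = math.sqrt(s2)
        for seg in self.segments:
            if seg.order >= 1:
                seg.r1 *= s
                seg.r2 *= s
        for b in self.branches.values():
            b["r_base"] *= s
            b["r_tip"] *= s

    def _seg_density(self, seg: _Segment) -> float:
        return _mean_density(seg, self.rho0, self.grad_a, self.grad_b,
                             self.h_nominal)

    # -- harvest records ---------------------------------------------------

    def _make_discs(self) -> tuple[list[Disc], list[dict]]:
        """Disc records plus per-subsample metadata (pool, true density)."""
        cfg, rng = self.cfg, self.rng
        specs: list[tuple[str, float, float]] = [
            ("SD1", 1.3, self._stem_radius(1.3)),
            ("SD2", 0.25 * self.fork_height,
             self._stem_radius(0.25 * self.fork_height)),
            ("SD3", 0.50 * self.fork_height,
             self._stem_radius(0.50 * self.fork_height)),
            ("SD4", 0.75 * self.fork_height,
             self._stem_radius(0.75 * self.fork_height)),
        ]
        for order, code in ((1, "BO1"), (2, "BO2"), (3, "BO3")):
            cands = [b for b in self.branches.values() if b["order"] == order]
            if not cands:
                continue
            b = cands[0]
            mid = b["start"] + b["dir"] * (0.5 * b["length"])
            r_mid = 0.5 * (b["r_base"] + b["r_tip"])
            specs.append((code, float(mid[2]), r_mid))

        discs: list[Disc] = []
        meta: list[dict] = []
        for code, z, radius in specs:
            n_sub = int(np.clip(round(2.0 * radius / cfg.subsample_size), 2,
                                cfg.max_subsamples_per_disc))
            subs = []
            for k in range(n_sub):
                offset = -radius + (k + 0.5) * (2.0 * radius / n_sub)
                r_rel = abs(offset) / radius
                rho_true = _point_density(z, r_rel, self.rho0, self.grad_a,
                                          self.grad_b, self.h_nominal)
                rho_meas = rho_true + (rng.normal(0.0, cfg.density_noise_sd)
                                       if cfg.density_noise_sd > 0 else 0.0)
                qm_meas = self.qm + (rng.normal(0.0, cfg.g2d_mass_noise_sd)
                                     if cfg.g2d_mass_noise_sd > 0 else 0.0)
                gv = cfg.subsample_volume_cm3
                dry_mass = rho_meas / 1000.0 * gv       # g
                position = OUTER if k in (0, n_sub - 1) else INNER
                missing = (cfg.green_volume_missing_frac > 0 and
                           rng.uniform() < cfg.green_volume_missing_frac)
                subs.append(Subsample(
                    green_mass=qm_meas * dry_mass,
                    dry_mass=dry_mass,
                    green_volume=None if missing else gv,
                    dry_volume=gv / self.qv,
                    radial_position=position,
                ))
                meta.append({"location": code,
                             "pool": STEM if code.startswith("SD") else CROWN,
                             "density_true": rho_true})
            discs.append(Disc(disc_id=f"{self.tree_id}-{code}",
                              location_class=code, height_above_ground=z,
                              subsamples=subs))
        return discs, meta

    def _mass_weighted_fixed_point(self, stem_dry: float, crown_dry: float,
                                   cut_volumes: Sequence[float],
                                   meta: list[dict]) -> float:
        """Solve for the mass-weighted density the pipeline will compute.

        The stem pool mass the pipeline weights with depends on the swarf
        already removed, which itself is priced at the mass-weighted
        density; iterate the (strongly contracting) fixed point. Uses the
        noise-free subsample densities: measurement noise must not alter
        the mass physically lost at the saw.
        """
        pools: dict[str, list[float]] = {STEM: [], CROWN: []}
        for m in meta:
            pools[m["pool"]].append(m["density_true"])
        x_stem = float(np.mean(pools[STEM]))
        x_crown = float(np.mean(pools[CROWN])) if pools[CROWN] else x_stem
        v_cut = float(sum(cut_volumes))
        rho = (stem_dry * x_stem + crown_dry * x_crown) / (
            stem_dry + crown_dry)
        for _ in range(60):
            m_stem = self.qm * (stem_dry - v_cut * rho)
            m_crown = self.qm * crown_dry
            new = (m_stem * x_stem + m_crown * x_crown) / (m_stem + m_crown)
            if abs(new - rho) < 1e-13:
                rho = new
                break
            rho = new
        return rho

    # -- assembly ----------------------------------------------------------

    def _assemble(self, stem_segments: list[_Segment],
                  bounds: Sequence[float]) -> SyntheticTree:
        cfg = self.cfg
        stem_dry = sum(s.volume * self._seg_density(s)
                       for s in self.segments if s.order == 0)
        crown_dry = sum(s.volume * self._seg_density(s)
                        for s in self.segments if s.order >= 1)
        stem_volume = sum(s.volume for s in self.segments if s.order == 0)
        crown_volume = sum(s.volume for s in self.segments if s.order >= 1)

        discs, meta = self._make_discs()

        # swarf: one kerf per stem section at its representative diameter,
        # mirroring the pipeline's correction exactly
        cut_volumes = [
            swarf_cut_volume(seg.r1 + seg.r2, cfg.cut_width)
            for seg in stem_segments
        ]
        rho_mw = self._mass_weighted_fixed_point(stem_dry, crown_dry,
                                                 cut_volumes, meta)

        sections: list[Section] = []
        for i, seg in enumerate(stem_segments):
            dry = seg.volume * self._seg_density(seg)
            green = self.qm * (dry - cut_volumes[i] * rho_mw)
            sections.append(Section(
                pool=STEM,
                green_mass=_round_to_division(green, cfg.scale_division),
                length=seg.length,
                end_diameter_1=2.0 * seg.r1,
                end_diameter_2=2.0 * seg.r2,
                is_stump=(i == 0),
            ))

        # crown: each first-order subtree's green mass split into sacks
        for root in sorted({s.root1 for s in self.segments if s.order >= 1}):
            subtree_dry = sum(s.volume * self._seg_density(s)
                              for s in self.segments if s.root1 == root)
            green = self.qm * subtree_dry
            n_sack = max(1, math.ceil(green / cfg.crown_section_max_mass))
            for _ in range(n_sack):
                sections.append(Section(
                    pool=CROWN,
                    green_mass=_round_to_division(green / n_sack,
                                                  cfg.scale_division),
                ))

        tree_height = max(float(s.end[2]) for s in self.segments)
        tree = HarvestTree(
            tree_id=self.tree_id, species=self.species,
            latitude=-1.798 + float(self.rng.normal(0, 1e-3)),
            longitude=-51.435 + float(self.rng.normal(0, 1e-3)),
            stem_diameter=self.d, tree_height=tree_height,
            diameter_protocol="dbh", sections=sections, discs=discs,
        )
        tree.validate()

        qsm, qsm_volume = self._make_qsm()
        truth = self._make_truth(tree, stem_dry, crown_dry, stem_volume,
                                 crown_volume, cut_volumes, rho_mw,
                                 tree_height, qsm_volume, meta)
        return SyntheticTree(tree=tree, qsm=qsm, truth=truth)

    def _make_qsm(self) -> tuple[QSMModel, float]:
        cfg, rng = self.cfg, self.rng
        n = len(self.segments)
        start = np.zeros((n, 3))
        axis = np.zeros((n, 3))
        radius = np.zeros(n)
        length = np.zeros(n)
        order = np.zeros(n, dtype=int)
        branch = np.zeros(n, dtype=int)
        parent = np.zeros(n, dtype=int)
        for i, seg in enumerate(self.segments):
            start[i] = seg.start
            vec = seg.end - seg.start
            ln = np.linalg.norm(vec)
            axis[i] = vec / ln
            length[i] = ln
            # volume-preserving equivalent cylinder radius of the frustum
            radius[i] = math.sqrt(
                (seg.r1 ** 2 + seg.r1 * seg.r2 + seg.r2 ** 2) / 3.0)
            order[i] = seg.order
            branch[i] = seg.branch_id
            parent[i] = seg.parent_branch
        if cfg.qsm_volume_error_sd > 0:
            factor = math.exp(rng.normal(0.0, cfg.qsm_volume_error_sd))
            radius = radius * math.sqrt(factor)
        if cfg.qsm_omission_radius > 0:
            keep = radius >= cfg.qsm_omission_radius
            keep |= order == 0  # never drop the stem
            start, axis = start[keep], axis[keep]
            radius, length = radius[keep], length[keep]
            order, branch, parent = order[keep], branch[keep], parent[keep]
        qsm = QSMModel(tree_id=self.tree_id, start=start, axis=axis,
                       radius=radius, length=length, branch_order=order,
                       branch_id=branch, parent_id=parent)
        qsm.validate()
        return qsm, float(np.sum(np.pi * radius ** 2 * length))

    def _make_truth(self, tree: HarvestTree, stem_dry: float,
                    crown_dry: float, stem_volume: float, crown_volume: float,
                    cut_volumes: Sequence[float], rho_mw: float,
                    tree_height: float, qsm_volume: float,
                    meta: list[dict]) -> SyntheticTruth:
        dry = stem_dry + crown_dry
        volume = stem_volume + crown_volume
        # the estimand of the mass-weighted approach: noise-free pool means
        # weighted by the pool masses actually recorded on the scale
        pools: dict[str, list[float]] = {STEM: [], CROWN: []}
        for m in meta:
            pools[m["pool"]].append(m["density_true"])
        pool_masses = tree.pool_green_mass
        num = den = 0.0
        for pool, values in pools.items():
            if values and pool in pool_masses:
                num += pool_masses[pool] * float(np.mean(values))
                den += pool_masses[pool]
        crown_pts = np.array([[*s.start, s.r1] for s in self.segments
                              if s.order >= 1] +
                             [[*s.end, s.r2] for s in self.segments
                              if s.order >= 1])
        xy = crown_pts[:, :2]
        rr = crown_pts[:, 3]
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2)) + rr[:, None] + rr[None, :]
        np.fill_diagonal(dist, 0.0)
        swarf_dry = float(sum(cut_volumes)) * rho_mw
        return SyntheticTruth(
            tree_id=self.tree_id, d_m=self.d, tree_height=tree_height,
            green_volume=volume, stem_volume=stem_volume,
            crown_volume=crown_volume, dry_mass=dry,
            stem_dry_mass=stem_dry, crown_dry_mass=crown_dry,
            green_mass=self.qm * dry,
            stem_green_mass=self.qm * stem_dry,
            crown_green_mass=self.qm * crown_dry,
            g2d_mass_ratio=self.qm, g2d_volume_ratio=self.qv,
            rho0=self.rho0, vertical_gradient=self.grad_a,
            radial_gradient=self.grad_b,
            pool_weighted_density=num / den,
            volumetric_density=dry / volume,
            swarf_dry_mass=swarf_dry,
            swarf_green_mass=self.qm * swarf_dry,
            crown_mass_fraction=crown_dry / dry,
            crown_base_height=self.fork_height,
            crown_major_axis=float(dist.max()),
            qsm_volume=qsm_volume,
        )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_tree(config: SyntheticConfig, seed: int | np.random.SeedSequence,
                  index: int = 0) -> SyntheticTree:
    """Generate one synthetic tree; deterministic for a fixed seed/index."""
    config.validate()
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence([int(seed), index])
    rng = np.random.default_rng(ss)
    builder = _TreeBuilder(config, rng, tree_id=f"S{index + 1}",
                           species=f"Synthetica arborea {index + 1}")
    return builder.build()


def generate_cohort(config: SyntheticConfig, seed: int) -> list[SyntheticTree]:
    """Generate ``config.n_trees`` independent trees.

    Each tree uses its own seed substream derived from (seed, index), so a
    cohort is reproducible and individual trees can be regenerated in
    isolation.
    """
    config.validate()
    return [generate_tree(config, np.random.SeedSequence([int(seed), i]),
                          index=i)
            for i in range(config.n_trees)]


def truth_table(cohort: Sequence[SyntheticTree]) -> pd.DataFrame:
    """Flatten cohort ground truth into a DataFrame."""
    return pd.DataFrame([vars(t.truth) for t in cohort])


def _qsm_estimator(item: SyntheticTree, config: SyntheticConfig,
                   rng: np.random.Generator) -> float:
    est = qsm_agb(item.qsm, mass_weighted_density(item.tree))
    return est.agb_est


def _allometric_estimator(item: SyntheticTree, config: SyntheticConfig,
                          rng: np.random.Generator) -> float:
    rho = mass_weighted_density(item.tree).basic_density
    agb = allometric_agb(item.truth.d_m * 100.0, item.truth.tree_height,
                         rho / 1000.0, DEFAULT_ALLOMETRIC_MODEL)
    if config.allometric_residual_sd > 0:
        agb *= math.exp(rng.normal(0.0, config.allometric_residual_sd))
    return agb


def _literature_qsm_estimator(item: SyntheticTree, config: SyntheticConfig,
                              rng: np.random.Generator) -> float:
    rho = item.truth.pool_weighted_density * (
        1.0 + config.literature_density_offset)
    db = pd.DataFrame({"species": [item.tree.species],
                       "basic_density_kg_m3": [rho]})
    est = qsm_agb(item.qsm, density_mod.literature_estimate(
        item.tree.species, db, item.tree.tree_id))
    return est.agb_est


ESTIMATORS: dict[str, Callable] = {
    "qsm": _qsm_estimator,
    "allometric": _allometric_estimator,
    "qsm_literature": _literature_qsm_estimator,
}


def recovery_experiment(config: SyntheticConfig, estimator: str,
                        seed: int) -> pd.DataFrame:
    """Estimate AGB on a fresh cohort and compare against ground truth.

    Returns one row per tree (true and estimated AGB, error, unsigned
    relative error in %). Summary statistics (bias, RMSE, MRE, error-size
    slope) are computed downstream with the performance module.
    """
    if estimator not in ESTIMATORS:
        raise ConfigurationError(
            f"unknown estimator {estimator!r}; choose from "
            f"{sorted(ESTIMATORS)}")
    cohort = generate_cohort(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 987654321]))
    fn = ESTIMATORS[estimator]
    rows = []
    for item in cohort:
        est = fn(item, config, rng)
        true = item.truth.dry_mass
        rows.append({
            "tree_id": item.truth.tree_id,
            "agb_true": true,
            "agb_est": est,
            "error": est - true,
            "relative_error": 100.0 * abs(est - true) / true,
        })
    return pd.DataFrame(rows)
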