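"""Non-destructive AGB estimators: pan-tropical allometry and QSM volume.

The allometric model is the widely used pan-tropical diameter-height-
density model AGB = a (D^2 H rho)^b with D in cm, H in m, rho in g cm-3
and AGB in kg (Chave et al. 2014, model 4; a = 0.0673, b = 0.976, fitted
on 4004 harvested trees). Published summaries often round the coefficient
to 0.067; the unrounded value reproduces published estimates to <0.05 %
and is therefore the default, with the rounded one available via
:class:`AllometricModel`.

The lidar route multiplies the total cylinder volume of a quantitative
structural model (QSM) — green woody volume fitted to a terrestrial-lidar
point cloud — by an above-ground basic woody tissue density. QSM fitting
itself is upstream; cylinder tables are consumed, not produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityEstimate
from .errors import DomainError, SchemaError, ValidationError
from .harvest_data import CROWN, STEM

logger = logging.getLogger(__name__)

ALLOMETRIC = "allometric"
QSM = "qsm"

_AXIS_NORM_TOL = 1e-6


@dataclass(frozen=True)
class AllometricModel:
    """Constants of the pan-tropical allometric model (output in kg)."""

    coefficient: float = 0.0673
    exponent: float = 0.976

    def __post_init__(self) -> None:
        if not (self.coefficient > 0 and self.exponent > 0):
            raise DomainError("allometric constants must be > 0")


DEFAULT_ALLOMETRIC_MODEL = AllometricModel()
#: The commonly printed two-significant-figure coefficient.
ROUNDED_ALLOMETRIC_MODEL = AllometricModel(coefficient=0.067)


def allometric_agb(d_cm: float, h_m: float, rho_g_cm3: float,
                   model: AllometricModel = DEFAULT_ALLOMETRIC_MODEL) -> float:
    """Allometric AGB (kg) from D (cm), H (m) and basic density (g cm-3)."""
    if not (d_cm > 0 and h_m > 0 and rho_g_cm3 > 0):
        raise DomainError("allometric inputs must be > 0")
    return model.coefficient * (d_cm ** 2 * h_m * rho_g_cm3) ** model.exponent


QSM_COLUMNS = ["tree_id", "cyl_id", "parent_id", "branch_id", "branch_order",
               "start_x", "start_y", "start_z", "axis_x", "axis_y", "axis_z",
               "radius_m", "length_m"]


@dataclass
class QSMModel:
    """A cylinder model of woody architecture (TreeQSM-style table).

    Arrays are aligned per cylinder. ``branch_order`` 0 is the stem; the
    first fork starts order 1.
    """

    tree_id: str
    start: np.ndarray          # (n, 3) m
    axis: np.ndarray           # (n, 3) unit vectors
    radius: np.ndarray         # (n,) m
    length: np.ndarray         # (n,) m
    branch_order: np.ndarray   # (n,) int
    branch_id: np.ndarray | None = None
    parent_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(-1, 3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float).ravel()
        self.length = np.asarray(self.length, dtype=float).ravel()
        self.branch_order = np.asarray(self.branch_order, dtype=int).ravel()

    @property
    def n_cylinders(self) -> int:
        return self.radius.size

    @property
    def end(self) -> np.ndarray:
        return self.start + self.axis * self.length[:, None]

    def validate(self) -> None:
        if self.n_cylinders == 0:
            raise ValidationError(f"tree {self.tree_id}: empty QSM")
        if not (self.radius > 0).all():
            raise ValidationError(f"tree {self.tree_id}: non-positive radius")
        if not (self.length > 0).all():
            raise ValidationError(f"tree {self.tree_id}: non-positive length")
        norms = np.linalg.norm(self.axis, axis=1)
        if not np.allclose(norms, 1.0, atol=_AXIS_NORM_TOL):
            raise ValidationError(
                f"tree {self.tree_id}: axis vectors not unit-norm")
        if not (self.branch_order == 0).any():
            raise ValidationError(
                f"tree {self.tree_id}: no stem (order-0) cylinders")
        if (self.branch_order < 0).any():
            raise ValidationError(f"tree {self.tree_id}: negative branch order")


@dataclass
class AGBEstimate:
    """A non-destructive AGB estimate (kg) with its provenance."""

    tree_id: str
    method: str
    agb_est: float
    green_volume: float | None = None          # m3, qsm only
    pool_split: dict[str, float] = field(default_factory=dict)  # kg
    density_used: DensityEstimate | None = None

    @property
    def stem_fraction(self) -> float | None:
        if not self.pool_split or self.agb_est <= 0:
            return None
        return self.pool_split.get(STEM, 0.0) / self.agb_est


def read_qsm_tables(path: str | Path) -> dict[str, QSMModel]:
    """Read a cylinder CSV (possibly several trees) into QSM models."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in QSM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    out: dict[str, QSMModel] = {}
    for tid, g in df.groupby("tree_id", sort=False):
        qsm = QSMModel(
            tree_id=str(tid),
            start=g[["start_x", "start_y", "start_z"]].to_numpy(),
            axis=g[["axis_x", "axis_y", "axis_z"]].to_numpy(),
            radius=g["radius_m"].to_numpy(),
            length=g["length_m"].to_numpy(),
            branch_order=g["branch_order"].to_numpy(),
            branch_id=g["branch_id"].to_numpy(),
            parent_id=g["parent_id"].to_numpy(),
        )
        qsm.validate()
        out[str(tid)] = qsm
    return out


def write_qsm_table(qsms: dict[str, QSMModel] | QSMModel,
                    path: str | Path) -> None:
    """Write QSM models to the cylinder CSV convention."""
    if isinstance(qsms, QSMModel):
        qsms = {qsms.tree_id: qsms}
    rows = []
    for qsm in qsms.values():
        n = qsm.n_cylinders
        bid = qsm.branch_id if qsm.branch_id is not None else np.zeros(n, int)
        pid = qsm.parent_id if qsm.parent_id is not None else np.full(n, -1)
        for i in range(n):
            rows.append({
                "tree_id": qsm.tree_id, "cyl_id": i, "parent_id": pid[i],
                "branch_id": bid[i], "branch_order": qsm.branch_order[i],
                "start_x": qsm.start[i, 0], "start_y": qsm.start[i, 1],
                "start_z": qsm.start[i, 2], "axis_x": qsm.axis[i, 0],
                "axis_y": qsm.axis[i, 1], "axis_z": qsm.axis[i, 2],
                "radius_m": qsm.radius[i], "length_m": qsm.length[i],
            })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=QSM_COLUMNS).to_csv(path, index=False)


def qsm_total_volume(qsm: QSMModel) -> float:
    """Total green woody volume (m3): sum of pi r^2 l over cylinders."""
    if qsm.n_cylinders == 0:
        raise DomainError("empty QSM has no volume")
    return float(np.sum(np.pi * qsm.radius ** 2 * qsm.length))


def partition_stem_crown(qsm: QSMModel) -> dict[str, float]:
    """Split QSM volume (m3) at the first fork: order 0 = stem, >=1 = crown."""
    if not (qsm.branch_order == 0).any():
        raise ValidationError(
            f"tree {qsm.tree_id}: no order-0 cylinders to define a stem")
    vol = np.pi * qsm.radius ** 2 * qsm.length
    stem = float(vol[qsm.branch_order == 0].sum())
    crown = float(vol[qsm.branch_order >= 1].sum())
    return {STEM: stem, CROWN: crown}


def qsm_agb(qsm: QSMModel, density: DensityEstimate) -> AGBEstimate:
    """AGB (kg) = total QSM green volume x basic density (kg m-3)."""
    volume = qsm_total_volume(qsm)
    if density.basic_density == 0:
        logger.warning("tree %s: zero density gives zero AGB", qsm.tree_id)
    split = partition_stem_crown(qsm)
    rho = density.basic_density
    return AGBEstimate(
        tree_id=qsm.tree_id,
        method=QSM,
        agb_est=volume * rho,
        green_volume=volume,
        pool_split={p: v * rho for p, v in split.items()},
        density_used=density,
    )


def allometric_estimate(tree_id: str, d_m: float, h_m: float,
                        density: DensityEstimate,
                        model: AllometricModel = DEFAULT_ALLOMETRIC_MODEL,
                        ) -> AGBEstimate:
    """Allometric AGB for a tree with D stored in m and density in kg m-3.

    Unit conversion happens at this boundary: D m -> cm, rho kg m-3 ->
    g cm-3.
    """
    agb = allometric_agb(d_m * 100.0, h_m, density.basic_density / 1000.0,
                         model)
    return AGBEstimate(tree_id=tree_id, method=ALLOMETRIC, agb_est=agb,
                       density_used=density)
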