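"""Crown-form and mass-distribution metrics from QSMs or point clouds.

The crown is everything above the first fork. From a QSM the crown base
is the lowest start point of a first-order cylinder; from a point cloud it
must be supplied. Crown form is summarised by the crown-to-tree-height
ratio and the crown aspect ratio (horizontal major-axis diameter over
crown height): shallow, wide crowns (high aspect) tend to hold less of the
tree's mass than deep ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .agb_estimators import AGBEstimate, QSMModel
from .errors import DomainError, SchemaError, ValidationError
from .harvest_data import STEM
from .reference_agb import ReferenceAGB

QSM_SOURCE = "qsm"
CLOUD_SOURCE = "point_cloud"


@dataclass(frozen=True)
class CrownMetrics:
    """Crown geometry summaries (m and dimensionless)."""

    tree_id: str
    crown_base_height: float
    crown_height: float
    crown_to_tree_height_ratio: float
    crown_major_axis_diameter: float
    crown_aspect_ratio: float
    source: str

    def __post_init__(self) -> None:
        if self.crown_base_height < 0:
            raise DomainError("crown base below ground")
        if not self.crown_height > 0:
            raise DomainError("crown height must be > 0")


def _max_pairwise_horizontal(points: np.ndarray) -> float:
    """Diameter of the horizontal (xy) extent of a point set.

    Uses the 2-D convex hull so only O(h^2) pairs are compared; falls back
    to all pairs for degenerate (collinear) sets.
    """
    xy = np.asarray(points, dtype=float)[:, :2]
    if len(xy) > 3:
        try:
            xy = xy[ConvexHull(xy).vertices]
        except Exception:  # collinear input: qhull refuses, brute force
            pass
    diff = xy[:, None, :] - xy[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).max())


def crown_metrics_from_qsm(qsm: QSMModel, tree_height: float) -> CrownMetrics:
    """Crown metrics with the crown base at the first fork of the QSM.

    The major axis is the maximum pairwise horizontal distance between
    crown cylinder endpoints, widened by the two endpoint radii.
    """
    crown = qsm.branch_order >= 1
    if not crown.any():
        raise ValidationError(
            f"tree {qsm.tree_id}: no crown (order >= 1) cylinders")
    base = float(qsm.start[crown, 2].min())
    if not base < tree_height:
        raise ValidationError(
            f"tree {qsm.tree_id}: crown base at or above tree height")
    pts = np.vstack([qsm.start[crown], qsm.end[crown]])
    radii = np.concatenate([qsm.radius[crown], qsm.radius[crown]])
    xy = pts[:, :2]
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2)) + radii[:, None] + radii[None, :]
    np.fill_diagonal(dist, 0.0)
    major = float(dist.max())
    crown_height = tree_height - base
    return CrownMetrics(
        tree_id=qsm.tree_id,
        crown_base_height=base,
        crown_height=crown_height,
        crown_to_tree_height_ratio=crown_height / tree_height,
        crown_major_axis_diameter=major,
        crown_aspect_ratio=major / crown_height,
        source=QSM_SOURCE,
    )


def crown_metrics_from_cloud(points: np.ndarray, crown_base_height: float,
                             tree_height: float,
                             tree_id: str = "") -> CrownMetrics:
    """Crown metrics from an xyz point cloud with a supplied crown base."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    above = points[points[:, 2] >= crown_base_height]
    if len(above) < 3:
        raise DomainError("need >= 3 points above the crown base")
    major = _max_pairwise_horizontal(above)
    crown_height = tree_height - crown_base_height
    if not crown_height > 0:
        raise DomainError("crown base at or above tree height")
    return CrownMetrics(
        tree_id=tree_id,
        crown_base_height=crown_base_height,
        crown_height=crown_height,
        crown_to_tree_height_ratio=crown_height / tree_height,
        crown_major_axis_diameter=major,
        crown_aspect_ratio=major / crown_height,
        source=CLOUD_SOURCE,
    )


def read_point_cloud(path: str | Path) -> np.ndarray:
    """Read an xyz point cloud from a PLY file or whitespace-delimited text.

    PLY support covers ascii and binary little-endian vertex elements with
    x/y/z properties, the convention used by lidar tree archives.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _read_ply_xyz(path)
    arr = np.loadtxt(path, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise SchemaError(f"{path}: expected whitespace-delimited xyz rows")
    return arr[:, :3]


_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply_xyz(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise SchemaError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise SchemaError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise SchemaError(f"{path}: list property in vertex element")
                props.append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if n_vertex is None:
            raise SchemaError(f"{path}: no vertex element")
        names = [n for n, _ in props]
        if not {"x", "y", "z"} <= set(names):
            raise SchemaError(f"{path}: vertex element lacks x/y/z")
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertex):
                rows.append([float(v) for v in fh.readline().split()])
            arr = np.array(rows, dtype=float)
            idx = [names.index(c) for c in ("x", "y", "z")]
            return arr[:, idx]
        if fmt == "binary_little_endian":
            dtype = np.dtype([(n, "<" + t) for n, t in props])
            data = np.frombuffer(fh.read(n_vertex * dtype.itemsize),
                                 dtype=dtype, count=n_vertex)
            return np.column_stack([data["x"], data["y"], data["z"]]
                                   ).astype(float)
        raise SchemaError(f"{path}: unsupported PLY format {fmt!r}")


def mass_distribution_report(references: Sequence[ReferenceAGB],
                             estimates: Sequence[AGBEstimate]) -> pd.DataFrame:
    """Per-tree stem-mass fractions, harvest vs estimator, with differences.

    Estimates without a stem/crown split (e.g. allometric) are reported
    with missing estimator columns.
    """
    est_by_id = {e.tree_id: e for e in estimates}
    rows = []
    for ref in references:
        est = est_by_id.get(ref.tree_id)
        harvest_frac = ref.stem_mass_ratio
        est_frac = est.stem_fraction if est is not None else None
        rows.append({
            "tree_id": ref.tree_id,
            "stem_fraction_harvest": harvest_frac,
            "stem_fraction_estimate": est_frac,
            "difference_points": (None if est_frac is None
                                  else 100.0 * (est_frac - harvest_frac)),
        })
    return pd.DataFrame(rows, columns=["tree_id", "stem_fraction_harvest",
                                       "stem_fraction_estimate",
                                       "difference_points"])


def stem_fraction_difference(harvest_fraction: float,
                             estimator_fraction: float) -> float:
    """Difference in percentage points (estimator minus harvest)."""
    return 100.0 * (estimator_fraction - harvest_fraction)
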