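"""Domain model and tabular I/O for destructive harvest campaigns.

A harvest campaign weighs every piece of a felled tree. Green mass is
assigned to two pools — the stem (bole from flush with the ground to the
first fork, including the stump) and the crown (everything above the first
fork). Discs cut from the stem and from branch mid-points are reduced in
the laboratory to subsamples on which green/dry mass and volume are
measured; these carry all moisture and density information.

Internal units: masses in kg, lengths in m, except laboratory subsamples
which keep their native g and cm3 scales.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

STEM = "stem"
CROWN = "crown"
POOLS = (STEM, CROWN)

#: Disc location codes: four stem discs (1.3 m above-ground and 25/50/75 %
#: of stem length) and up to three branch discs at the mid-points of
#: first-, second- and third-order branches.
STEM_DISC_CLASSES = ("SD1", "SD2", "SD3", "SD4")
BRANCH_DISC_CLASSES = ("BO1", "BO2", "BO3")
DISC_CLASSES = STEM_DISC_CLASSES + BRANCH_DISC_CLASSES

OUTER = "outer"
INNER = "inner"


@dataclass
class Subsample:
    """A wood block (~150 x 50 x 50 mm) cut from a disc along its major axis.

    Masses in g, volumes in cm3. ``green_volume`` may be absent on ingest
    (the field campaign may only measure it on later reference material) and
    is then imputed from ``dry_volume`` and the tree's mean green-to-dry
    volume ratio; ``imputed_green_volume`` records that provenance.
    """

    green_mass: float
    dry_mass: float
    green_volume: float | None
    dry_volume: float
    radial_position: str = INNER
    imputed_green_volume: bool = False

    def validate(self, where: str = "") -> None:
        tag = f" ({where})" if where else ""
        if not self.dry_mass > 0:
            raise ValidationError(f"subsample dry mass must be > 0{tag}")
        if not self.green_mass > self.dry_mass:
            raise ValidationError(
                f"subsample green mass must exceed dry mass{tag}"
            )
        if not self.dry_volume > 0:
            raise ValidationError(f"subsample dry volume must be > 0{tag}")
        if self.green_volume is not None and self.green_volume < self.dry_volume:
            raise ValidationError(
                f"green volume smaller than dry volume (swelling impossible){tag}"
            )
        if self.radial_position not in (OUTER, INNER):
            raise ValidationError(f"radial position must be outer/inner{tag}")


@dataclass
class Disc:
    """A ~50 mm thick cross-sectional disc with its ordered subsamples.

    Subsamples are ordered along the disc's major axis, so the first and
    last are the outer blocks (periderm/phloem/cambium included).
    """

    disc_id: str
    location_class: str
    height_above_ground: float | None = None
    subsamples: list[Subsample] = field(default_factory=list)

    @property
    def pool(self) -> str:
        return STEM if self.location_class.startswith("SD") else CROWN

    def validate(self) -> None:
        if self.location_class not in DISC_CLASSES:
            raise ValidationError(
                f"disc {self.disc_id}: unknown location class "
                f"{self.location_class!r} (expected one of {DISC_CLASSES})"
            )
        if not self.subsamples:
            raise ValidationError(f"disc {self.disc_id}: no subsamples")
        for i, s in enumerate(self.subsamples):
            s.validate(where=f"disc {self.disc_id} subsample {i}")
        if self.subsamples[0].radial_position != OUTER or (
            self.subsamples[-1].radial_position != OUTER
        ):
            raise ValidationError(
                f"disc {self.disc_id}: first and last subsamples must be outer"
            )


@dataclass
class Section:
    """One weighed piece of the tree (stem section, branch section or sack).

    Stem sections carry length and both end diameters so that geometric
    volume (Smalian) and chainsaw-kerf swarf can be reconstructed; crown
    sacks only carry mass.
    """

    pool: str
    green_mass: float
    length: float | None = None
    end_diameter_1: float | None = None
    end_diameter_2: float | None = None
    is_stump: bool = False

    def validate(self, where: str = "") -> None:
        tag = f" ({where})" if where else ""
        if self.pool not in POOLS:
            raise ValidationError(f"section pool must be stem/crown{tag}")
        if self.green_mass < 0:
            raise ValidationError(f"section green mass must be >= 0{tag}")
        if self.length is not None and not self.length > 0:
            raise ValidationError(f"section length must be > 0{tag}")
        for d in (self.end_diameter_1, self.end_diameter_2):
            if d is not None and not d > 0:
                raise ValidationError(f"section diameter must be > 0{tag}")

    def representative_diameter(self) -> float | None:
        """Mid diameter of the section (mean of ends, or the single end)."""
        ds = [d for d in (self.end_diameter_1, self.end_diameter_2) if d is not None]
        if not ds:
            return None
        return sum(ds) / len(ds)


@dataclass
class HarvestTree:
    """One harvested tree: metadata, weighed sections and laboratory discs.

    ``stem_diameter`` (m) is recorded at 1.3 m above-ground or, for
    buttressed stems, 0.5 m above the buttress; ``diameter_protocol``
    records which.
    """

    tree_id: str
    species: str
    latitude: float
    longitude: float
    stem_diameter: float
    tree_height: float
    diameter_protocol: str = "dbh"
    sections: list[Section] = field(default_factory=list)
    discs: list[Disc] = field(default_factory=list)

    @property
    def pool_green_mass(self) -> dict[str, float]:
        """Weighed green mass per pool (kg), summed over sections."""
        out = {p: 0.0 for p in POOLS}
        for s in self.sections:
            out[s.pool] += s.green_mass
        return {p: m for p, m in out.items() if m > 0 or p in
                {s.pool for s in self.sections}}

    @property
    def total_green_mass(self) -> float:
        return sum(s.green_mass for s in self.sections)

    def stem_sections(self) -> list[Section]:
        return [s for s in self.sections if s.pool == STEM]

    def crown_sections(self) -> list[Section]:
        return [s for s in self.sections if s.pool == CROWN]

    def discs_in_pool(self, pool: str) -> list[Disc]:
        return [d for d in self.discs if d.pool == pool]

    def disc_by_class(self, location_class: str) -> Disc | None:
        for d in self.discs:
            if d.location_class == location_class:
                return d
        return None

    def validate(self) -> None:
        if not self.stem_diameter > 0:
            raise ValidationError(f"tree {self.tree_id}: D must be > 0")
        if not self.tree_height > 0:
            raise ValidationError(f"tree {self.tree_id}: H must be > 0")
        if self.diameter_protocol not in ("dbh", "above_buttress"):
            raise ValidationError(
                f"tree {self.tree_id}: diameter protocol must be "
                "'dbh' or 'above_buttress'"
            )
        if not self.sections:
            raise ValidationError(
                f"tree {self.tree_id}: no weighed sections (no mass records)"
            )
        for i, s in enumerate(self.sections):
            s.validate(where=f"tree {self.tree_id} section {i}")
        for d in self.discs:
            d.validate()


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

TREES_COLUMNS = ["tree_id", "species", "lat", "lon", "d_m", "d_protocol", "h_m"]
SECTIONS_COLUMNS = ["tree_id", "pool", "green_mass_kg", "length_m", "d1_m",
                    "d2_m", "is_stump"]
DISCS_COLUMNS = ["tree_id", "disc_id", "location_class", "height_m"]
SUBSAMPLES_COLUMNS = ["disc_id", "position_index", "radial_position",
                      "green_mass_g", "dry_mass_g", "green_volume_cm3",
                      "dry_volume_cm3"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) {missing}")


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_harvest_tables(
    data_dir: str | Path,
    *,
    trees_file: str = "trees.csv",
    sections_file: str = "sections.csv",
    discs_file: str = "discs.csv",
    subsamples_file: str = "subsamples.csv",
) -> list[HarvestTree]:
    """Read the four linked campaign tables into validated trees.

    Tables are comma-separated UTF-8 with a mandatory header row; records
    are linked by ``tree_id`` and ``disc_id``. Every tree must have at
    least one weighed section; every disc at least one subsample.
    """
    data_dir = Path(data_dir)
    trees_df = pd.read_csv(data_dir / trees_file, float_precision="round_trip")
    sections_df = pd.read_csv(data_dir / sections_file, float_precision="round_trip")
    discs_df = pd.read_csv(data_dir / discs_file, float_precision="round_trip")
    subs_df = pd.read_csv(data_dir / subsamples_file, float_precision="round_trip")

    _require_columns(trees_df, TREES_COLUMNS, trees_file)
    _require_columns(sections_df, SECTIONS_COLUMNS, sections_file)
    _require_columns(discs_df, DISCS_COLUMNS, discs_file)
    _require_columns(subs_df, SUBSAMPLES_COLUMNS, subsamples_file)

    subs_by_disc: dict[str, list[tuple[int, Subsample]]] = {}
    for row in subs_df.itertuples(index=False):
        gv = _opt(row.green_volume_cm3)
        sub = Subsample(
            green_mass=float(row.green_mass_g),
            dry_mass=float(row.dry_mass_g),
            green_volume=gv,
            dry_volume=float(row.dry_volume_cm3),
            radial_position=str(row.radial_position),
            imputed_green_volume=False,
        )
        subs_by_disc.setdefault(str(row.disc_id), []).append(
            (int(row.position_index), sub)
        )

    discs_by_tree: dict[str, list[Disc]] = {}
    for row in discs_df.itertuples(index=False):
        disc_id = str(row.disc_id)
        ordered = [s for _, s in sorted(subs_by_disc.get(disc_id, []),
                                        key=lambda t: t[0])]
        disc = Disc(
            disc_id=disc_id,
            location_class=str(row.location_class),
            height_above_ground=_opt(row.height_m),
            subsamples=ordered,
        )
        discs_by_tree.setdefault(str(row.tree_id), []).append(disc)

    sections_by_tree: dict[str, list[Section]] = {}
    for row in sections_df.itertuples(index=False):
        section = Section(
            pool=str(row.pool),
            green_mass=float(row.green_mass_kg),
            length=_opt(row.length_m),
            end_diameter_1=_opt(row.d1_m),
            end_diameter_2=_opt(row.d2_m),
            is_stump=bool(row.is_stump),
        )
        sections_by_tree.setdefault(str(row.tree_id), []).append(section)

    trees: list[HarvestTree] = []
    for row in trees_df.itertuples(index=False):
        tid = str(row.tree_id)
        tree = HarvestTree(
            tree_id=tid,
            species=str(row.species),
            latitude=float(row.lat),
            longitude=float(row.lon),
            stem_diameter=float(row.d_m),
            tree_height=float(row.h_m),
            diameter_protocol=str(row.d_protocol),
            sections=sections_by_tree.get(tid, []),
            discs=discs_by_tree.get(tid, []),
        )
        tree.validate()
        trees.append(tree)
    return trees


def write_harvest_tables(trees: Iterable[HarvestTree], data_dir: str | Path) -> None:
    """Write trees back to the four campaign CSVs (inverse of the reader)."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    t_rows, s_rows, d_rows, ss_rows = [], [], [], []
    for tree in trees:
        t_rows.append({
            "tree_id": tree.tree_id, "species": tree.species,
            "lat": tree.latitude, "lon": tree.longitude,
            "d_m": tree.stem_diameter, "d_protocol": tree.diameter_protocol,
            "h_m": tree.tree_height,
        })
        for s in tree.sections:
            s_rows.append({
                "tree_id": tree.tree_id, "pool": s.pool,
                "green_mass_kg": s.green_mass, "length_m": s.length,
                "d1_m": s.end_diameter_1, "d2_m": s.end_diameter_2,
                "is_stump": s.is_stump,
            })
        for d in tree.discs:
            d_rows.append({
                "tree_id": tree.tree_id, "disc_id": d.disc_id,
                "location_class": d.location_class,
                "height_m": d.height_above_ground,
            })
            for i, ss in enumerate(d.subsamples):
                ss_rows.append({
                    "disc_id": d.disc_id, "position_index": i,
                    "radial_position": ss.radial_position,
                    "green_mass_g": ss.green_mass, "dry_mass_g": ss.dry_mass,
                    "green_volume_cm3": ss.green_volume,
                    "dry_volume_cm3": ss.dry_volume,
                })
    pd.DataFrame(t_rows, columns=TREES_COLUMNS).to_csv(
        data_dir / "trees.csv", index=False)
    pd.DataFrame(s_rows, columns=SECTIONS_COLUMNS).to_csv(
        data_dir / "sections.csv", index=False)
    pd.DataFrame(d_rows, columns=DISCS_COLUMNS).to_csv(
        data_dir / "discs.csv", index=False)
    pd.DataFrame(ss_rows, columns=SUBSAMPLES_COLUMNS).to_csv(
        data_dir / "subsamples.csv", index=False)


def read_density_db(path: str | Path) -> pd.DataFrame:
    """Read a literature wood-density lookup table (species, kg m-3)."""
    df = pd.read_csv(path)
    _require_columns(df, ["species", "basic_density_kg_m3"], str(path))
    return df


def write_report(results: pd.DataFrame, path: str | Path,
                 float_format: str = "%.1f") -> None:
    """Write a deterministic results CSV (fixed column order and precision).

    The same input always produces byte-identical output, so reports can be
    diffed across runs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    results.to_csv(buf, index=False, float_format=float_format,
                   lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
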