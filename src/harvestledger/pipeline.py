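"""End-to-end orchestration: harvest tables to performance report.

The pipeline runs densities -> reference AGB -> non-destructive estimators
-> error decomposition, writing deterministic CSVs (densities.csv,
reference_agb.csv, estimates.csv, performance.csv) and logging every
constant and approach used. Two runs with identical inputs and
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import density as density_mod
from .agb_estimators import (AGBEstimate, AllometricModel, allometric_estimate,
                             qsm_agb, read_qsm_tables)
from .config import PipelineConfig
from .errors import ConfigurationError, HarvestLedgerError
from .harvest_data import (HarvestTree, read_density_db, read_harvest_tables,
                           write_report)
from .performance import error_records, trueness_precision_accuracy
from .reference_agb import ReferenceAGB, reference_agb

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory bundle of everything a pipeline run computed."""

    trees: list[HarvestTree] = field(default_factory=list)
    densities: pd.DataFrame | None = None
    references: list[ReferenceAGB] = field(default_factory=list)
    estimates: list[AGBEstimate] = field(default_factory=list)
    performance: pd.DataFrame | None = None


def _density_rows(trees, approaches, density_db) -> tuple[pd.DataFrame, dict]:
    rows = []
    primary: dict[str, density_mod.DensityEstimate] = {}
    for tree in trees:
        density_mod.impute_missing_green_volumes(tree)
        for approach in approaches:
            est = density_mod.estimate_density(tree, approach, density_db)
            rows.append({
                "tree_id": tree.tree_id, "approach": approach,
                "basic_density_kg_m3": est.basic_density,
                "g2d_mass": est.g2d_mass_ratio,
                "g2d_volume": est.g2d_volume_ratio,
            })
        # reference AGB always needs the mass-weighted ratios
        primary[tree.tree_id] = density_mod.mass_weighted_density(tree)
    df = pd.DataFrame(rows, columns=["tree_id", "approach",
                                     "basic_density_kg_m3", "g2d_mass",
                                     "g2d_volume"])
    return df, primary


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full chain described by ``config``.

    Any stage failure aborts with a stage-named error; partial CSV outputs
    are removed so a result directory is either complete or absent.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    model = AllometricModel(config.allometric_coefficient,
                            config.allometric_exponent)
    logger.info("pipeline start: density approach=%s, allometric "
                "coefficient=%g exponent=%g, cut width=%g m, seed=%d",
                config.density_approach, model.coefficient, model.exponent,
                config.cut_width_m, config.seed)
    try:
        result = PipelineResult()
        try:
            result.trees = read_harvest_tables(config.data_dir)
        except HarvestLedgerError as exc:
            raise type(exc)(f"ingest: {exc}") from exc

        density_db = None
        approaches = ([config.density_approach]
                      if config.density_approach != "all"
                      else ["mass_weighted", "stem", "literature"])
        if "literature" in approaches:
            if config.density_db is None:
                raise ConfigurationError(
                    "density: literature approach requires density_db")
            density_db = read_density_db(config.density_db)
        try:
            result.densities, primary = _density_rows(result.trees,
                                                      approaches, density_db)
        except HarvestLedgerError as exc:
            raise type(exc)(f"density: {exc}") from exc

        try:
            result.references = [
                reference_agb(tree, primary[tree.tree_id],
                              cut_width=config.cut_width_m,
                              extra_cuts=config.extra_cuts)
                for tree in result.trees
            ]
        except HarvestLedgerError as exc:
            raise type(exc)(f"reference: {exc}") from exc

        approach = (config.density_approach
                    if config.density_approach != "all" else "mass_weighted")
        try:
            qsms = (read_qsm_tables(config.qsm_file)
                    if config.qsm_file else {})
            for tree in result.trees:
                rho = density_mod.estimate_density(tree, approach, density_db)
                # carry the mass-weighted ratios for green-density identities
                if rho.g2d_mass_ratio is None:
                    rho.g2d_mass_ratio = primary[tree.tree_id].g2d_mass_ratio
                result.estimates.append(allometric_estimate(
                    tree.tree_id, tree.stem_diameter, tree.tree_height, rho,
                    model))
                if tree.tree_id in qsms:
                    result.estimates.append(qsm_agb(qsms[tree.tree_id], rho))
        except HarvestLedgerError as exc:
            raise type(exc)(f"estimate: {exc}") from exc

        try:
            refs = {r.tree_id: r.agb_ref for r in result.references}
            panels = []
            for method in sorted({e.method for e in result.estimates}):
                ests = {e.tree_id: e.agb_est for e in result.estimates
                        if e.method == method}
                if set(ests) != set(refs):
                    logger.warning("performance: method %s lacks estimates "
                                   "for some trees; skipped", method)
                    continue
                table = trueness_precision_accuracy(
                    error_records(refs, ests), method)
                panels.append(vars(table))
            result.performance = pd.DataFrame(panels)
        except HarvestLedgerError as exc:
            raise type(exc)(f"performance: {exc}") from exc

        fmt = f"%.{config.report_decimals}f"
        ref_df = pd.DataFrame([{
            "tree_id": r.tree_id, "agb_ref_kg": r.agb_ref,
            "stem_kg": r.pool_dry_mass.get("stem", 0.0),
            "crown_kg": r.pool_dry_mass.get("crown", 0.0),
            "swarf_kg": r.swarf_correction, "swarf_pct": r.swarf_fraction,
            "crown_mass_ratio": r.crown_mass_ratio,
        } for r in result.references])
        est_df = pd.DataFrame([{
            "tree_id": e.tree_id, "method": e.method, "agb_est_kg": e.agb_est,
            "green_volume_m3": e.green_volume,
            "stem_fraction": e.stem_fraction,
        } for e in result.estimates])
        for name, df in (("densities.csv", result.densities),
                         ("reference_agb.csv", ref_df),
                         ("estimates.csv", est_df),
                         ("performance.csv", result.performance)):
            path = out_dir / name
            write_report(df, path, float_format=fmt)
            written.append(path)
        logger.info("pipeline complete: %d trees, %d estimates",
                    len(result.trees), len(result.estimates))
        return result
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
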