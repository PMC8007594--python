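"""End-to-end orchestration: scene -> classification -> products -> EMI ->
co-variability report, from a single validated config.

Every run writes its artifacts plus a manifest of SHA-256 checksums into
the output directory; with a fixed seed a rerun reproduces the manifest
bit-identically. All randomness flows through seeds derived from the one
configured seed via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import classify, emi, morphology, products, spatial, synth
from .grids import GridSpec, write_geotiff, write_point_csv, filter_yield_artifacts, convert_yield_units

log = logging.getLogger("soilplant")


@dataclass
class PipelineConfig:
    """Validated run configuration with the field-trial defaults."""

    out_dir: str = "run_out"
    seed: int = 0
    # scene synthesis
    extent_m: tuple = (100.0, 100.0)
    cell_size: float = 0.10
    row_spacing_m: float = 0.9
    plant_density: float = 0.7
    green_contrast: float = 60.0
    noise_sd: float = 5.0
    eca_range_m: float = 20.0
    eca_sill: float = 25.0
    eca_suppression: float = 0.6
    # classification
    ap_thresholds: tuple = (25, 100, 400)
    connectivity: int = 4
    n_train_per_class: int = 1000
    svm_c: float = 10.0
    folds: int = 5
    # products
    product_cell_m: float = 2.0
    block_cell_m: float = 20.0
    # EMI
    transect_spacing_m: float = 9.0
    antenna_offset_m: float = 4.5
    idw_power: float = 2.0
    idw_radius_m: float = 10.0
    eca_grid_m: float = 2.0
    expected_swath: int = 11
    section_boundaries: tuple | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 <= self.plant_density <= 1:
            raise ValueError("plant_density must be in [0, 1]")
        if self.product_cell_m % self.cell_size > 1e-9 \
                and abs(self.product_cell_m / self.cell_size
                        - round(self.product_cell_m / self.cell_size)) > 1e-9:
            raise ValueError("product cell must be a multiple of pixel size")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full synthetic-scene workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(4)]
    timings: dict[str, float] = {}
    current = {"stage": None, "t0": 0.0}

    def stage(name):
        log.info("stage: %s", name)
        current["stage"] = name
        current["t0"] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - current["t0"]

    try:
        stage("synthesis")
        scene = synth.make_scene(
            extent_m=tuple(config.extent_m), cell_size=config.cell_size,
            row_spacing_m=config.row_spacing_m,
            plant_density=config.plant_density,
            green_contrast=config.green_contrast, noise_sd=config.noise_sd,
            eca_range_m=config.eca_range_m, eca_sill=config.eca_sill,
            eca_suppression=config.eca_suppression, seed=seeds[0])
        write_geotiff(scene.rgb, out / "rgb.tif")
        write_geotiff(scene.true_mask, out / "true_mask.tif")
        write_geotiff(scene.true_eca, out / "true_eca.tif")
        done("synthesis")

        stage("classification")
        profile = morphology.build_profile(scene.rgb, config.ap_thresholds,
                                           config.connectivity)
        train = classify.extract_training_samples(
            profile, scene.true_mask, config.n_train_per_class, seed=seeds[1])
        model = classify.train_svm(train, c=config.svm_c)
        mask = classify.predict_mask_like(model, profile, scene.true_mask)
        report = classify.kfold_report(train, k=config.folds, seed=seeds[1],
                                       c=config.svm_c)
        write_geotiff(mask, out / "plant_mask.tif")
        report.to_json(out / "classification_report.json")
        done("classification")

        stage("products")
        pgrid = GridSpec.from_extent(scene.true_mask.extent,
                                     config.product_cell_m)
        abundance = products.compute_abundance(mask, pgrid)
        gcc = products.compute_gcc(scene.rgb)
        vigor = products.compute_vigor(gcc, mask, pgrid)
        height = products.compute_height(scene.dsm, scene.reference_dem)
        write_geotiff(abundance.percent, out / "abundance.tif")
        write_geotiff(vigor.gcc_mean, out / "vigor.tif")
        write_geotiff(height, out / "height.tif")
        done("products")

        stage("emi")
        survey = synth.emi_survey(scene.true_eca, soil_temp_c=18.0,
                                  transect_spacing_m=config.transect_spacing_m,
                                  seed=seeds[2],
                                  antenna_offset_m=config.antenna_offset_m)
        survey = emi.shift_correct(survey, offset_m=-config.antenna_offset_m)
        survey = emi.temperature_correct(survey)
        write_point_csv(survey, out / "emi_corrected.csv")
        egrid = GridSpec.from_extent(scene.true_eca.extent, config.eca_grid_m)
        surface = emi.interpolate_to_grid(survey, egrid,
                                          power=config.idw_power,
                                          search_radius_m=config.idw_radius_m)
        zones = emi.classify_eca_zones(surface)
        write_geotiff(surface.grid, out / "eca_surface.tif")
        write_geotiff(zones, out / "eca_zones.tif")
        done("emi")

        stage("statistics")
        ycloud = filter_yield_artifacts(scene.yield_cloud,
                                        config.expected_swath)
        ycloud = convert_yield_units(ycloud, "bu_ac_to_kg_ha")
        bgrid = GridSpec.from_extent(scene.true_mask.extent,
                                     config.block_cell_m)
        blocks = {
            "abundance": spatial.block_average(abundance.percent, bgrid),
            "vigor": spatial.block_average(vigor.gcc_mean, bgrid),
            "height": spatial.block_average(height, bgrid),
            "eca": spatial.block_average(surface.grid, bgrid),
            "yield_kg_ha": spatial.block_average(ycloud, bgrid),
            "elevation": spatial.block_average(scene.reference_dem, bgrid),
        }
        table = spatial.blocks_to_table(blocks)
        table = spatial.assign_sections(
            table, boundaries=config.section_boundaries,
            extent=(scene.true_mask.extent[0], scene.true_mask.extent[2]))
        zone_block = spatial.block_average(zones, bgrid)
        table["eca_zone"] = np.where(
            zone_block.values.ravel() == zone_block.nodata, np.nan,
            (zone_block.values.ravel() > 0.5).astype(float))
        pairs = [("eca", "abundance"), ("eca", "vigor"), ("eca", "height"),
                 ("eca", "elevation"), ("abundance", "yield_kg_ha")]
        corr = spatial.covariability_report(table, pairs)
        corr_all = spatial.covariability_report(table, pairs,
                                                section_col=None)
        summary = spatial.zone_summary(
            table, ["abundance", "vigor", "height", "yield_kg_ha"])
        table.to_csv(out / "blocks.csv", index=False)
        corr.to_csv(out / "covariability_by_section.csv", index=False)
        corr_all.to_csv(out / "covariability.csv", index=False)
        summary.to_csv(out / "zone_summary.csv", index=False)
        done("statistics")
    except Exception as exc:  # annotate the failing stage
        raise RuntimeError(
            f"pipeline failed in stage {current['stage']}: {exc}") from exc

    # timings.json varies between runs, so it stays out of the manifest
    artifacts = {}
    for p in sorted(out.iterdir()):
        if p.name in ("manifest.json", "timings.json") or p.is_dir():
            continue
        artifacts[p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(artifacts, fh, indent=2, sort_keys=True)
    with open(out / "timings.json", "w") as fh:
        json.dump({k: round(v, 3) for k, v in timings.items()}, fh,
                  indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return out
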