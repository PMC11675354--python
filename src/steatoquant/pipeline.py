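"""End-to-end pipeline: detection -> classification -> regions -> profile.

`run_pipeline` ties the modules together for one slide and (optionally)
writes a results bundle: candidates CSV, the 45-column profile CSV, the
diameter distribution CSV, region areas, the config used and a log. Errors
are re-raised tagged with the pipeline stage where they occurred.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cart as cart_mod
from . import detect as detect_mod
from . import io as io_mod
from . import quantify as quant_mod
from . import regions as regions_mod
from .config import PipelineConfig

logger = logging.getLogger("steatoquant")


class PipelineError(RuntimeError):
    """An error tagged with the pipeline stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineResult:
    """Everything one slide's run produced."""

    profile: quant_mod.SteatosisProfile
    distribution: quant_mod.DiameterDistribution
    candidates: list[detect_mod.VacuoleCandidate]
    fat_vacuoles: list[detect_mod.VacuoleCandidate]
    vessels: list[regions_mod.VesselCall]
    region_map: regions_mod.RegionMap
    tissue: io_mod.TissueMask
    config: PipelineConfig

    def profile_frame(self) -> pd.DataFrame:
        row = self.profile.to_dict()
        row["config_hash"] = self.config.hash()
        return pd.DataFrame([row])

    def distribution_frame(self) -> pd.DataFrame:
        d = self.distribution
        return pd.DataFrame(
            {
                "bin_start_um": d.bin_edges_um[:-1],
                "bin_end_um": d.bin_edges_um[1:],
                "count_per_mm2": d.counts_per_mm2,
            }
        )


def _stage(stage: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(
    slide: "io_mod.SlideImage | str | os.PathLike",
    model: "cart_mod.CartTree | str | os.PathLike",
    config: PipelineConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run the full steatosis analysis on one slide with a trained model."""
    cfg = config or PipelineConfig()

    img = _stage("load")(_load_slide)(slide, cfg)
    tree = _stage("load")(_load_model)(model)
    tissue = _stage("tissue")(io_mod.tissue_mask)(img, cfg.tissue_min_object_um2)
    logger.info("tissue area %.4f mm^2", tissue.tissue_area_mm2)

    candidates = _stage("detect")(detect_mod.detect_candidates)(
        img,
        tissue,
        cfg.min_diameter_um,
        cfg.max_diameter_um,
        cfg.annulus_width_um,
        cfg.max_hole_intensity_ratio,
    )
    logger.info("detected %d candidates", len(candidates))

    predictions = _stage("classify")(_classify)(tree, candidates)
    fat = [c for c, p in zip(candidates, predictions) if p == cart_mod.FAT]
    non_fat = [c for c, p in zip(candidates, predictions) if p != cart_mod.FAT]
    logger.info("classified %d fat vacuoles", len(fat))

    vessels = _stage("regions")(regions_mod.call_vessels)(
        non_fat, cfg.min_lumen_diameter_um, cfg.portal_collagen_fraction_min
    )
    region_map = _stage("regions")(regions_mod.build_region_map)(
        tissue, vessels, img.shg, cfg.halo_um, cfg.perisinusoidal_halo_um
    )

    profile = _stage("quantify")(quant_mod.quantify)(
        fat, region_map, tissue, cfg.macro_threshold_um
    )
    distribution = _stage("quantify")(quant_mod.diameter_distribution)(
        fat, tissue, cfg.bin_width_um, cfg.max_diameter_bin_um
    )

    result = PipelineResult(
        profile=profile,
        distribution=distribution,
        candidates=candidates,
        fat_vacuoles=fat,
        vessels=vessels,
        region_map=region_map,
        tissue=tissue,
        config=cfg,
    )
    if out_dir is not None:
        _stage("write")(_write_bundle)(result, Path(out_dir))
    return result


def _load_slide(slide, cfg: PipelineConfig) -> io_mod.SlideImage:
    if isinstance(slide, io_mod.SlideImage):
        return slide
    return io_mod.read_slide(slide, pixel_size_um=cfg.pixel_size_um)


def _load_model(model) -> cart_mod.CartTree:
    if isinstance(model, cart_mod.CartTree):
        return model
    if not Path(model).exists():
        raise FileNotFoundError(f"model file not found: {model}")
    return cart_mod.CartTree.load(model)


def _classify(tree: cart_mod.CartTree, candidates) -> np.ndarray:
    if not candidates:
        return np.array([], dtype=object)
    return tree.predict(cart_mod.feature_matrix(candidates))


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.profile_frame().to_csv(out_dir / "profile.csv", index=False)
    result.distribution_frame().to_csv(out_dir / "distribution.csv", index=False)
    detect_mod.candidates_to_frame(result.candidates).to_csv(
        out_dir / "candidates.csv", index=False
    )
    areas = pd.DataFrame(
        sorted(result.region_map.region_areas_mm2.items()),
        columns=["region", "area_mm2"],
    )
    areas.to_csv(out_dir / "region_areas.csv", index=False)
    result.config.to_yaml(out_dir / "config.yaml")
    io_mod.write_mask(out_dir / "tissue_mask.tif", result.tissue.mask)
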