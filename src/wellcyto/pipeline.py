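"""Pipeline orchestration: mono-culture counting and co-culture analysis.

``run_mono`` implements the counting chain (background subtraction →
nuclear segmentation → per-cell measurement); ``run_coculture`` implements
the full co-culture workflow: illumination-correct each stain channel,
build the inclusive population masks, barcode and filter nuclei per
population, grow seeded secondary objects, and measure features per
population.  Every run is deterministic given (inputs, config); each stage
emits one structured, machine-parsable log line.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .cytometry import WellSummary, measure_cells, summarize_well
from .io import WellImageSet, save_label_map, write_csv
from .populations import (
    absolute_counts,
    assign_barcodes,
    filter_nuclei_by_mask,
    make_population_mask,
)
from .preprocess import TileGrid, correct_illumination, subtract_background, enhance_contrast
from .segment import count_objects, segment_nuclei, segment_secondary

logger = logging.getLogger("wellcyto")


@contextmanager
def _stage(name: str, **info):
    t0 = time.perf_counter()
    out: dict = {}
    yield out
    extras = " ".join(f"{k}={v}" for k, v in {**info, **out}.items())
    logger.info("stage=%s wall_s=%.3f %s", name, time.perf_counter() - t0, extras)


@dataclasses.dataclass
class RunResult:
    """Outputs of one pipeline run on one well."""

    well_id: str
    summary: WellSummary
    records: pd.DataFrame
    nuclei_labels: np.ndarray
    cell_labels: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    barcodes: pd.DataFrame | None = None
    counts: dict[str, int] | None = None


def _preprocess_channel(image: np.ndarray, config: RunConfig) -> np.ndarray:
    out = subtract_background(image, config.preprocess.rolling_ball_radius)
    if config.preprocess.enhance_contrast is not None:
        out = enhance_contrast(out, config.preprocess.enhance_contrast)
    return out


def run_mono(wellset: WellImageSet, config: RunConfig) -> RunResult:
    """Mono-culture pipeline: absolute count plus nuclear-only features."""
    config.validate_channels(list(wellset.channels))
    nuclear = wellset.channel("nuclear")
    with _stage("preprocess", well=wellset.well_id):
        cleaned = _preprocess_channel(nuclear, config)
    with _stage("segment_nuclei", well=wellset.well_id) as info:
        labels = segment_nuclei(cleaned, config.nuclei)
        info["objects"] = count_objects(labels)
    with _stage("measure", well=wellset.well_id) as info:
        records = measure_cells(
            labels, labels, wellset, contact_radius_px=config.contact_radius_px
        )
        info["records"] = len(records)
    summary = summarize_well(records, well_id=wellset.well_id)
    return RunResult(
        well_id=wellset.well_id,
        summary=summary,
        records=records,
        nuclei_labels=labels,
    )


def _illumination_grid(wellset: WellImageSet) -> TileGrid:
    if wellset.tile_grid is not None:
        return wellset.tile_grid
    return TileGrid(1, 1)


def run_coculture(wellset: WellImageSet, config: RunConfig) -> RunResult:
    """Co-culture pipeline: per-population absolute counts and features.

    Stage order follows the published mask workflow: illumination-correct
    each stain → classify into an inclusive mask → apply the mask to the
    nuclei → count the retained nuclei, which then seed secondary
    whole-cell identification in their own stain channel.
    """
    if not config.populations:
        raise ValueError("co-culture run requires at least one population")
    config.validate_channels(list(wellset.channels))
    nuclear = wellset.channel("nuclear")
    with _stage("preprocess", well=wellset.well_id):
        cleaned = _preprocess_channel(nuclear, config)
    with _stage("segment_nuclei", well=wellset.well_id) as info:
        nuclei = segment_nuclei(cleaned, config.nuclei)
        info["objects"] = count_objects(nuclei)

    grid = _illumination_grid(wellset)
    stains: dict[str, np.ndarray] = {}
    masks = []
    for pop in config.populations:
        with _stage("population_mask", well=wellset.well_id, population=pop.name) as info:
            stain = _preprocess_channel(wellset.channel(pop.stain_channel), config)
            stain = correct_illumination(
                stain, grid, config.preprocess.illumination_smoothing_px
            )
            stains[pop.name] = stain
            mask = make_population_mask(stain, pop)
            masks.append(mask)
            info["mask_px"] = int(mask.sum())

    with _stage("assign_barcodes", well=wellset.well_id) as info:
        barcodes = assign_barcodes(
            nuclei, list(config.populations), masks, config.min_overlap_fraction
        )
        counts = absolute_counts(barcodes, list(config.populations))
        info["classes"] = len(counts)

    all_records = []
    cell_labels: dict[str, np.ndarray] = {}
    for pop, mask in zip(config.populations, masks):
        with _stage("secondary", well=wellset.well_id, population=pop.name) as info:
            seeds = filter_nuclei_by_mask(nuclei, mask, config.min_overlap_fraction)
            secondary = segment_secondary(
                stains[pop.name],
                seeds,
                threshold_method=pop.threshold_method,
                regularization=config.secondary_regularization,
                fixed_threshold=pop.fixed_threshold,
            )
            cell_labels[pop.name] = secondary
            records = measure_cells(
                secondary, seeds, wellset, contact_radius_px=config.contact_radius_px
            )
            records["population_class"] = pop.name
            all_records.append(records)
            info["objects"] = count_objects(secondary)

    records = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else measure_cells(np.zeros_like(nuclei), None, wellset)
    )
    pop_names = [p.name for p in config.populations]
    summary = summarize_well(records, populations=pop_names, well_id=wellset.well_id)
    # class counts come from the barcode table (the authoritative per-nucleus
    # assignment); the summary keeps the barcode-based totals
    summary.counts = dict(counts)
    summary.total = sum(counts.values())
    return RunResult(
        well_id=wellset.well_id,
        summary=summary,
        records=records,
        nuclei_labels=nuclei,
        cell_labels=cell_labels,
        barcodes=barcodes,
        counts=counts,
    )


def save_result(result: RunResult, directory: str | Path) -> dict[str, Path]:
    """Write per-cell, barcode, and summary CSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["records"] = write_csv(
        result.records, directory / f"{result.well_id}_cells.csv"
    )
    if result.barcodes is not None:
        paths["barcodes"] = write_csv(
            result.barcodes, directory / f"{result.well_id}_barcodes.csv"
        )
    summary = result.summary
    rows = []
    for cls, cnt in summary.counts.items():
        rows.append(
            {
                "well_id": summary.well_id,
                "class": cls,
                "count": cnt,
                "mean_area_px": summary.mean_area.get(cls, float("nan")),
                **{
                    f"mean_mfi_{ch}": v
                    for ch, v in summary.mean_mfi.get(cls, {}).items()
                },
            }
        )
    paths["summary"] = write_csv(
        pd.DataFrame(rows), directory / f"{result.well_id}_summary.csv"
    )
    paths["nuclei_labels"] = save_label_map(
        result.nuclei_labels, directory / f"{result.well_id}_nuclei_labels.tif"
    )
    for pop, labels in result.cell_labels.items():
        paths[f"cells_{pop}"] = save_label_map(
            labels, directory / f"{result.well_id}_cells_{pop}_labels.tif"
        )
    return paths
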