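"""Per-cell feature extraction and well-level statistics.

Turns label maps plus channel rasters into a flow-cytometry-style event
table (one row per cell: area, per-channel mean fluorescence intensity,
shape and neighborhood features), summarizes wells per population class,
fits the dilution-series regressions used to validate counting accuracy,
and implements the partial-well sampling strategies (random fields, box
crop, whole well) whose comparison motivates whole-well imaging.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .io import WellImageSet


def measure_cells(
    cell_labels: np.ndarray,
    nuclei_labels: np.ndarray | None,
    channels: WellImageSet | dict,
    contact_radius_px: float | None = None,
    barcodes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell records from a (secondary) label map.

    area = pixel count of the region; MFI = mean channel intensity over the
    region's pixels; eccentricity and orientation come from the region's
    second central moments (orientation in degrees, (-90, 90]); neighbors =
    number of other cells whose centroid lies within ``contact_radius_px``
    (default: twice the well's mean equivalent cell radius); the
    first-closest-object distance is the centroid distance to the nearest
    other cell, reported as missing (NaN) for a lone cell.

    When ``nuclei_labels`` is given, secondary labels are assumed aligned
    with their nuclear seeds and each record carries its nucleus area.
    """
    cell_labels = np.asarray(cell_labels)
    chan = channels.channels if isinstance(channels, WellImageSet) else dict(channels)
    n = int(cell_labels.max())
    channel_names = list(chan)
    cols = [
        "cell_id", "population_class", "row", "col", "area_px",
        "nucleus_area_px", "eccentricity", "orientation_deg",
        "n_neighbors", "closest_distance_px",
    ] + [f"mfi_{c}" for c in channel_names]
    if n == 0:
        return pd.DataFrame(columns=cols)

    props = regionprops(cell_labels)
    ids = np.array([p.label for p in props], dtype=int)
    centroids = np.array([p.centroid for p in props])
    areas = np.array([p.area for p in props], dtype=float)
    ecc = np.array([p.eccentricity for p in props])
    orient = np.degrees([p.orientation for p in props])

    nuc_areas = np.full(len(ids), np.nan)
    if nuclei_labels is not None:
        nuclei_labels = np.asarray(nuclei_labels)
        if nuclei_labels.shape != cell_labels.shape:
            raise ValueError("nuclei and cell label maps differ in shape")
        counts = np.bincount(nuclei_labels.ravel(), minlength=int(nuclei_labels.max()) + 1)
        nuc_areas = np.array(
            [counts[i] if i < len(counts) else 0 for i in ids], dtype=float
        )

    mfi = {}
    for name in channel_names:
        img = np.asarray(chan[name], dtype=np.float64)
        if img.shape != cell_labels.shape:
            raise ValueError(f"channel {name!r} shape differs from label map")
        mfi[name] = ndimage.mean(img, labels=cell_labels, index=ids)

    if contact_radius_px is None:
        contact_radius_px = 2.0 * float(np.mean(np.sqrt(areas / math.pi)))
    if len(ids) > 1:
        tree = cKDTree(centroids)
        dists, _ = tree.query(centroids, k=2)
        closest = dists[:, 1]
        neighbor_lists = tree.query_ball_point(centroids, r=contact_radius_px)
        n_neighbors = np.array([len(lst) - 1 for lst in neighbor_lists])
    else:
        closest = np.array([np.nan])
        n_neighbors = np.array([0])

    data = {
        "cell_id": ids,
        "population_class": "all",
        "row": centroids[:, 0],
        "col": centroids[:, 1],
        "area_px": areas,
        "nucleus_area_px": nuc_areas,
        "eccentricity": ecc,
        "orientation_deg": orient,
        "n_neighbors": n_neighbors,
        "closest_distance_px": closest,
    }
    for name in channel_names:
        data[f"mfi_{name}"] = np.asarray(mfi[name], dtype=float)
    records = pd.DataFrame(data)
    if barcodes is not None and len(barcodes):
        mapping = dict(zip(barcodes["nucleus_id"], barcodes["population_class"]))
        records["population_class"] = [
            mapping.get(i, "negative") for i in records["cell_id"]
        ]
    return records


@dataclasses.dataclass
class WellSummary:
    """Per-well class counts and per-class feature means.

    Empty classes report missing means (NaN), never 0, so condition-level
    normalization is not corrupted by absent populations.
    """

    well_id: str
    counts: dict[str, int]
    mean_area: dict[str, float]
    mean_mfi: dict[str, dict[str, float]]
    total: int


def summarize_well(
    records: pd.DataFrame,
    populations: list[str] | None = None,
    well_id: str = "well",
) -> WellSummary:
    """Aggregate per-cell records of one well into class-level statistics."""
    classes: list[str]
    if populations:
        classes = list(populations) + ["multi_positive", "negative"]
    else:
        classes = ["all"]
    if len(records):
        unknown = set(records["population_class"]) - set(classes)
        if unknown:
            raise ValueError(f"records contain unknown classes {sorted(unknown)}")
    mfi_cols = [c for c in records.columns if c.startswith("mfi_")]
    counts: dict[str, int] = {}
    mean_area: dict[str, float] = {}
    mean_mfi: dict[str, dict[str, float]] = {}
    for cls in classes:
        sub = records[records["population_class"] == cls] if len(records) else records
        counts[cls] = int(len(sub))
        mean_area[cls] = float(sub["area_px"].mean()) if len(sub) else math.nan
        mean_mfi[cls] = {
            c[len("mfi_"):]: (float(sub[c].mean()) if len(sub) else math.nan)
            for c in mfi_cols
        }
    return WellSummary(
        well_id=well_id,
        counts=counts,
        mean_area=mean_area,
        mean_mfi=mean_mfi,
        total=int(len(records)),
    )


def normalize_to_control(values: dict[str, float], control: str) -> dict[str, float]:
    """Divide each condition's value by the named control condition's value
    (the control normalizes to exactly 1.0)."""
    if control not in values:
        raise KeyError(f"control condition {control!r} not among {sorted(values)}")
    ref = values[control]
    if not ref or not math.isfinite(ref):
        raise ValueError(f"control condition {control!r} has unusable value {ref!r}")
    return {cond: v / ref for cond, v in values.items()}


@dataclasses.dataclass
class DilutionResult:
    """Plated vs measured counts with their least-squares line."""

    plated: np.ndarray
    measured: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def fit_dilution(plated, measured) -> DilutionResult:
    """Ordinary least squares of measured counts on plated counts.

    ``measured`` may be one value per plated point or a 2-D array of
    replicates (one row per plated point); replicates are fit as individual
    observations.  R² is defined against the mean-only model and cannot be
    negative for an OLS fit with intercept.
    """
    plated = np.asarray(plated, dtype=np.float64)
    measured = np.asarray(measured, dtype=np.float64)
    if measured.ndim == 2:
        if measured.shape[0] != plated.size:
            raise ValueError("replicate rows must match plated points")
        x = np.repeat(plated, measured.shape[1])
        y = measured.ravel()
    else:
        if measured.size != plated.size:
            raise ValueError("plated and measured lengths differ")
        x, y = plated, measured
    if x.size < 3:
        raise ValueError("need at least 3 points for a dilution fit")
    if np.all(x == x[0]):
        raise ValueError("degenerate fit: plated counts are constant")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    assert r2 >= 0.0
    return DilutionResult(
        plated=x, measured=y,
        slope=float(res.slope), intercept=float(res.intercept), r_squared=r2,
    )


@dataclasses.dataclass
class SampledFields:
    """Sub-rasters of a partial-well sampling plus their area fraction
    (fraction of the well's area covered, used to scale counts)."""

    fields: list[np.ndarray]
    area_fraction: float
    offsets: list[tuple[int, int]]


def sample_partial_well(
    raster: np.ndarray,
    mode: str,
    n_fields: int = 5,
    field_size: int | None = None,
    rng: np.random.Generator | int | None = None,
    well_center: tuple[float, float] | None = None,
    well_diameter_px: float | None = None,
) -> SampledFields:
    """Sample a well raster the three ways an experimenter might.

    ``"whole_well"`` returns the raster itself (fraction 1); ``"box_crop"``
    a single square of side ``field_size`` centered on the well;
    ``"random_fields"`` ``n_fields`` square fields placed uniformly inside
    the well (deterministic given ``rng``).  The area fraction is measured
    against the circular well footprint when the well geometry is known,
    else against the full raster.
    """
    img = np.asarray(raster)
    h, w = img.shape
    if mode == "whole_well":
        return SampledFields([img], 1.0, [(0, 0)])
    if field_size is None:
        raise ValueError(f"mode {mode!r} requires field_size")
    if field_size > min(h, w):
        raise ValueError(f"field size {field_size} exceeds raster {img.shape}")
    if well_center is None:
        well_center = ((h - 1) / 2.0, (w - 1) / 2.0)

    yy, xx = np.mgrid[0:h, 0:w]
    if well_diameter_px is not None:
        region = ((yy - well_center[0]) ** 2 + (xx - well_center[1]) ** 2) <= (
            well_diameter_px / 2.0
        ) ** 2
    else:
        region = np.ones((h, w), dtype=bool)

    covered = np.zeros((h, w), dtype=bool)
    fields: list[np.ndarray] = []
    offsets: list[tuple[int, int]] = []

    def add_field(r0: int, c0: int) -> None:
        r0 = int(np.clip(r0, 0, h - field_size))
        c0 = int(np.clip(c0, 0, w - field_size))
        fields.append(img[r0 : r0 + field_size, c0 : c0 + field_size])
        offsets.append((r0, c0))
        covered[r0 : r0 + field_size, c0 : c0 + field_size] = True

    if mode == "box_crop":
        add_field(
            int(round(well_center[0] - field_size / 2)),
            int(round(well_center[1] - field_size / 2)),
        )
    elif mode == "random_fields":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        radius = (well_diameter_px / 2.0) if well_diameter_px else min(h, w) / 2.0
        for _ in range(n_fields):
            phi = gen.uniform(0, 2 * math.pi)
            r = (radius - field_size / 2.0) * math.sqrt(gen.random())
            add_field(
                int(round(well_center[0] + r * math.sin(phi) - field_size / 2)),
                int(round(well_center[1] + r * math.cos(phi) - field_size / 2)),
            )
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")

    fraction = float((covered & region).sum()) / float(region.sum())
    return SampledFields(fields, fraction, offsets)


def estimate_count_by_sampling(
    raster: np.ndarray,
    mode: str,
    nuclei_params=None,
    **kwargs,
) -> float:
    """Count nuclei on the sampled sub-rasters and scale by area fraction."""
    from .segment import count_objects, segment_nuclei

    sampled = sample_partial_well(raster, mode, **kwargs)
    total = sum(count_objects(segment_nuclei(f, nuclei_params)) for f in sampled.fields)
    if sampled.area_fraction <= 0:
        raise ValueError("sampled area fraction is zero")
    return total / sampled.area_fraction
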