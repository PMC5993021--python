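"""Co-culture population assignment via inclusive stain masks.

Primary segmentation of cytoplasmic or surface stains is unreliable for
spindly or inhomogeneously stained cells, so populations are identified the
robust way: whole-cell fluorescence from each population's stain is turned
into an *inclusive* binary mask (hole-filled so a surface ring becomes a
full disk), and each segmented nucleus is assigned to every population
whose mask covers it.  Repeating the masking per stain groups every nucleus
with its cell population; nuclei claimed by several masks (double
positives) or by none are reported as their own classes rather than
force-assigned, since silent reassignment would bias absolute counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.segmentation import relabel_sequential

from .segment import robust_threshold

MULTI_POSITIVE = "multi_positive"
NEGATIVE = "negative"


@dataclasses.dataclass(frozen=True)
class PopulationDef:
    """A cell population identified by one stain channel plus mask rules."""

    name: str
    stain_channel: str
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    fill_holes: bool = True
    max_hole_px: int = 2000
    min_region_px: int = 32

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("population name must be nonempty")
        if self.name in (MULTI_POSITIVE, NEGATIVE):
            raise ValueError(f"population name {self.name!r} is reserved")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold requires fixed_threshold")
        if self.max_hole_px < 1 or self.min_region_px < 1:
            raise ValueError("max_hole_px and min_region_px must be positive")


def make_population_mask(stain_image: np.ndarray, params: PopulationDef) -> np.ndarray:
    """Inclusive binary mask of one population's whole-cell footprint.

    Threshold-classifies the (illumination-corrected) stain raster, fills
    interior holes up to ``max_hole_px`` (turning surface-stain rings into
    filled disks that retain the nuclei contained within), and removes
    speckle regions below ``min_region_px``.  A blank stain yields an empty
    mask.
    """
    img = np.asarray(stain_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)
    else:
        thr = robust_threshold(img)
    mask = img > thr
    if params.fill_holes and mask.any():
        # connectivity=1: holes are 4-connected background, matching the
        # package-wide raster topology convention; holes up to max_hole_px
        # pixels (inclusive) are filled
        mask = remove_small_holes(mask, connectivity=1, max_size=params.max_hole_px)
    if mask.any():
        # drop speckle regions strictly below min_region_px
        mask = remove_small_objects(
            mask, connectivity=2, max_size=params.min_region_px - 1
        )
    return mask


def overlap_fractions(nuclei: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-label fraction of nucleus pixels covered by the mask.

    Returns an array of length ``max_label + 1``; entry 0 is unused.
    """
    nuclei = np.asarray(nuclei)
    mask = np.asarray(mask, dtype=bool)
    if nuclei.shape != mask.shape:
        raise ValueError(f"shape mismatch: nuclei {nuclei.shape} vs mask {mask.shape}")
    n = int(nuclei.max())
    sizes = np.bincount(nuclei.ravel(), minlength=n + 1).astype(np.float64)
    inside = np.bincount(nuclei.ravel(), weights=mask.ravel(), minlength=n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(sizes > 0, inside / sizes, 0.0)
    frac[0] = 0.0
    return frac


def filter_nuclei_by_mask(
    nuclei: np.ndarray, mask: np.ndarray, min_overlap_fraction: float = 0.5
) -> np.ndarray:
    """Retain nuclei whose overlap with the mask reaches the threshold.

    Retained objects keep their exact pixel sets; labels are re-made
    contiguous (in ascending original-label order).
    """
    if not 0.0 < min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must be in (0, 1]")
    frac = overlap_fractions(nuclei, mask)
    keep = frac >= min_overlap_fraction
    keep[0] = False
    lut = np.zeros(len(frac), dtype=np.int32)
    lut[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    out = lut[np.asarray(nuclei)]
    out, _, _ = relabel_sequential(out)
    return out.astype(np.int32)


def assign_barcodes(
    nuclei: np.ndarray,
    populations: list[PopulationDef],
    masks: list[np.ndarray],
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-nucleus presence/absence barcode over all population masks.

    Membership in each population is tested independently (overlap fraction
    ≥ ``min_overlap_fraction``), so double- and zero-positive nuclei are
    representable.  Returns one row per nucleus with its centroid, the
    per-population overlap fractions, the barcode string (e.g. ``"A+B-"``),
    and the reporting class: the population name for single positives,
    ``"multi_positive"``, or ``"negative"``.
    """
    if len(populations) != len(masks):
        raise ValueError(
            f"{len(populations)} populations but {len(masks)} masks"
        )
    nuclei = np.asarray(nuclei)
    n = int(nuclei.max())
    ids = np.arange(1, n + 1)
    if n > 0:
        centroids = ndimage.center_of_mass(np.ones_like(nuclei), nuclei, ids)
        rows_c = [c[0] for c in centroids]
        cols_c = [c[1] for c in centroids]
    else:
        rows_c, cols_c = [], []
    data: dict = {
        "nucleus_id": ids,
        "row": rows_c,
        "col": cols_c,
    }
    members = []
    for pop, mask in zip(populations, masks):
        frac = overlap_fractions(nuclei, mask)[1:]
        data[f"overlap_{pop.name}"] = frac
        members.append(frac >= min_overlap_fraction)
    member_arr = (
        np.stack(members, axis=1) if members else np.zeros((n, 0), dtype=bool)
    )
    barcodes = []
    classes = []
    for i in range(n):
        code = "".join(
            f"{pop.name}{'+' if member_arr[i, k] else '-'}"
            for k, pop in enumerate(populations)
        )
        barcodes.append(code)
        positives = [pop.name for k, pop in enumerate(populations) if member_arr[i, k]]
        if len(positives) == 1:
            classes.append(positives[0])
        elif len(positives) > 1:
            classes.append(MULTI_POSITIVE)
        else:
            classes.append(NEGATIVE)
    data["barcode"] = barcodes
    data["population_class"] = classes
    return pd.DataFrame(data)


def absolute_counts(
    barcodes: pd.DataFrame, populations: list[PopulationDef] | list[str]
) -> dict[str, int]:
    """Totals per reporting class: one entry per population (its
    single-positive count) plus the multi-positive and negative classes.
    The class totals always sum to the number of nuclei."""
    names = [p.name if isinstance(p, PopulationDef) else str(p) for p in populations]
    counts = {name: 0 for name in names}
    counts[MULTI_POSITIVE] = 0
    counts[NEGATIVE] = 0
    if len(barcodes):
        observed = barcodes["population_class"].value_counts()
        for cls, cnt in observed.items():
            if cls not in counts:
                raise ValueError(f"barcode class {cls!r} unknown to populations {names}")
            counts[cls] = int(cnt)
    return counts


def relative_counts(counts: dict[str, int]) -> dict[str, float]:
    """Class percentages of the assayed sample; they sum to 100.

    Relative counts can invert the apparent direction of an effect between
    conditions (a population's share may rise while its absolute count
    falls), which is why absolute counts are the primary output.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("relative counts undefined for an empty well (total = 0)")
    return {cls: 100.0 * cnt / total for cls, cnt in counts.items()}
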