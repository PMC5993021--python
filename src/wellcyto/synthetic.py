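"""Synthetic whole-well renderer with per-cell ground truth.

Renders multi-channel fluorescence rasters that emulate what the microscope
sees for one well of a multiwell plate: DAPI-like nuclei (Gaussian-profiled
disks), a CFDA-like cytoplasmic stain (filled, possibly elongated ellipse
containing the nucleus), an antibody-like surface stain (a boundary band
around the cell body), per-tile radial vignetting, a broad autofluorescence
ring at the well edge, and sensor noise (Poisson gain plus additive
Gaussian), applied in that order.  Every rendered cell is recorded in a
ground-truth table so each downstream stage can be validated without real
microscopy data.

Determinism: a spec with the same ``rng_seed`` renders bit-identical
rasters.  Ground-truth mean intensities are recorded from each cell's own
clean contribution, before vignetting, the edge ring, and noise.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import WellImageSet, to_uint16
from .preprocess import TileGrid

KNOWN_CHANNELS = ("nuclear", "cytoplasmic", "surface")

#: ground-truth table columns, in order
TRUTH_COLUMNS = (
    "cell_id",
    "population",
    "row",
    "col",
    "nucleus_area_px",
    "cell_area_px",
    "mean_nuclear",
    "mean_cytoplasmic",
    "mean_surface",
)


class PlacementError(RuntimeError):
    """Raised when a well is over-confluent and cells cannot be placed."""


@dataclasses.dataclass(frozen=True)
class SyntheticPopulation:
    """One cell population to render.

    ``nucleus_radius_px`` is a (mean, sd) pair; each cell draws its radius
    from that normal, truncated at 1.5 px.  The cell body is an ellipse of
    equivalent radius ``cell_radius_factor`` times the nucleus radius;
    ``cell_shape="spindly"`` elongates it by ``elongation`` (> 1) at a
    random orientation while preserving area.  ``stain_inhomogeneity`` in
    [0, 1] modulates within-cell intensity by a smoothed noise field.
    """

    name: str
    n_cells: int
    nucleus_radius_px: tuple[float, float] = (5.0, 0.5)
    cell_shape: str = "round"
    elongation: float = 1.0
    stain_channels: tuple[str, ...] = ("nuclear",)
    stain_inhomogeneity: float = 0.0
    intensity_mean: float = 3000.0
    cell_radius_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.cell_shape not in ("round", "spindly"):
            raise ValueError(f"unknown cell_shape {self.cell_shape!r}")
        if self.cell_shape == "spindly" and not self.elongation > 1:
            raise ValueError("spindly cells require elongation > 1")
        if self.cell_shape == "round" and self.elongation != 1.0:
            raise ValueError("round cells must have elongation 1")
        unknown = set(self.stain_channels) - set(KNOWN_CHANNELS)
        if unknown:
            raise ValueError(f"unknown stain channels {sorted(unknown)}")
        if not 0.0 <= self.stain_inhomogeneity <= 1.0:
            raise ValueError("stain_inhomogeneity must be in [0, 1]")
        if self.intensity_mean <= 0:
            raise ValueError("intensity_mean must be positive")
        mean, sd = self.nucleus_radius_px
        if mean <= 0 or sd < 0:
            raise ValueError("nucleus radius mean must be > 0 and sd >= 0")
        # the cell body's minor semi-axis must still enclose the nucleus
        if self.cell_radius_factor / math.sqrt(self.elongation) < 1.1:
            raise ValueError(
                "cell body narrower than its nucleus: require "
                "cell_radius_factor / sqrt(elongation) >= 1.1"
            )


@dataclasses.dataclass(frozen=True)
class SyntheticWellSpec:
    """Parameters of one rendered well.

    The raster is ``tile_grid * tile_size_px`` pixels with the circular well
    of ``well_diameter_px`` inscribed at its center.  ``spacing`` controls
    the non-overlap constraint during placement: ``"nucleus"`` forbids
    nucleus–nucleus overlap only (cell bodies may touch — the segmentation
    confound real co-cultures show), ``"cell"`` keeps whole cell bodies
    disjoint.  ``radial_bias`` > 0 concentrates cells toward the well
    center (density ∝ ``(1 - (r/R)^2)^bias``), emulating the non-uniform
    settling that makes partial-well sampling unreliable.
    """

    well_diameter_px: int
    tile_size_px: int
    tile_grid: tuple[int, int] = (1, 1)
    populations: tuple[SyntheticPopulation, ...] = ()
    vignette_strength: float = 0.1
    edge_ring_amplitude: float = 400.0
    edge_ring_width_px: float | None = None
    gaussian_sd: float = 150.0
    poisson_gain: float = 0.0
    rng_seed: int = 0
    spacing: str = "nucleus"
    radial_bias: float = 0.0
    max_place_attempts: int = 500
    well_id: str = "well"

    def __post_init__(self) -> None:
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1 or self.tile_size_px < 1:
            raise ValueError("tile grid and tile size must be positive")
        if self.well_diameter_px < 8:
            raise ValueError("well_diameter_px too small")
        if min(rows, cols) * self.tile_size_px < self.well_diameter_px:
            raise ValueError("tile grid * tile size must cover the well diameter")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must be in [0, 1)")
        if self.edge_ring_amplitude < 0 or self.gaussian_sd < 0 or self.poisson_gain < 0:
            raise ValueError("amplitudes and noise parameters must be nonnegative")
        if self.spacing not in ("nucleus", "cell"):
            raise ValueError("spacing must be 'nucleus' or 'cell'")
        if isinstance(self.populations, list):
            object.__setattr__(self, "populations", tuple(self.populations))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.tile_grid[0] * self.tile_size_px, self.tile_grid[1] * self.tile_size_px)

    @property
    def well_center(self) -> tuple[float, float]:
        h, w = self.shape
        return ((h - 1) / 2.0, (w - 1) / 2.0)

    @property
    def ring_width(self) -> float:
        if self.edge_ring_width_px is not None:
            return float(self.edge_ring_width_px)
        return 0.12 * self.well_diameter_px


def vignette_profile(tile_size_px: int, strength: float) -> np.ndarray:
    """Per-tile radial intensity falloff: 1 at tile center, ``1 - strength``
    at the tile corners, quadratic in the normalized radius."""
    c = (tile_size_px - 1) / 2.0
    yy, xx = np.mgrid[0:tile_size_px, 0:tile_size_px]
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    return 1.0 - strength * d2 / (2.0 * c * c if c > 0 else 1.0)


def _sample_position(rng, center, max_r, bias):
    while True:
        u = rng.random()
        phi = rng.uniform(0.0, 2.0 * math.pi)
        r = max_r * math.sqrt(u)
        if bias > 0:
            w = (1.0 - (r / max_r) ** 2) ** bias
            if rng.random() > w:
                continue
        return center[0] + r * math.sin(phi), center[1] + r * math.cos(phi)


class _SpatialHash:
    """Uniform grid over placed cells for O(1) min-distance queries."""

    def __init__(self, bin_size: float) -> None:
        self.bin = max(bin_size, 1.0)
        self.cells: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def ok(self, r: float, c: float, radius: float) -> bool:
        bi, bj = int(r // self.bin), int(c // self.bin)
        for i in range(bi - 1, bi + 2):
            for j in range(bj - 1, bj + 2):
                for (pr, pc, prad) in self.cells.get((i, j), ()):
                    lim = radius + prad + 1.0
                    if (pr - r) ** 2 + (pc - c) ** 2 < lim * lim:
                        return False
        return True

    def add(self, r: float, c: float, radius: float) -> None:
        self.cells.setdefault((int(r // self.bin), int(c // self.bin)), []).append(
            (r, c, radius)
        )


def _inhomogeneity_field(rng, shape, strength):
    if strength <= 0:
        return 1.0
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, 1.5)
    peak = np.abs(smooth).max()
    if peak == 0:
        return 1.0
    return 1.0 + 0.5 * strength * (smooth / peak)


def render_well(spec: SyntheticWellSpec) -> tuple[WellImageSet, pd.DataFrame]:
    """Render one well; returns the image set and its ground-truth table.

    Raises :class:`PlacementError` (naming the achieved count) if the well
    is over-confluent and a cell cannot be placed within
    ``spec.max_place_attempts`` attempts.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    center = spec.well_center
    well_r = spec.well_diameter_px / 2.0

    channels_needed = sorted(
        {ch for pop in spec.populations for ch in pop.stain_channels},
        key=KNOWN_CHANNELS.index,
    )
    images = {ch: np.zeros((h, w), dtype=np.float64) for ch in channels_needed}

    max_cell_r = 1.0
    for pop in spec.populations:
        mean, sd = pop.nucleus_radius_px
        max_cell_r = max(max_cell_r, (mean + 4 * sd) * pop.cell_radius_factor)
    hash_grid = _SpatialHash(2 * max_cell_r + 2)

    rows: list[dict] = []
    cell_id = 0
    for pop in spec.populations:
        mean, sd = pop.nucleus_radius_px
        for _ in range(pop.n_cells):
            nuc_r = max(1.5, rng.normal(mean, sd)) if sd > 0 else max(1.5, mean)
            cell_r = nuc_r * pop.cell_radius_factor
            a = cell_r * math.sqrt(pop.elongation)
            b = cell_r / math.sqrt(pop.elongation)
            theta = rng.uniform(0.0, math.pi) if pop.cell_shape == "spindly" else 0.0
            margin = well_r - a - 2.0
            if margin <= 0:
                raise PlacementError(
                    f"well too small for cells of radius {cell_r:.1f}; "
                    f"placed {cell_id} of "
                    f"{sum(p.n_cells for p in spec.populations)} cells"
                )
            spacing_r = nuc_r if spec.spacing == "nucleus" else cell_r
            for attempt in range(spec.max_place_attempts):
                cy, cx = _sample_position(rng, center, margin, spec.radial_bias)
                if hash_grid.ok(cy, cx, spacing_r):
                    break
            else:
                raise PlacementError(
                    f"could not place cell after {spec.max_place_attempts} "
                    f"attempts (well over-confluent); placed {cell_id} of "
                    f"{sum(p.n_cells for p in spec.populations)} cells"
                )
            hash_grid.add(cy, cx, spacing_r)
            cell_id += 1
            record = _render_cell(
                images, rng, pop, cy, cx, nuc_r, a, b, theta, channels_needed
            )
            record.update(cell_id=cell_id, population=pop.name, row=cy, col=cx)
            rows.append(record)

    # per-tile vignetting, applied independently to every tile of every channel
    if spec.vignette_strength > 0 and images:
        tile_v = vignette_profile(spec.tile_size_px, spec.vignette_strength)
        full_v = np.tile(tile_v, spec.tile_grid)
        for ch in channels_needed:
            images[ch] *= full_v

    # autofluorescence ring at the well border, shared by all channels
    if spec.edge_ring_amplitude > 0 and images:
        yy, xx = np.mgrid[0:h, 0:w]
        rho = np.sqrt((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
        ring = spec.edge_ring_amplitude * np.exp(
            -((rho - well_r) ** 2) / (2.0 * spec.ring_width**2)
        )
        for ch in channels_needed:
            images[ch] += ring

    # sensor noise, applied last; channel order fixed for determinism
    for ch in channels_needed:
        img = images[ch]
        if spec.poisson_gain > 0:
            img = rng.poisson(img / spec.poisson_gain).astype(np.float64) * spec.poisson_gain
        if spec.gaussian_sd > 0:
            img = img + rng.normal(0.0, spec.gaussian_sd, size=img.shape)
        images[ch] = np.clip(img, 0.0, None).astype(np.float32)

    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    if truth.empty:
        truth = pd.DataFrame(columns=list(TRUTH_COLUMNS))
    wellset = WellImageSet(
        well_id=spec.well_id,
        channels={ch: images[ch] for ch in channels_needed},
        well_diameter_px=spec.well_diameter_px,
        well_center=center,
        tile_grid=TileGrid(spec.tile_grid[0], spec.tile_grid[1], spec.tile_size_px),
    )
    return wellset, truth


def _render_cell(images, rng, pop, cy, cx, nuc_r, a, b, theta, channels_needed):
    """Stamp one cell into the channel rasters; returns its truth fields."""
    h, w = next(iter(images.values())).shape if images else (0, 0)

    def window(extent):
        r0 = max(0, int(math.floor(cy - extent)))
        r1 = min(h, int(math.ceil(cy + extent)) + 1)
        c0 = max(0, int(math.floor(cx - extent)))
        c1 = min(w, int(math.ceil(cx + extent)) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        return (slice(r0, r1), slice(c0, c1)), yy - cy, xx - cx

    # nucleus: Gaussian-profiled disk, footprint = exact discretized disk
    win, dy, dx = window(nuc_r + 1)
    d2 = dy * dy + dx * dx
    nuc_mask = d2 <= nuc_r * nuc_r
    sigma = nuc_r / 1.5
    profile = pop.intensity_mean * np.exp(-d2 / (2.0 * sigma * sigma))
    mean_nuclear = math.nan
    if "nuclear" in pop.stain_channels:
        images["nuclear"][win][nuc_mask] += profile[nuc_mask]
        mean_nuclear = float(profile[nuc_mask].mean()) if nuc_mask.any() else math.nan
    nucleus_area = int(nuc_mask.sum())

    # cell body: rotated ellipse, area-preserving elongation
    winc, dyc, dxc = window(a + 1)
    ct, st = math.cos(theta), math.sin(theta)
    u = (dyc * ct + dxc * st) / a
    v = (-dyc * st + dxc * ct) / b
    rho2 = u * u + v * v
    foot = rho2 <= 1.0
    cell_area = int(foot.sum())

    mean_cyto = math.nan
    if "cytoplasmic" in pop.stain_channels:
        field = _inhomogeneity_field(rng, foot.shape, pop.stain_inhomogeneity)
        vals = np.asarray(pop.intensity_mean * (1.0 - 0.2 * rho2) * field)
        images["cytoplasmic"][winc][foot] += vals[foot]
        mean_cyto = float(vals[foot].mean()) if foot.any() else math.nan

    mean_surface = math.nan
    if "surface" in pop.stain_channels:
        interior = ndimage.binary_erosion(foot, iterations=2)
        band = foot & ~interior
        field = _inhomogeneity_field(rng, foot.shape, pop.stain_inhomogeneity)
        vals = pop.intensity_mean * np.broadcast_to(np.asarray(field, dtype=np.float64), foot.shape)
        images["surface"][winc][band] += vals[band]
        mean_surface = float(vals[band].mean()) if band.any() else math.nan

    return dict(
        nucleus_area_px=nucleus_area,
        cell_area_px=cell_area,
        mean_nuclear=mean_nuclear,
        mean_cytoplasmic=mean_cyto,
        mean_surface=mean_surface,
    )


def _scaled_populations(
    populations: tuple[SyntheticPopulation, ...], total: int
) -> tuple[SyntheticPopulation, ...]:
    base_total = sum(p.n_cells for p in populations)
    if base_total <= 0:
        raise ValueError("base spec must place at least one cell")
    scaled = []
    assigned = 0
    for i, pop in enumerate(populations):
        if i == len(populations) - 1:
            n = total - assigned
        else:
            n = int(round(total * pop.n_cells / base_total))
            assigned += n
        scaled.append(dataclasses.replace(pop, n_cells=max(0, n)))
    return tuple(scaled)


def render_dilution_plate(
    base_spec: SyntheticWellSpec,
    counts: list[int],
    replicates: int,
    rng_seed: int,
) -> list[tuple[WellImageSet, pd.DataFrame]]:
    """Render one well per (count, replicate) pair of a dilution series.

    Population sizes in ``base_spec`` are rescaled proportionally so each
    well totals the requested count.  Per-well seeds are the deterministic
    substream ``rng_seed + well_index``, so the same top-level seed renders
    a bit-identical plate.
    """
    if not counts:
        raise ValueError("counts must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be positive")
    wells = []
    index = 0
    for count in counts:
        if count < 0:
            raise ValueError("counts must be nonnegative")
        for rep in range(replicates):
            spec = dataclasses.replace(
                base_spec,
                populations=_scaled_populations(base_spec.populations, count),
                rng_seed=int(rng_seed) + index,
                well_id=f"{base_spec.well_id}_n{count}_r{rep}",
            )
            wells.append(render_well(spec))
            index += 1
    return wells


def write_tiles(wellset: WellImageSet, grid, directory) -> list:
    """Write each channel as a row-major grid of 16-bit TIFF tiles.

    ``grid`` is a :class:`TileGrid` or ``(rows, cols)`` pair.  Rasters not
    divisible by the grid are padded with zeros (same dialect as
    :func:`wellcyto.preprocess.crop_to_stack`); the tiles round-trip through
    :func:`wellcyto.preprocess.stitch_tiles`.
    """
    import tifffile
    from pathlib import Path

    from .preprocess import crop_to_stack

    if not isinstance(grid, TileGrid):
        grid = TileGrid(int(grid[0]), int(grid[1]))
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch in wellset.names():
        tiles = crop_to_stack(to_uint16(wellset.channels[ch]), grid)
        for idx, tile in enumerate(tiles):
            i, j = divmod(idx, grid.cols)
            path = directory / f"{wellset.well_id}_{ch}_r{i:02d}_c{j:02d}.tif"
            tifffile.imwrite(path, tile)
            paths.append(path)
    return paths
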