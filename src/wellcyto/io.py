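"""Reading and writing well images, plate layouts, and tabular outputs.

Raster conventions: 2-D grayscale arrays, 0-based ``(row, col)`` pixel
coordinates, row-major order.  On disk every channel is a 16-bit grayscale
TIFF named ``<well>_<channel>.tif`` for whole-well rasters, or
``<well>_<channel>_r<RR>_c<CC>.tif`` for abutting (zero-overlap) tiles.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .preprocess import TileGrid, stitch_tiles

#: channel names recognised by the pipeline, in canonical order
CHANNEL_ORDER = ("nuclear", "cytoplasmic", "surface")

#: tile grids the acquisition protocol defines per plate format
PLATE_TILE_GRIDS = {48: (10, 10), 12: (19, 19)}

_TILE_RE = re.compile(r"_r(\d+)_c(\d+)\.tif$")


class MissingChannelError(KeyError):
    """A required channel is absent from a well image set or directory."""


@dataclasses.dataclass
class WellImageSet:
    """Named-channel raster stack for one well — the pipeline's unit of work.

    Parameters
    ----------
    well_id:
        Identifier used in file names.
    channels:
        Mapping from channel name (e.g. ``"nuclear"``) to a 2-D raster.
        All rasters must share one shape.
    well_diameter_px, well_center:
        Optional physical geometry of the circular well within the raster;
        the well center is the origin of the tiled acquisition.
    tile_grid:
        Acquisition grid, if the raster was stitched from tiles.
    """

    well_id: str
    channels: dict[str, np.ndarray]
    well_diameter_px: int | None = None
    well_center: tuple[float, float] | None = None
    tile_grid: TileGrid | None = None

    def __post_init__(self) -> None:
        shapes = {ch: np.asarray(im).shape for ch, im in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for ch, im in self.channels.items():
            arr = np.asarray(im)
            if arr.ndim != 2:
                raise ValueError(f"channel {ch!r} is not a 2-D raster")
            self.channels[ch] = arr

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} not present in well {self.well_id!r}; "
                f"available: {sorted(self.channels)}"
            ) from None

    def names(self) -> list[str]:
        order = {ch: i for i, ch in enumerate(CHANNEL_ORDER)}
        return sorted(self.channels, key=lambda c: (order.get(c, 99), c))


def to_uint16(image: np.ndarray) -> np.ndarray:
    """Quantize a floating-point raster to 16 bits with saturation clipping."""
    arr = np.asarray(image, dtype=np.float64)
    return np.clip(np.rint(arr), 0, 65535).astype(np.uint16)


def save_well(wellset: WellImageSet, directory: str | Path) -> list[Path]:
    """Write one 16-bit TIFF per channel; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch in wellset.names():
        path = directory / f"{wellset.well_id}_{ch}.tif"
        tifffile.imwrite(path, to_uint16(wellset.channels[ch]))
        paths.append(path)
    return paths


_ALLOWED_DTYPES = ("uint8", "uint16", "float32", "float64")


def _read_raster(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.dtype.name not in _ALLOWED_DTYPES:
        raise ValueError(
            f"{path.name}: unsupported bit depth {arr.dtype}; "
            f"expected one of {_ALLOWED_DTYPES}"
        )
    return arr


def load_well(
    directory: str | Path,
    well_id: str,
    channels: list[str] | None = None,
    layout: "PlateLayout | None" = None,
) -> WellImageSet:
    """Load a well from whole-well TIFFs or a directory of row/col tiles.

    For each requested channel, a whole-well file ``<well>_<channel>.tif`` is
    preferred; otherwise tiles ``<well>_<channel>_r<RR>_c<CC>.tif`` are
    collected and stitched row-major.  Raises :class:`MissingChannelError`
    naming the first channel that cannot be found.
    """
    directory = Path(directory)
    if channels is None:
        if layout is not None:
            channels = list(layout.channels)
        else:
            channels = _discover_channels(directory, well_id)
    if not channels:
        raise MissingChannelError(f"no channel TIFFs for well {well_id!r} in {directory}")
    loaded: dict[str, np.ndarray] = {}
    for ch in channels:
        whole = directory / f"{well_id}_{ch}.tif"
        if whole.exists():
            loaded[ch] = _read_raster(whole)
            continue
        tiles = sorted(directory.glob(f"{well_id}_{ch}_r*_c*.tif"))
        if not tiles:
            raise MissingChannelError(
                f"channel {ch!r} for well {well_id!r} not found in {directory}"
            )
        loaded[ch] = _stitch_tile_files(tiles)
    grid = layout.tile_grid_obj() if layout is not None else None
    return WellImageSet(well_id=well_id, channels=loaded, tile_grid=grid)


def _discover_channels(directory: Path, well_id: str) -> list[str]:
    names = set()
    for path in directory.glob(f"{well_id}_*.tif"):
        stem = path.name[len(well_id) + 1 : -len(".tif")]
        stem = _TILE_RE.sub("", stem + ".tif")
        stem = stem[:-len(".tif")] if stem.endswith(".tif") else stem
        names.add(stem)
    order = {ch: i for i, ch in enumerate(CHANNEL_ORDER)}
    return sorted(names, key=lambda c: (order.get(c, 99), c))


def _stitch_tile_files(paths: list[Path]) -> np.ndarray:
    indexed = []
    for path in paths:
        m = _TILE_RE.search(path.name)
        if m is None:
            raise ValueError(f"tile file {path.name} lacks _rRR_cCC indices")
        indexed.append((int(m.group(1)), int(m.group(2)), path))
    indexed.sort()
    rows = max(r for r, _, _ in indexed) + 1
    cols = max(c for _, c, _ in indexed) + 1
    tiles = [_read_raster(p) for _, _, p in indexed]
    shapes = {t.shape for t in tiles}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent tile shapes: {sorted(shapes)}")
    grid = TileGrid(rows=rows, cols=cols, tile_size_px=tiles[0].shape[0])
    return stitch_tiles(tiles, grid)


@dataclasses.dataclass(frozen=True)
class PlateLayout:
    """Plate format, acquisition tile grid, and channel roster.

    The two formats the acquisition protocol prints are seeded in
    :data:`PLATE_TILE_GRIDS` (48-well → 10×10 tiles, 12-well → 19×19 tiles);
    any other format requires an explicit ``tile_grid``.
    """

    n_wells: int
    tile_grid: tuple[int, int]
    tile_size_px: int = 1600
    channels: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: {"nuclear": "nuclear"}
    )

    def __post_init__(self) -> None:
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1 or self.tile_size_px < 1:
            raise ValueError("tile grid and tile size must be positive")
        names = list(self.channels)
        if len(names) != len(set(names)):
            raise ValueError("channel names must be unique")

    @classmethod
    def for_format(
        cls,
        n_wells: int,
        tile_size_px: int = 1600,
        channels: Mapping[str, str] | None = None,
    ) -> "PlateLayout":
        if n_wells not in PLATE_TILE_GRIDS:
            raise ValueError(
                f"no default tile grid for a {n_wells}-well plate; "
                "pass tile_grid explicitly"
            )
        return cls(
            n_wells=n_wells,
            tile_grid=PLATE_TILE_GRIDS[n_wells],
            tile_size_px=tile_size_px,
            channels=dict(channels or {"nuclear": "nuclear"}),
        )

    def tile_grid_obj(self) -> TileGrid:
        return TileGrid(self.tile_grid[0], self.tile_grid[1], self.tile_size_px)


def save_label_map(labels: np.ndarray, path: str | Path) -> Path:
    """Persist a label map as TIFF (16-bit when labels fit, else 32-bit)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    return path


def save_qc_overlay(image: np.ndarray, labels: np.ndarray, path: str | Path) -> Path:
    """Write a PNG of object outlines drawn over the grayscale raster."""
    import imageio.v3 as iio
    from skimage.segmentation import mark_boundaries

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = np.asarray(image, dtype=np.float64)
    top = np.quantile(img, 0.999) or 1.0
    base = np.clip(img / top, 0.0, 1.0)
    overlay = mark_boundaries(base, np.asarray(labels), color=(1.0, 0.2, 0.2))
    iio.imwrite(path, (overlay * 255).astype(np.uint8))
    return path


def write_csv(df, path: str | Path) -> Path:
    """Write a DataFrame as comma-separated UTF-8 with header, empty missing
    values and ``\\n`` line endings — pinned so re-runs are byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", na_rep="")
    return path
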