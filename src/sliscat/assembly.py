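"""Assembling per-pixel scattering patterns from an image series.

A scatterometry measurement yields one camera image per kernel position,
i.e. an ``m × m`` grid of ``H × W`` images.  Pivoting the axes gives, for
every image pixel, an ``m × m`` *scattering pattern*: entry ``(i, j)`` of the
pattern at pixel ``p`` is the value of pixel ``p`` in the image recorded with
the kernel at grid position ``(i, j)``.  The first recorded image (kernel in
the display's upper-left corner) therefore lands in the upper-left corner of
every pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SCAN_ORDERS = ("row-major", "column-major", "serpentine")


class AssemblyError(ValueError):
    """Raised for incomplete or inconsistent image series."""


@dataclass
class SeriesMeta:
    """Acquisition metadata of an image series."""

    kernel_size: int = 1
    kernels_per_side: int = 64
    shots: int = 1
    illumination_time_s: float = 1.0
    gain: float = 1.0
    scan_order: str = "row-major"

    def __post_init__(self) -> None:
        if self.scan_order not in SCAN_ORDERS:
            raise AssemblyError(f"unknown scan order {self.scan_order!r}")


@dataclass
class ImageSeries:
    """Grid of camera images indexed by kernel position.

    ``images`` has shape ``(grid_rows, grid_cols, H, W)``; shot averaging has
    already been applied.  A full scatterometry series is square
    (``grid_rows == grid_cols == m``); a calibration scan may be ``1 × m``.
    """

    images: np.ndarray
    meta: SeriesMeta = field(default_factory=SeriesMeta)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 4:
            raise AssemblyError("images must have shape (rows, cols, H, W)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.images.shape[:2]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[2:]


@dataclass
class ScatteringPattern:
    """One pixel's m×m scattering pattern with centring information.

    ``center`` (fractional ``(row, col)``) and ``crop_radius`` are filled by
    :func:`sliscat.profiles.center_pattern`; ``degenerate_center`` flags an
    all-equal pattern whose centre defaulted to the geometric middle.
    """

    values: np.ndarray
    center: tuple[float, float] | None = None
    crop_radius: float | None = None
    degenerate_center: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise AssemblyError("pattern values must be 2-D")
        if self.center is not None:
            r, c = self.center
            rows, cols = self.values.shape
            if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
                raise AssemblyError(f"center {self.center} outside pattern")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PatternCube:
    """Per-pixel scattering patterns: array of shape ``(H, W, m, m)``."""

    patterns: np.ndarray
    meta: SeriesMeta = field(default_factory=SeriesMeta)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns)
        if self.patterns.ndim != 4:
            raise AssemblyError("patterns must have shape (H, W, m, m)")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.patterns.shape[:2]

    def pattern(self, row: int, col: int) -> ScatteringPattern:
        return ScatteringPattern(values=self.patterns[row, col])

    def to_series(self) -> ImageSeries:
        """Re-serialise the cube into the image-series layout (exact inverse)."""
        return ImageSeries(
            images=np.ascontiguousarray(np.moveaxis(self.patterns, (2, 3), (0, 1))),
            meta=self.meta,
        )


def average_shots(repeats: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise arithmetic mean of repeated exposures at one kernel position.

    Up to a few shots are recorded per kernel position to reduce noise; the
    raw frames are averaged and stored as 32-bit floats.
    """
    frames = [np.asarray(f) for f in repeats]
    if not frames:
        raise AssemblyError("need at least one shot")
    shape = frames[0].shape
    for f in frames[1:]:
        if f.shape != shape:
            raise AssemblyError(f"shot shape mismatch: {f.shape} vs {shape}")
    return np.mean(np.stack(frames, axis=0), axis=0, dtype=np.float64).astype(
        np.float32
    )


def assemble(
    series: ImageSeries,
    roi: tuple[slice, slice] | None = None,
    chunk_rows: int | None = None,
    memory_budget_bytes: int = 256 * 1024 * 1024,
) -> PatternCube:
    """Pivot an image series into the per-pixel pattern cube.

    ``cube[p][i, j] == images[i, j][p]`` for every pixel ``p`` and kernel
    position ``(i, j)``.  ``roi`` restricts the image pixels (not the kernel
    grid).  The pivot runs over row chunks so the peak working set stays
    below ``memory_budget_bytes`` regardless of image size; ``chunk_rows``
    overrides the derived chunk height.
    """
    grid_rows, grid_cols, height, width = series.images.shape
    if grid_rows != grid_cols:
        raise AssemblyError(
            f"assemble needs a square kernel grid, got {grid_rows}x{grid_cols}"
        )
    nan_mask = np.isnan(series.images).reshape(grid_rows * grid_cols, -1).all(axis=1)
    if nan_mask.any():
        missing = [
            (int(i // grid_cols), int(i % grid_cols))
            for i in np.flatnonzero(nan_mask)
        ]
        raise AssemblyError(f"missing kernel positions: {missing}")

    if roi is None:
        roi = (slice(0, height), slice(0, width))
    sub = series.images[:, :, roi[0], roi[1]]
    _, _, sub_h, sub_w = sub.shape
    if chunk_rows is None:
        bytes_per_row = grid_rows * grid_cols * sub_w * 4 * 2  # in + out copy
        chunk_rows = max(1, int(memory_budget_bytes // max(1, bytes_per_row)))
    out = np.empty((sub_h, sub_w, grid_rows, grid_cols), dtype=np.float32)
    for start in range(0, sub_h, chunk_rows):
        stop = min(start + chunk_rows, sub_h)
        block = sub[:, :, start:stop, :]  # (m, m, rows, W)
        out[start:stop] = np.moveaxis(block, (0, 1), (2, 3))
    return PatternCube(patterns=out, meta=series.meta)


# ---------------------------------------------------------------------------
# File I/O: TIFF series and HDF5 cubes


def _kernel_index_order(m: int, scan_order: str) -> Iterable[tuple[int, int]]:
    if scan_order == "row-major":
        for i in range(m):
            for j in range(m):
                yield i, j
    elif scan_order == "column-major":
        for j in range(m):
            for i in range(m):
                yield i, j
    elif scan_order == "serpentine":
        for i in range(m):
            cols = range(m) if i % 2 == 0 else range(m - 1, -1, -1)
            for j in cols:
                yield i, j
    else:
        raise AssemblyError(f"unknown scan order {scan_order!r}")


def save_series_tiffs(series: ImageSeries, directory) -> list[Path]:
    """Write a series as numbered single-page TIFFs ``i_{row}_{col}.tif``."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    rows, cols = series.grid_shape
    for i in range(rows):
        for j in range(cols):
            path = directory / f"i_{i:03d}_{j:03d}.tif"
            tifffile.imwrite(path, series.images[i, j].astype(np.float32))
            paths.append(path)
    return paths


def load_series_tiffs(directory, meta: SeriesMeta | None = None) -> ImageSeries:
    """Load a series written by :func:`save_series_tiffs`.

    Shot suffixes (``i_{row}_{col}_s{shot}.tif``) are averaged per position.
    """
    import re

    import tifffile

    directory = Path(directory)
    pattern = re.compile(r"i_(\d+)_(\d+)(?:_s(\d+))?\.tif{1,2}$")
    groups: dict[tuple[int, int], list[Path]] = {}
    for path in sorted(directory.iterdir()):
        match = pattern.match(path.name)
        if match:
            key = (int(match.group(1)), int(match.group(2)))
            groups.setdefault(key, []).append(path)
    if not groups:
        raise AssemblyError(f"no series TIFFs found in {directory}")
    rows = 1 + max(k[0] for k in groups)
    cols = 1 + max(k[1] for k in groups)
    missing = [
        (i, j) for i in range(rows) for j in range(cols) if (i, j) not in groups
    ]
    if missing:
        raise AssemblyError(f"missing kernel positions: {missing}")
    first = tifffile.imread(groups[(0, 0)][0])
    images = np.empty((rows, cols) + first.shape, dtype=np.float32)
    for (i, j), paths in groups.items():
        images[i, j] = average_shots([tifffile.imread(p) for p in paths])
    if meta is None:
        meta = SeriesMeta(kernels_per_side=max(rows, cols))
    return ImageSeries(images=images, meta=meta)


def save_cube_h5(cube: PatternCube, path) -> None:
    """Persist a pattern cube as chunked HDF5; one pattern per chunk."""
    import h5py

    h, w, m1, m2 = cube.patterns.shape
    with h5py.File(path, "w") as handle:
        dset = handle.create_dataset(
            "patterns",
            data=cube.patterns.astype(np.float32),
            chunks=(1, 1, m1, m2),
        )
        dset.attrs["kernel_size"] = cube.meta.kernel_size
        dset.attrs["kernels_per_side"] = cube.meta.kernels_per_side
        dset.attrs["shots"] = cube.meta.shots
        dset.attrs["illumination_time_s"] = cube.meta.illumination_time_s
        dset.attrs["gain"] = cube.meta.gain
        dset.attrs["scan_order"] = cube.meta.scan_order


def load_cube_h5(path) -> PatternCube:
    import h5py

    with h5py.File(path, "r") as handle:
        dset = handle["patterns"]
        meta = SeriesMeta(
            kernel_size=int(dset.attrs["kernel_size"]),
            kernels_per_side=int(dset.attrs["kernels_per_side"]),
            shots=int(dset.attrs["shots"]),
            illumination_time_s=float(dset.attrs["illumination_time_s"]),
            gain=float(dset.attrs["gain"]),
            scan_order=str(dset.attrs["scan_order"]),
        )
        return PatternCube(patterns=dset[()], meta=meta)
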