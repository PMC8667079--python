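"""Azimuthal line profiles of scattering patterns.

Each scattering pattern contains a bright region where unscattered light
falls straight into the camera; its position varies across the field of view.
The pattern is therefore centred on the centroid of its maximum-intensity
pixels, cropped to the largest circle that fits around that centre, and
radially integrated: the profile value at azimuth ``phi`` is the sum of
bilinearly interpolated intensities at one-pixel radial steps from the centre
to the crop circle, with ``phi = 0`` at the top of the pattern and increasing
clockwise.  Peaks of the resulting periodic curve sit perpendicular to the
in-plane fiber directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import ScatteringPattern


class ProfileError(ValueError):
    """Raised for patterns too small or points outside the sampling domain."""


@dataclass
class SLIProfile:
    """Periodic azimuthal intensity curve ``I(phi)``.

    ``values[k]`` is the integral at ``phi = k * delta_phi`` degrees (bin
    starts, not centres).  ``radius_px`` records the integration radius so
    border pixels with tiny crop circles can be filtered downstream.
    """

    values: np.ndarray
    delta_phi: float
    radius_px: int = 0
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = round(360.0 / self.delta_phi)
        if n != len(self.values) or abs(n * self.delta_phi - 360.0) > 1e-9:
            raise ProfileError(
                f"length {len(self.values)} inconsistent with delta_phi "
                f"{self.delta_phi}"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def angles(self) -> np.ndarray:
        """Azimuth of each bin in degrees."""
        return np.arange(len(self.values)) * self.delta_phi

    def normalized(self) -> np.ndarray:
        """Min-max normalised copy of the values (flat profile maps to 0)."""
        lo = self.values.min()
        span = self.values.max() - lo
        if span == 0:
            return np.zeros_like(self.values)
        return (self.values - lo) / span


def find_center(pattern: ScatteringPattern) -> tuple[float, float, bool]:
    """Centroid of the maximum-intensity pixels of a pattern.

    Scattering patterns are not radially symmetric, so the plain intensity
    centroid would be biased by the reflexes; instead the centre of the
    unscattered beam is estimated as the centroid of all pixels attaining
    the maximum value.  Returns ``(row, col, degenerate)``; for an all-equal
    pattern the geometric centre is returned with ``degenerate=True``.
    """
    values = np.asarray(pattern.values, dtype=float)
    if values.size == 0:
        raise ProfileError("empty pattern")
    if np.ptp(values) == 0:
        rows, cols = values.shape
        return (rows - 1) / 2.0, (cols - 1) / 2.0, True
    peak_rows, peak_cols = np.nonzero(values == values.max())
    return float(peak_rows.mean()), float(peak_cols.mean()), False


def crop_radius(shape: tuple[int, int], center: tuple[float, float]) -> float:
    """Radius of the largest centred disc that fits inside the matrix."""
    rows, cols = shape
    r, c = center
    if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
        raise ProfileError(f"center {center} outside shape {shape}")
    return float(min(r, rows - 1 - r, c, cols - 1 - c))


def center_pattern(pattern: ScatteringPattern) -> ScatteringPattern:
    """Fill ``center``, ``crop_radius`` and the degenerate flag in place."""
    row, col, degenerate = find_center(pattern)
    pattern.center = (row, col)
    pattern.crop_radius = crop_radius(pattern.shape, (row, col))
    pattern.degenerate_center = degenerate
    return pattern


def bilinear_sample(values: np.ndarray, rows, cols):
    """Bilinear interpolation of ``values`` at fractional ``(rows, cols)``.

    Accepts scalars or arrays; every point must lie inside
    ``[0, H-1] x [0, W-1]`` (the caller guarantees the crop circle is
    interior to the pattern).
    """
    values = np.asarray(values, dtype=float)
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    h, w = values.shape
    if (rows < 0).any() or (rows > h - 1).any() or (cols < 0).any() or (
        cols > w - 1
    ).any():
        raise ProfileError("sample point outside the pattern")
    r0 = np.clip(np.floor(rows).astype(int), 0, h - 2)
    c0 = np.clip(np.floor(cols).astype(int), 0, w - 2)
    fr = rows - r0
    fc = cols - c0
    top = values[r0, c0] * (1 - fc) + values[r0, c0 + 1] * fc
    bottom = values[r0 + 1, c0] * (1 - fc) + values[r0 + 1, c0 + 1] * fc
    out = top * (1 - fr) + bottom * fr
    return out if out.ndim else float(out)


def azimuthal_profile(
    pattern: ScatteringPattern,
    delta_phi: float = 1.0,
    include_center: bool = False,
) -> SLIProfile:
    """Integrate a centred pattern radially for each azimuth bin.

    ``I(phi) = sum_{r=1..floor(R)} pattern(center + r * (-cos phi, +sin phi))``
    with bilinear interpolation at each sample; the fractional final step is
    dropped ("one pixel steps") and the centre sample ``r = 0`` is excluded by
    default so the constant central-blob value does not offset every bin
    (``include_center=True`` restores it).
    """
    if pattern.center is None or pattern.crop_radius is None:
        center_pattern(pattern)
    n_bins = round(360.0 / delta_phi)
    if abs(n_bins * delta_phi - 360.0) > 1e-9:
        raise ProfileError(f"360 must be divisible by delta_phi, got {delta_phi}")
    radius = int(np.floor(pattern.crop_radius))
    if radius < 1:
        raise ProfileError(
            f"pattern too small to integrate (crop radius {pattern.crop_radius})"
        )
    phi = np.radians(np.arange(n_bins) * delta_phi)
    r = np.arange(1, radius + 1, dtype=float)
    cr, cc = pattern.center
    rows = cr - np.outer(r, np.cos(phi))
    cols = cc + np.outer(r, np.sin(phi))
    samples = bilinear_sample(pattern.values, rows, cols)
    values = samples.sum(axis=0)
    if include_center:
        values = values + bilinear_sample(pattern.values, cr, cc)
    return SLIProfile(
        values=values,
        delta_phi=delta_phi,
        radius_px=radius,
        source={"center": pattern.center, "degenerate": pattern.degenerate_center},
    )


def profiles_from_cube(cube, delta_phi: float = 1.0, min_radius: int = 1):
    """Compute one profile per cube pixel; yields ``(row, col, profile)``.

    Pixels whose crop circle is smaller than ``min_radius`` (pattern border
    artefacts) yield ``None`` in place of a profile.
    """
    h, w = cube.image_shape
    for row in range(h):
        for col in range(w):
            pattern = cube.pattern(row, col)
            center_pattern(pattern)
            if int(np.floor(pattern.crop_radius)) < max(1, min_radius):
                yield row, col, None
                continue
            profile = azimuthal_profile(pattern, delta_phi)
            profile.source.update({"row": row, "col": col})
            yield row, col, profile


def write_profiles_h5(path, entries, delta_phi: float) -> None:
    """Compact binary profile table: datasets ``pixels`` (y, x, center_row,
    center_col, radius) and ``values`` (one row of I(phi) per profile)."""
    import h5py

    kept = [(r, c, p) for r, c, p in entries if p is not None]
    n_bins = round(360.0 / delta_phi)
    pixels = np.zeros((len(kept), 5), dtype=np.float32)
    values = np.zeros((len(kept), n_bins), dtype=np.float32)
    for k, (row, col, profile) in enumerate(kept):
        cr, cc = profile.source.get("center", (np.nan, np.nan))
        pixels[k] = (row, col, cr, cc, profile.radius_px)
        values[k] = profile.values
    with h5py.File(path, "w") as handle:
        handle.create_dataset("pixels", data=pixels)
        dset = handle.create_dataset("values", data=values)
        dset.attrs["delta_phi"] = delta_phi


def write_profiles_csv(path, entries, delta_phi: float) -> None:
    """Write profiles as CSV: y, x, center_row, center_col, radius, I(0), ...

    ``entries`` is an iterable of ``(row, col, profile_or_None)``.
    """
    n_bins = round(360.0 / delta_phi)
    header = "y,x,center_row,center_col,radius," + ",".join(
        f"I({k * delta_phi:g})" for k in range(n_bins)
    )
    with open(path, "w") as handle:
        handle.write(header + "\n")
        for row, col, profile in entries:
            if profile is None:
                continue
            cr, cc = profile.source.get("center", (np.nan, np.nan))
            fields = [str(row), str(col), f"{cr:.3f}", f"{cc:.3f}",
                      str(profile.radius_px)]
            fields += [f"{v:.6g}" for v in profile.values]
            handle.write(",".join(fields) + "\n")
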