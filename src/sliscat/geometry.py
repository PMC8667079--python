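"""Measurement geometry of the LED-display scatterometer.

The instrument illuminates a thin tissue section from below with a square
*kernel* of ``n × n`` LEDs that is scanned across an LED display (``m × m``
kernel positions), while a camera above the sample records the transmitted
light at normal incidence.  This module maps display/kernel coordinates and
image-pixel positions to illumination angles ``(theta, phi)``, provides the
gnomonic-projection ring radii used to annotate scattering patterns, and
computes the diffusor calibration curve (mean transmitted intensity versus
illumination angle).

Angle conventions
-----------------
* ``theta`` — polar angle from the sample normal, degrees in ``[0, 90)``.
* ``phi``  — azimuth, degrees in ``[0, 360)``; ``phi = 0`` points to the top
  of the display (and of the assembled scattering pattern), increasing
  clockwise as displayed.  In ``(row, col)`` image coordinates the unit step
  for azimuth ``phi`` is ``(d_row, d_col) = (-cos(phi), +sin(phi))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised for inconsistent display geometry or out-of-domain angles."""


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical layout of the LED display, sample stage and camera.

    Parameters
    ----------
    leds_per_side
        Number of individually controllable LEDs along one display edge.
    pixel_pitch_mm
        Centre-to-centre LED spacing in millimetres.
    source_sample_distance_mm
        Distance H between the display plane and the sample.
    sample_camera_distance_mm
        Distance L between the sample and the camera objective.
    kernel_size
        Side length n of the square of simultaneously lit LEDs.
    kernels_per_side
        Number m of kernel positions per display axis; one camera image is
        taken per position, so a measurement yields an m x m image series.
    object_pixel_size_um
        Object-space size of one camera pixel, micrometres.
    """

    leds_per_side: int = 256
    pixel_pitch_mm: float = 1.8
    source_sample_distance_mm: float = 130.0
    sample_camera_distance_mm: float = 400.0
    kernel_size: int = 1
    kernels_per_side: int = 64
    object_pixel_size_um: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "pixel_pitch_mm",
            "source_sample_distance_mm",
            "sample_camera_distance_mm",
            "object_pixel_size_um",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.leds_per_side < 1 or self.kernel_size < 1 or self.kernels_per_side < 1:
            raise GeometryError("counts must be >= 1")
        if self.kernel_size * self.kernels_per_side > self.leds_per_side:
            raise GeometryError(
                "kernel_size * kernels_per_side exceeds the display width"
            )

    @property
    def kernel_pitch_mm(self) -> float:
        """Width of one kernel step on the display (n LED pitches)."""
        return self.kernel_size * self.pixel_pitch_mm

    @property
    def display_halfwidth_mm(self) -> float:
        return self.leds_per_side * self.pixel_pitch_mm / 2.0


@dataclass(frozen=True)
class IlluminationAngle:
    """Direction of illumination: polar angle and azimuth in degrees."""

    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 90.0:
            raise GeometryError(f"theta must lie in [0, 90), got {self.theta}")
        object.__setattr__(self, "phi", float(self.phi) % 360.0)


def max_illumination_angle(geom: DisplayGeometry) -> float:
    """Largest polar illumination angle the display can realize, degrees.

    A kernel at the display edge sits half a display width from the centre,
    so the maximum angle is ``arctan(half display width / H)``.
    """
    return float(
        np.degrees(
            np.arctan(geom.display_halfwidth_mm / geom.source_sample_distance_mm)
        )
    )


def kernel_illumination_angle(
    geom: DisplayGeometry,
    kernel_offset_x: float,
    kernel_offset_y: float,
    pixel_offset_mm: tuple[float, float] = (0.0, 0.0),
) -> IlluminationAngle:
    """Illumination angle of a kernel as seen from a point in the sample.

    Parameters
    ----------
    kernel_offset_x, kernel_offset_y
        Kernel-centre offset from the display centre in units of the kernel
        width (``n`` LED pitches).  For even ``n`` physical kernel centres
        sit at half-integer offsets (a square of n x n LEDs is centred
        between LEDs); any real offset is accepted.
        ``x`` increases to the right, ``y`` towards the top of the display.
    pixel_offset_mm
        In-plane ``(x, y)`` offset, millimetres, of the sample point directly
        above the display centre.

    Returns
    -------
    IlluminationAngle
        ``theta = arctan(d / H)`` with ``d`` the in-plane distance between
        kernel centre and the point beneath the pixel; ``phi`` the planar
        direction from the sample point towards the kernel (0 = top,
        clockwise).
    """
    kp = geom.kernel_pitch_mm
    dx = kernel_offset_x * kp - pixel_offset_mm[0]
    dy = kernel_offset_y * kp - pixel_offset_mm[1]
    dist = float(np.hypot(dx, dy))
    theta = float(np.degrees(np.arctan(dist / geom.source_sample_distance_mm)))
    phi = float(np.degrees(np.arctan2(dx, dy))) % 360.0
    return IlluminationAngle(theta=theta, phi=phi)


def theta_ring_radius(theta: float, scale: float = 1.0) -> float:
    """Radial distance of the constant-``theta`` ring in a gnomonic pattern.

    Scattering patterns show the distribution of scattered light on a plane,
    so equal-``theta`` rings sit at ``scale * tan(theta)``: the spacing of the
    10-degree rings grows with increasing ``theta``.
    """
    if not 0.0 <= theta < 90.0:
        raise GeometryError(f"theta must lie in [0, 90), got {theta}")
    return float(scale * np.tan(np.radians(theta)))


def scan_positions(count: int) -> np.ndarray:
    """Kernel-centre offsets of a centred scan, in kernel widths.

    ``count`` positions symmetric about the display centre: for an even count
    the offsets are half-integers (e.g. 32 positions span -15.5 .. 15.5).
    """
    return np.arange(count, dtype=float) - (count - 1) / 2.0


def calibration_curve(series, geom: DisplayGeometry, roi: int = 1000) -> np.ndarray:
    """Mean transmitted intensity of a diffusor versus illumination angle.

    The diffusor scan moves the kernel along the display centre-line; for
    each position the mean of the central ``roi x roi`` image pixels is
    paired with the signed polar angle ``theta = arctan(x * n * pitch / H)``
    (negative left of the display centre).

    Parameters
    ----------
    series : ImageSeries
        A 1-D scan (single row of kernel positions), or a full m x m series
        from which the middle grid row is taken as the centre-line.
    geom
        Display geometry providing kernel pitch and source-sample distance.
    roi
        Side length of the centred square region to average over.

    Returns
    -------
    ndarray, shape (positions, 2)
        Columns ``(theta_deg, mean_intensity)``, ordered by scan position.
    """
    images = series.images
    if images.ndim != 4:
        raise ValueError("series.images must have shape (rows, cols, H, W)")
    grid_rows, grid_cols, height, width = images.shape
    if roi > height or roi > width:
        raise ValueError(
            f"ROI {roi} exceeds image size {height}x{width}"
        )
    row = grid_rows // 2  # centre-line of the scan
    r0 = (height - roi) // 2
    c0 = (width - roi) // 2
    offsets = scan_positions(grid_cols)
    theta = np.degrees(
        np.arctan(offsets * geom.kernel_pitch_mm / geom.source_sample_distance_mm)
    )
    means = images[row, :, r0 : r0 + roi, c0 : c0 + roi].mean(axis=(1, 2))
    return np.column_stack([theta, means])


def write_calibration_csv(path, curve: np.ndarray) -> None:
    """Write a calibration curve as a two-column CSV (theta_deg, intensity)."""
    np.savetxt(
        path,
        curve,
        delimiter=",",
        header="theta_deg,mean_intensity",
        comments="",
    )
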