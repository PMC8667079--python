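"""Fiber orientation maps and orientation distribution maps.

Directions in ``[0, 180)`` are colour-coded on the HSV hue wheel with
``hue = 2 * angle`` so that 0 and 180 degrees coincide — the only injective
periodic choice; saturation and value stay at maximum.  The orientation map
expands every image pixel into 2x2 subpixels holding up to four direction
colours; the distribution map overlays low-alpha unit vectors per block of
pixels so dominant orientations emerge while lone deviating vectors remain
faintly visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb


def direction_to_rgb(angles) -> np.ndarray:
    """RGB colour(s) in [0, 1] for direction angle(s) in degrees.

    ``color(angle) == color(angle + 180)``; NaN maps to black.
    """
    angles = np.asarray(angles, dtype=float)
    hue = (2.0 * angles % 360.0) / 360.0
    hsv = np.stack(
        [np.nan_to_num(hue), np.ones_like(hue), np.ones_like(hue)], axis=-1
    )
    rgb = hsv_to_rgb(hsv)
    rgb[np.isnan(angles)] = 0.0
    return rgb


def orientation_map(directions: np.ndarray) -> np.ndarray:
    """Hue-coded direction image with 2x2 subpixels per image pixel.

    ``directions`` is ``(H, W, 4)`` with NaN for undefined slots (angles
    ascending).  Subpixel fill per pixel: one direction fills all four
    subpixels; two directions split main diagonal vs anti-diagonal; three
    duplicate the first direction in the fourth subpixel; four get one each,
    row-major in ascending angle.  Pixels without any direction are black.
    Output shape is exactly ``(2H, 2W, 3)``, float RGB in [0, 1].
    """
    h, w, _ = directions.shape
    out = np.zeros((2 * h, 2 * w, 3))
    for row in range(h):
        for col in range(w):
            angles = directions[row, col]
            angles = np.sort(angles[~np.isnan(angles)])
            colors = direction_to_rgb(angles)
            n = len(angles)
            if n == 0:
                continue
            if n == 1:
                block = [colors[0]] * 4
            elif n == 2:
                block = [colors[0], colors[1], colors[1], colors[0]]
            elif n == 3:
                block = [colors[0], colors[1], colors[2], colors[0]]
            else:
                block = [colors[0], colors[1], colors[2], colors[3]]
            out[2 * row, 2 * col] = block[0]
            out[2 * row, 2 * col + 1] = block[1]
            out[2 * row + 1, 2 * col] = block[2]
            out[2 * row + 1, 2 * col + 1] = block[3]
    return out


@dataclass
class Segment:
    """One drawable unit vector: endpoints in (x, y) image coordinates."""

    x0: float
    y0: float
    x1: float
    y1: float
    rgb: tuple[float, float, float]
    alpha: float


def distribution_map(
    directions: np.ndarray,
    block: int = 40,
    alpha: float = 0.1,
    min_defined_fraction: float = 0.08,
    segment_scale: float = 0.9,
) -> list[Segment]:
    """Block-wise overlay of per-pixel direction vectors.

    For every ``block x block`` region whose fraction of pixels with at
    least one defined direction reaches ``min_defined_fraction``
    (inclusive), one segment per direction per pixel is emitted, centred on
    the block centre, length ``segment_scale * block`` display units so
    neighbouring blocks do not overlap, coloured by direction hue with the
    given alpha.  Blocks below the coverage threshold emit nothing.
    """
    if block < 1:
        raise ValueError("block size must be >= 1")
    h, w, _ = directions.shape
    segments: list[Segment] = []
    half = segment_scale * block / 2.0
    for top in range(0, h, block):
        for left in range(0, w, block):
            tile = directions[top : top + block, left : left + block]
            defined = ~np.isnan(tile).all(axis=-1)
            if defined.mean() < min_defined_fraction:
                continue
            cy = top + (tile.shape[0] - 1) / 2.0
            cx = left + (tile.shape[1] - 1) / 2.0
            angles = tile[~np.isnan(tile)]
            for angle in angles:
                # angle 0 points up; clockwise positive in display coords
                dx = float(np.sin(np.radians(angle))) * half
                dy = -float(np.cos(np.radians(angle))) * half
                rgb = tuple(direction_to_rgb(angle))
                segments.append(
                    Segment(cx - dx, cy - dy, cx + dx, cy + dy, rgb, alpha)
                )
    return segments


def plot_distribution_map(
    segments: list[Segment],
    image_shape: tuple[int, int],
    png_path=None,
    svg_path=None,
    background: str = "black",
):
    """Render segments with matplotlib; optionally save PNG and/or SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    h, w = image_shape
    fig, ax = plt.subplots(figsize=(max(2, w / 50), max(2, h / 50)))
    ax.set_facecolor(background)
    if segments:
        lines = [[(s.x0, s.y0), (s.x1, s.y1)] for s in segments]
        colors = [(*s.rgb, s.alpha) for s in segments]
        ax.add_collection(LineCollection(lines, colors=colors, linewidths=1.0))
    ax.set_xlim(-0.5, w - 0.5)
    ax.set_ylim(h - 0.5, -0.5)  # image convention: y down
    ax.set_aspect("equal")
    ax.axis("off")
    for path in (png_path, svg_path):
        if path is not None:
            fig.savefig(path, dpi=150, facecolor=background, bbox_inches="tight")
    plt.close(fig)


def save_orientation_map_png(directions: np.ndarray, path) -> None:
    """Write the 2Hx2W orientation map as an 8-bit PNG."""
    from PIL import Image

    rgb = (orientation_map(directions) * 255).round().astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(path)


def save_color_wheel(path, size: int = 200) -> None:
    """Legend: direction angle -> hue wheel (0 at top, clockwise)."""
    yy, xx = np.mgrid[0:size, 0:size] - (size - 1) / 2.0
    radius = np.hypot(xx, yy)
    angle = np.degrees(np.arctan2(xx, -yy)) % 180.0
    rgb = direction_to_rgb(angle)
    rgb[(radius > size / 2) | (radius < size / 5)] = 0.0
    from PIL import Image

    Image.fromarray((rgb * 255).round().astype(np.uint8), mode="RGB").save(path)
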