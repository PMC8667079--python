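"""From profile peaks to in-plane nerve-fiber directions.

In-plane fibers scatter light into a reflex band perpendicular to their
orientation, so an azimuthal profile shows a peak pair roughly 180 degrees
apart per fiber bundle.  Peak positions are refined below the sampling step
by the centroid of the peak tip, peaks are matched into pairs with a
circular separation of 180 +/- 35 degrees, and each pair's axis — rotated by
90 degrees — gives one fiber direction in ``[0, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .assembly import ScatteringPattern
from .profiles import SLIProfile, azimuthal_profile, center_pattern
from .smoothing import PRESETS, FilterParams, circular_peaks, lowpass

PAIRING_TOLERANCE_DEG = 35.0


@dataclass
class PeakSet:
    """Significant profile peaks: positions in degrees plus prominences."""

    positions: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.prominences = self.prominences[order]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class FiberDirections:
    """Up to four in-plane direction angles for one image pixel.

    ``validity`` is ``"valid"`` when at least one direction was derived,
    ``"none"`` when no peak pair was found, ``"too_many_peaks"`` when more
    than four directions emerged (the 2x2-subpixel display limit), and
    ``"invalid"`` when a processing stage failed for this pixel.
    """

    angles: np.ndarray = field(default_factory=lambda: np.array([]))
    validity: str = "none"

    def __post_init__(self) -> None:
        self.angles = np.sort(np.asarray(self.angles, dtype=float) % 180.0)

    def __len__(self) -> int:
        return len(self.angles)


def find_significant_peaks(
    profile: SLIProfile, prominence_threshold: float = 0.08
) -> PeakSet:
    """Detect significant circular peaks; positions are bin angles."""
    idx, prom = circular_peaks(profile.values, prominence_threshold)
    return PeakSet(positions=idx * profile.delta_phi, prominences=prom)


def refine_peak(
    profile: SLIProfile,
    peak_index: int,
    tip_fraction: float = 0.06,
    prominence: float | None = None,
) -> float:
    """Sub-bin peak position from the centroid of the peak tip, degrees.

    The contiguous run of samples around the peak whose (normalised) height
    stays within ``tip_fraction * prominence`` of the peak height is reduced
    to a circular centroid weighted by the height above that cut line (so
    edge samples enter smoothly), improving on the angular sampling step.
    """
    values = profile.normalized()
    n = len(values)
    peak_index = int(peak_index) % n
    if prominence is None:
        idx, prom = circular_peaks(profile.values, prominence=0.0)
        matches = np.nonzero(idx == peak_index)[0]
        prominence = float(prom[matches[0]]) if len(matches) else float(
            np.ptp(values)
        )
    threshold = values[peak_index] - tip_fraction * prominence
    left = 0
    while left < n // 2 - 1 and values[(peak_index - (left + 1)) % n] >= threshold:
        left += 1
    right = 0
    while right < n // 2 - 1 and values[(peak_index + (right + 1)) % n] >= threshold:
        right += 1
    offsets = np.arange(-left, right + 1)
    weights = values[(peak_index + offsets) % n] - threshold
    if weights.sum() == 0:
        return (peak_index * profile.delta_phi) % 360.0
    centroid = peak_index + float((weights * offsets).sum() / weights.sum())
    return (centroid * profile.delta_phi) % 360.0


def circular_separation(a: float, b: float) -> float:
    """Shortest circular distance between two azimuths, degrees in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def pair_peaks(
    positions_deg,
    tolerance: float = PAIRING_TOLERANCE_DEG,
) -> tuple[list[tuple[float, float]], list[float]]:
    """Match peaks into pairs with circular separation 180 +/- tolerance.

    Among all matchings the one with the largest number of valid pairs is
    chosen; ties are resolved by the smallest total deviation from 180
    degrees.  Implemented as a maximum-cardinality, maximum-weight matching
    with edge weight ``C - |separation - 180|``.  Returns ``(pairs,
    unpaired)``; each peak joins at most one pair.
    """
    positions = sorted(float(p) % 360.0 for p in np.atleast_1d(positions_deg))
    graph = nx.Graph()
    graph.add_nodes_from(range(len(positions)))
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            deviation = abs(circular_separation(positions[i], positions[j]) - 180.0)
            if deviation <= tolerance:
                graph.add_edge(i, j, weight=1000.0 - deviation)
    matching = nx.max_weight_matching(graph, maxcardinality=True)
    paired_idx = set()
    pairs = []
    for i, j in matching:
        i, j = min(i, j), max(i, j)
        pairs.append((positions[i], positions[j]))
        paired_idx.update((i, j))
    pairs.sort()
    unpaired = [positions[k] for k in range(len(positions)) if k not in paired_idx]
    return pairs, unpaired


def _axis_mean(phi1: float, phi2: float) -> float:
    """Mean axis of two azimuths modulo 180, via doubled-angle vectors."""
    a1, a2 = np.radians([2 * (phi1 % 180.0), 2 * (phi2 % 180.0)])
    mean = np.arctan2(np.sin(a1) + np.sin(a2), np.cos(a1) + np.cos(a2))
    return float(np.degrees(mean) / 2.0) % 180.0


def directions_from_pairs(
    pairs,
    reflex_rotation: float = 90.0,
    merge_tolerance: float = 0.5,
) -> FiberDirections:
    """Convert peak pairs into fiber directions.

    The axis of a pair ``(phi1, phi2)`` is their circular mean modulo 180;
    the fiber direction is that axis rotated by ``reflex_rotation`` (90
    degrees by default: reflexes are perpendicular to in-plane fibers; the
    switch exists for tooling that already applies the rotation upstream).
    Near-duplicate directions within ``merge_tolerance`` degrees are merged;
    more than four surviving directions invalidate the pixel.
    """
    angles: list[float] = []
    for phi1, phi2 in pairs:
        direction = (_axis_mean(phi1, phi2) + reflex_rotation) % 180.0
        if not any(
            min(abs(direction - a), 180.0 - abs(direction - a)) <= merge_tolerance
            for a in angles
        ):
            angles.append(direction)
    if len(angles) > 4:
        return FiberDirections(angles=[], validity="too_many_peaks")
    if not angles:
        return FiberDirections(angles=[], validity="none")
    return FiberDirections(angles=angles, validity="valid")


def analyze_pixel(
    pattern: ScatteringPattern,
    delta_phi: float = 1.0,
    filter_params: FilterParams | None = PRESETS["sli-1deg"],
    prominence_threshold: float = 0.08,
    tip_fraction: float = 0.06,
    pairing_tolerance: float = PAIRING_TOLERANCE_DEG,
    reflex_rotation: float = 90.0,
    min_radius: int = 2,
    min_contrast: float = 0.05,
) -> FiberDirections:
    """Full per-pixel chain: centre, profile, smooth, peaks, pair, rotate.

    Stage failures (e.g. a border pixel whose crop circle is too small) are
    reported as ``validity="invalid"`` rather than raised, so a whole-map
    analysis never aborts on single pixels.  Profiles whose azimuthal
    modulation ``(max - min) / max`` stays below ``min_contrast`` are treated
    as isotropic (no reflex): min-max normalisation would otherwise amplify
    sub-percent ripple into spurious "significant" peaks.
    """
    try:
        center_pattern(pattern)
        if int(np.floor(pattern.crop_radius)) < max(1, min_radius):
            return FiberDirections(angles=[], validity="invalid")
        profile = azimuthal_profile(pattern, delta_phi)
        if profile.values.max() <= 0 or (
            np.ptp(profile.values) / profile.values.max() < min_contrast
        ):
            return FiberDirections(angles=[], validity="none")
        if filter_params is not None:
            profile = lowpass(profile, filter_params)
        peaks = find_significant_peaks(profile, prominence_threshold)
        refined = [
            refine_peak(profile, round(pos / delta_phi), tip_fraction, prom)
            for pos, prom in zip(peaks.positions, peaks.prominences)
        ]
        pairs, _ = pair_peaks(refined, tolerance=pairing_tolerance)
        return directions_from_pairs(
            pairs,
            reflex_rotation=reflex_rotation,
            merge_tolerance=max(delta_phi / 2.0, 0.5),
        )
    except (ValueError, ArithmeticError):
        return FiberDirections(angles=[], validity="invalid")


def analyze_cube(cube, **kwargs) -> np.ndarray:
    """Direction map of a pattern cube: float32 array (H, W, 4), NaN-padded."""
    h, w = cube.image_shape
    out = np.full((h, w, 4), np.nan, dtype=np.float32)
    for row in range(h):
        for col in range(w):
            result = analyze_pixel(cube.pattern(row, col), **kwargs)
            for k, angle in enumerate(result.angles[:4]):
                out[row, col, k] = angle
    return out


def write_directions_csv(path, directions: np.ndarray) -> None:
    """CSV summary of a direction map: y, x, n_directions, angles."""
    h, w, _ = directions.shape
    with open(path, "w") as handle:
        handle.write("y,x,n_directions,dir1,dir2,dir3,dir4\n")
        for row in range(h):
            for col in range(w):
                angles = directions[row, col]
                n = int(np.sum(~np.isnan(angles)))
                rendered = ",".join(
                    "" if np.isnan(a) else f"{a:.2f}" for a in angles
                )
                handle.write(f"{row},{col},{n},{rendered}\n")
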