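"""Fourier low-pass smoothing of azimuthal profiles and filter optimisation.

Finely sampled profiles (e.g. 1-degree azimuthal steps) carry high-frequency
components that reflect sub-resolution detail of the underlying fibers and
measurement noise; peak counting works on smoothed curves.  The filter
multiplies each Fourier coefficient at normalised frequency
``g = |f| / f_max`` (``f_max`` = Nyquist frequency of the sampled profile) by

    M(g) = 1 - [0.5 + 0.5 * tanh((g - cutoff) / width)]

i.e. a soft low-pass whose *cutoff frequency* sets the fraction of passing
frequencies and whose *window width* sets the sharpness of the roll-off.

The filter parameters are selected by a grid search over regions of known
fiber constellation: for each parameter pair the *detection rate* — the
fraction of profiles whose significant-peak count matches the constellation's
expected count (with even counts additionally required to pair at
180 +/- 35 degrees) — is computed per region; the per-region rate matrices
are normalised by their maximum and summed so every constellation weighs
equally, and the argmax of the summed matrix is the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .profiles import SLIProfile


class SmoothingError(ValueError):
    """Raised for invalid filter parameters or degenerate optimisation input."""


@dataclass(frozen=True)
class FilterParams:
    """Low-pass parameters: cutoff in (0, 1], window width in (0, 0.25]."""

    cutoff: float
    width: float

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff <= 1.0:
            raise SmoothingError(f"cutoff must lie in (0, 1], got {self.cutoff}")
        if self.width == 0:
            raise SmoothingError(
                "window width 0 is undefined; request a step filter explicitly "
                "via a tiny width (e.g. 1e-6)"
            )
        if not 0.0 < self.width <= 0.25:
            raise SmoothingError(f"width must lie in (0, 0.25], got {self.width}")


#: Optimised presets: 1-degree profiles use cutoff 4% / width 0.125,
#: 5-degree profiles cutoff 40% / width 0.225.
PRESETS: dict[str, FilterParams] = {
    "sli-1deg": FilterParams(cutoff=0.04, width=0.125),
    "sli-5deg": FilterParams(cutoff=0.40, width=0.225),
}


def filter_gain(g, params: FilterParams):
    """Closed-form filter gain ``M(g)`` at normalised frequency ``g``."""
    g = np.abs(np.asarray(g, dtype=float))
    return 1.0 - (0.5 + 0.5 * np.tanh((g - params.cutoff) / params.width))


def lowpass_values(values: np.ndarray, params: FilterParams) -> np.ndarray:
    """Apply the tanh low-pass to periodic profile values (last axis)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if n < 4:
        raise SmoothingError("profile too short to filter")
    f_max = n / 2.0  # Nyquist, cycles per turn
    g = np.arange(n // 2 + 1) / f_max
    spectrum = np.fft.rfft(values, axis=-1)
    spectrum = spectrum * filter_gain(g, params)
    return np.fft.irfft(spectrum, n=n, axis=-1)


def lowpass(profile: SLIProfile, params: FilterParams) -> SLIProfile:
    """Smoothed copy of a profile; length, step and metadata unchanged.

    The multiplier is real and even, so the filter is zero-phase; it is
    applied literally to all coefficients including the mean (``f = 0``),
    whose mild attenuation ``M(0) < 1`` is harmless because peak analysis
    works on min-max-normalised profiles.
    """
    return SLIProfile(
        values=lowpass_values(profile.values, params),
        delta_phi=profile.delta_phi,
        radius_px=profile.radius_px,
        source=dict(profile.source),
    )


def _normalize(values: np.ndarray) -> np.ndarray:
    lo = values.min()
    span = values.max() - lo
    if span == 0:
        return np.zeros_like(values)
    return (values - lo) / span


def circular_peaks(
    values: np.ndarray, prominence: float = 0.08
) -> tuple[np.ndarray, np.ndarray]:
    """Circular local maxima with prominence above threshold.

    The profile is min-max normalised, tiled three times so that prominences
    are evaluated with full wrap-around context, and peaks are taken from the
    middle period.  Plateaus count once, at their midpoint.  Returns
    ``(indices, prominences)`` with indices in ``[0, len(values))``.
    """
    norm = _normalize(np.asarray(values, dtype=float))
    n = len(norm)
    if np.ptp(norm) == 0:
        return np.array([], dtype=int), np.array([])
    tiled = np.concatenate([norm, norm, norm])
    idx, props = find_peaks(tiled, prominence=prominence)
    keep = (idx >= n) & (idx < 2 * n)
    return idx[keep] - n, props["prominences"][keep]


def count_significant_peaks(
    profile: SLIProfile | np.ndarray, prominence_threshold: float = 0.08
) -> int:
    """Number of significant peaks of a (normalised) circular profile."""
    values = profile.values if isinstance(profile, SLIProfile) else profile
    return len(circular_peaks(values, prominence_threshold)[0])


def _peaks_pairable(positions_deg: np.ndarray, tolerance: float = 35.0) -> bool:
    """True if every peak joins a partner at circular distance 180 +/- tol."""
    from .orientation import pair_peaks  # local import: avoids module cycle

    pairs, unpaired = pair_peaks(positions_deg, tolerance=tolerance)
    return len(unpaired) == 0


def detection_rate(
    profiles: Sequence[SLIProfile],
    accepted_counts: Iterable[int],
    params: FilterParams | None = None,
    prominence_threshold: float = 0.08,
    pairing_tolerance: float = 35.0,
) -> float:
    """Fraction of profiles whose peak count matches the fiber constellation.

    Each profile is smoothed with ``params`` (``None`` = unsmoothed), its
    significant peaks counted, and counted as detected when (a) the count is
    in ``accepted_counts`` and (b) for even counts all peaks pair up at
    180 +/- ``pairing_tolerance`` degrees — the peak-distance check that
    guards against false positives.
    """
    accepted = set(int(c) for c in accepted_counts)
    if not accepted:
        raise SmoothingError("accepted_counts must not be empty")
    if not profiles:
        raise SmoothingError("need at least one profile")
    stack = np.stack([p.values for p in profiles])
    if params is not None:
        stack = lowpass_values(stack, params)
    delta_phi = profiles[0].delta_phi
    hits = 0
    for row in stack:
        idx, _ = circular_peaks(row, prominence_threshold)
        count = len(idx)
        if count not in accepted:
            continue
        if count % 2 == 0 and count > 0:
            if not _peaks_pairable(idx * delta_phi, pairing_tolerance):
                continue
        hits += 1
    return hits / len(stack)


@dataclass
class DetectionGrid:
    """Detection-rate matrices of the filter grid search.

    ``rates[region]`` has shape ``(len(cutoffs), len(widths))`` with entries
    in ``[0, 1]``.
    """

    cutoffs: np.ndarray
    widths: np.ndarray
    rates: dict[str, np.ndarray] = field(default_factory=dict)

    def summed_normalized(self) -> np.ndarray:
        """Sum of per-region matrices, each divided by its maximum."""
        total = np.zeros((len(self.cutoffs), len(self.widths)))
        for region, matrix in self.rates.items():
            peak = matrix.max()
            if peak == 0:
                warnings.warn(
                    f"region {region!r}: all detection rates zero; excluded "
                    "from the parameter selection"
                )
                continue
            total += matrix / peak
        return total

    def write_csv(self, path) -> None:
        """Long-format CSV (region, cutoff, width, rate) for heatmaps."""
        with open(path, "w") as handle:
            handle.write("region,cutoff,width,rate\n")
            for region, matrix in self.rates.items():
                for i, cutoff in enumerate(self.cutoffs):
                    for j, width in enumerate(self.widths):
                        handle.write(
                            f"{region},{cutoff:g},{width:g},{matrix[i, j]:.6g}\n"
                        )


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """Standard search grid: cutoffs 2%..100% in 2% steps, widths
    0.025..0.25 in 0.025 steps (width 0 is excluded: the filter is undefined
    there)."""
    cutoffs = np.round(np.arange(0.02, 1.0 + 1e-9, 0.02), 10)
    widths = np.round(np.arange(0.025, 0.25 + 1e-9, 0.025), 10)
    return cutoffs, widths


def optimize_filter(
    fixtures: Mapping[str, tuple[Sequence[SLIProfile], Iterable[int]]],
    cutoffs: np.ndarray | None = None,
    widths: np.ndarray | None = None,
    prominence_threshold: float = 0.08,
) -> tuple[FilterParams, DetectionGrid]:
    """Grid-search the filter parameters over known-constellation regions.

    ``fixtures`` maps region name to ``(profiles, accepted_counts)``.  The
    argmax of the summed normalised rate matrices is returned; ties break to
    the lowest cutoff, then the lowest width.
    """
    if not fixtures:
        raise SmoothingError("need at least one region")
    if cutoffs is None or widths is None:
        default_c, default_w = default_grid()
        cutoffs = default_c if cutoffs is None else np.asarray(cutoffs, float)
        widths = default_w if widths is None else np.asarray(widths, float)
    grid = DetectionGrid(cutoffs=np.asarray(cutoffs), widths=np.asarray(widths))
    for region, (profiles, accepted) in fixtures.items():
        matrix = np.zeros((len(cutoffs), len(widths)))
        for i, cutoff in enumerate(cutoffs):
            for j, width in enumerate(widths):
                matrix[i, j] = detection_rate(
                    profiles,
                    accepted,
                    FilterParams(cutoff=float(cutoff), width=float(width)),
                    prominence_threshold,
                )
        grid.rates[region] = matrix
    total = grid.summed_normalized()
    if total.max() == 0:
        raise SmoothingError("all regions have all-zero detection rates")
    # np.argmax on the (cutoff, width) row-major array realises the tie-break:
    # first maximum encountered has the lowest cutoff, then the lowest width.
    best = np.unravel_index(int(np.argmax(total)), total.shape)
    params = FilterParams(
        cutoff=float(cutoffs[best[0]]), width=float(widths[best[1]])
    )
    return params, grid
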