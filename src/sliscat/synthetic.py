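"""Forward simulation of scatterometry measurements of fiber phantoms.

The renderer produces scattering patterns with the qualitative features of
transmitted-light scattering by myelinated nerve fibers:

* an in-plane fiber bundle scatters into an elongated *reflex band* through
  the pattern centre, oriented perpendicular to the fiber direction, modelled
  as an anisotropic Gaussian band (Gaussian cross-section of ``reflex_width``
  pixels, smoothly truncated at ``reflex_halflength``);
* a fiber inclined out of the section plane displaces its reflex along the
  fiber direction and bends it into an arc, both effects growing with the
  inclination angle (encoded as a centroid shift ``s = k * tan(inclination)``
  plus parabolic bending);
* a bright, unscattered central blob whose position drifts linearly across
  the field of view (each image pixel sits above a slightly different display
  position);
* an intensity falloff ``cos^q(theta)`` with the illumination angle,
  emulating the 1/r^2 loss and the limited LED view angle seen in diffusor
  calibration measurements;
* camera gain and shot averaging with Poisson shot noise plus Gaussian read
  noise.

The model is deliberately phenomenological — controllable ground truth for
the analysis chain, not an electromagnetic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import ImageSeries, ScatteringPattern, SeriesMeta
from .geometry import DisplayGeometry


class SyntheticError(ValueError):
    """Raised for inconsistent phantom or renderer input."""


@dataclass(frozen=True)
class FiberBundle:
    """One fiber population within a pixel.

    direction : in-plane angle, degrees in [0, 180); 0 = fiber pointing to
        the top of the image, angles increase clockwise.
    inclination : out-of-plane angle, degrees in [0, 90].
    weight : relative scattering strength (>= 0).
    reflex_width : angular std-dev of the reflex band, pattern pixels.
    reflex_halflength : half-length of the band, pattern pixels.
    """

    direction: float
    inclination: float = 0.0
    weight: float = 1.0
    reflex_width: float = 3.0
    reflex_halflength: float = 18.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise SyntheticError("weight must be >= 0")
        if not 0.0 <= self.inclination <= 90.0:
            raise SyntheticError("inclination must lie in [0, 90]")
        object.__setattr__(self, "direction", float(self.direction) % 180.0)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise, Gaussian read noise, gain, averaging.

    Rendered intensities are scaled to expected photon counts by
    ``shot_scale * illumination_time``, Poisson-sampled per shot, read noise
    added, the ``n_shots`` frames averaged, and the camera gain applied to
    the average.  Deterministic given ``seed``.
    """

    shot_scale: float = 50.0
    read_sigma: float = 0.05
    gain: float = 1.0
    illumination_time: float = 1.0
    n_shots: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shots < 1:
            raise SyntheticError("n_shots must be >= 1")
        if self.shot_scale <= 0 or self.illumination_time <= 0:
            raise SyntheticError("shot_scale and illumination_time must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        photons = np.clip(intensity, 0, None) * self.shot_scale * self.illumination_time
        shots = rng.poisson(lam=photons[None].repeat(self.n_shots, axis=0)).astype(
            float
        )
        shots /= self.shot_scale * self.illumination_time
        shots += rng.normal(0.0, self.read_sigma, size=shots.shape)
        return np.clip(self.gain * shots.mean(axis=0), 0, None)


@dataclass
class Phantom:
    """Labelled fiber phantom standing in for a histological section.

    ``label_map`` is an ``H x W`` integer grid; ``constellations`` maps each
    label to its list of fiber bundles (an empty list is isotropic,
    gray-matter-like tissue).
    """

    label_map: np.ndarray
    constellations: dict[int, list[FiberBundle]]
    background_transmittance: float = 0.05
    center_amplitude: float = 2.0
    center_sigma: float = 1.5

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=int)
        missing = set(np.unique(self.label_map)) - set(self.constellations)
        if missing:
            raise SyntheticError(f"labels without constellation entry: {missing}")


# Inclination encoding: reflex centroid shift and curvature per tan(inclination).
INCLINATION_SHIFT_PX = 6.0
INCLINATION_CURVATURE = 0.02


def _direction_unit(angle_deg: float) -> tuple[float, float]:
    """(d_row, d_col) unit step for an azimuth (0 = up, clockwise)."""
    a = np.radians(angle_deg)
    return -float(np.cos(a)), float(np.sin(a))


def render_pattern(
    constellation: list[FiberBundle],
    size: int,
    center: tuple[float, float],
    geom: DisplayGeometry | None = None,
    vignetting_exponent: float = 4.0,
    background: float = 0.05,
    center_amplitude: float = 2.0,
    center_sigma: float = 1.5,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> ScatteringPattern:
    """Render one ``size x size`` scattering pattern.

    The pattern is the sum of the unscattered central blob, the reflex band
    of every bundle, and an isotropic background, multiplied by the
    ``cos^q(theta)`` illumination falloff (``theta`` computed per pattern
    pixel from ``geom``; no falloff if ``geom`` is None).  Noise is applied
    last if a model is given.
    """
    cr, cc = center
    if not (0 <= cr <= size - 1 and 0 <= cc <= size - 1):
        raise SyntheticError(f"center {center} outside {size}x{size} pattern")
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    d_row = rows - cr
    d_col = cols - cc

    total = np.full((size, size), float(background))
    total += center_amplitude * np.exp(
        -(d_row**2 + d_col**2) / (2.0 * center_sigma**2)
    )
    for bundle in constellation:
        total += _reflex_band(d_row, d_col, bundle)
    if geom is not None and vignetting_exponent != 0:
        dist_kernels = np.hypot(d_row, d_col)
        theta = np.arctan(
            dist_kernels * geom.kernel_pitch_mm / geom.source_sample_distance_mm
        )
        total *= np.cos(theta) ** vignetting_exponent
    if noise is not None:
        total = noise.apply(total, rng if rng is not None else noise.rng())
    return ScatteringPattern(values=total)


def _reflex_band(d_row: np.ndarray, d_col: np.ndarray, bundle: FiberBundle):
    """Intensity of one bundle's reflex band on the centred pixel grid."""
    axis = bundle.direction + 90.0  # reflex is perpendicular to the fiber
    e_axis = _direction_unit(axis)
    e_perp = _direction_unit(axis + 90.0)
    e_fiber = _direction_unit(bundle.direction)
    tan_incl = float(np.tan(np.radians(min(bundle.inclination, 89.0))))
    shift = INCLINATION_SHIFT_PX * tan_incl
    dr = d_row - shift * e_fiber[0]
    dc = d_col - shift * e_fiber[1]
    along = dr * e_axis[0] + dc * e_axis[1]
    across = dr * e_perp[0] + dc * e_perp[1]
    # inclined fibers: reflex bends into an arc opening along the fiber
    across = across - INCLINATION_CURVATURE * tan_incl * along**2
    profile_across = np.exp(-(across**2) / (2.0 * bundle.reflex_width**2))
    # smooth truncation of the band at +/- reflex_halflength
    envelope = np.exp(-0.5 * (along / bundle.reflex_halflength) ** 6)
    return bundle.weight * profile_across * envelope


def pattern_center_for_pixel(
    pixel: tuple[int, int],
    image_shape: tuple[int, int],
    geom: DisplayGeometry,
) -> tuple[float, float]:
    """Pattern centre for an image pixel: drifts linearly across the field.

    The unscattered beam lands at the display position directly beneath the
    pixel, so the centre moves by one kernel per ``n * pitch`` of in-plane
    object distance away from the field centre.
    """
    m = geom.kernels_per_side
    h, w = image_shape
    px_mm = geom.object_pixel_size_um / 1000.0
    base = (m - 1) / 2.0
    d_row = (pixel[0] - (h - 1) / 2.0) * px_mm / geom.kernel_pitch_mm
    d_col = (pixel[1] - (w - 1) / 2.0) * px_mm / geom.kernel_pitch_mm
    return base + d_row, base + d_col


def render_stack(
    phantom: Phantom,
    geom: DisplayGeometry,
    noise: NoiseModel | None = None,
    vignetting_exponent: float = 4.0,
) -> ImageSeries:
    """Forward-simulate the full image series of a phantom.

    Image ``(i, j)`` of the series holds, at pixel ``p``, the value of
    ``render_pattern(constellation at p, center_p)[i, j]`` — the exact
    inverse of pattern assembly, so ``assemble(render_stack(...))``
    reproduces every pattern bit-exactly when noise is off.
    """
    m = geom.kernels_per_side
    h, w = phantom.label_map.shape
    images = np.empty((m, m, h, w), dtype=np.float32)
    rng = noise.rng() if noise is not None else None
    for row in range(h):
        for col in range(w):
            label = int(phantom.label_map[row, col])
            pattern = render_pattern(
                phantom.constellations[label],
                size=m,
                center=pattern_center_for_pixel((row, col), (h, w), geom),
                geom=geom,
                vignetting_exponent=vignetting_exponent,
                background=phantom.background_transmittance,
                center_amplitude=phantom.center_amplitude,
                center_sigma=phantom.center_sigma,
                noise=noise,
                rng=rng,
            )
            images[:, :, row, col] = pattern.values
    meta = SeriesMeta(
        kernel_size=geom.kernel_size,
        kernels_per_side=m,
        shots=noise.n_shots if noise is not None else 1,
        illumination_time_s=noise.illumination_time if noise is not None else 1.0,
        gain=noise.gain if noise is not None else 1.0,
    )
    return ImageSeries(images=images, meta=meta)


# ---------------------------------------------------------------------------
# Randomised fixtures for filter optimisation and recovery studies

REGION_KINDS = ("parallel_inplane", "outofplane", "crossing2", "crossing3")

#: Expected significant-peak counts per fiber constellation: two peaks per
#: in-plane bundle; a strongly inclined bundle may merge its pair into one.
EXPECTED_COUNTS = {
    "parallel_inplane": {2},
    "outofplane": {1, 2},
    "crossing2": {4},
    "crossing3": {6},
}


def random_constellation(
    kind: str, rng: np.random.Generator, pattern_size: int = 49
) -> list[FiberBundle]:
    """Draw a randomised bundle constellation of the requested kind.

    Directions are jittered, weights and reflex widths varied; reflex sizes
    scale with the pattern so peaks stay resolvable at 1-degree steps.
    """
    if kind not in REGION_KINDS:
        raise SyntheticError(f"unknown region kind {kind!r}")
    radius = (pattern_size - 1) / 2.0

    def bundle(direction: float, inclination: float = 0.0) -> FiberBundle:
        return FiberBundle(
            direction=direction % 180.0,
            inclination=inclination,
            weight=float(rng.uniform(0.7, 1.3)),
            reflex_width=float(rng.uniform(0.10, 0.16)) * radius,
            reflex_halflength=float(rng.uniform(0.75, 0.95)) * radius,
        )

    base = float(rng.uniform(0.0, 180.0))
    if kind == "parallel_inplane":
        return [bundle(base)]
    if kind == "outofplane":
        return [bundle(base, inclination=float(rng.uniform(45.0, 70.0)))]
    if kind == "crossing2":
        delta = 90.0 + float(rng.uniform(-20.0, 20.0))
        return [bundle(base), bundle(base + delta)]
    deltas = 60.0 + rng.uniform(-8.0, 8.0, size=2)
    return [bundle(base), bundle(base + deltas[0]), bundle(base + deltas[0] + deltas[1])]


def pattern_fixture(
    kind: str,
    n_patterns: int,
    seed: int,
    pattern_size: int = 49,
    geom: DisplayGeometry | None = None,
    noise: NoiseModel | None = NoiseModel(),
    vignetting_exponent: float = 4.0,
) -> list[tuple[ScatteringPattern, list[FiberBundle]]]:
    """Render ``n_patterns`` randomised patterns of one constellation kind.

    Returns ``(pattern, ground-truth bundles)`` tuples; patterns are centred
    at the middle of the grid.  With ``noise=None`` the patterns are
    noiseless.
    """
    if n_patterns < 1:
        raise SyntheticError("n_patterns must be >= 1")
    if geom is None:
        geom = DisplayGeometry(kernel_size=4, kernels_per_side=pattern_size)
    rng = np.random.default_rng(seed)
    center = ((pattern_size - 1) / 2.0, (pattern_size - 1) / 2.0)
    out = []
    for _ in range(n_patterns):
        constellation = random_constellation(kind, rng, pattern_size)
        pattern = render_pattern(
            constellation,
            size=pattern_size,
            center=center,
            geom=geom,
            vignetting_exponent=vignetting_exponent,
            noise=noise,
            rng=rng,
        )
        out.append((pattern, constellation))
    return out


def region_fixture(
    kind: str,
    n_profiles: int,
    seed: int,
    delta_phi: float = 1.0,
    pattern_size: int = 49,
    noise: NoiseModel | None = NoiseModel(),
):
    """Randomised profile suite of one fiber-region kind.

    Returns ``(profiles, accepted_counts)``: ``n_profiles`` azimuthal
    profiles rendered from jittered bundles of the requested kind, and the
    set of significant-peak counts a correct detection must produce
    (parallel {2}, out-of-plane {1, 2}, two crossings {4}, three {6}).
    Deterministic given ``seed``.
    """
    from .profiles import azimuthal_profile, center_pattern

    fixtures = pattern_fixture(
        kind, n_profiles, seed, pattern_size=pattern_size, noise=noise
    )
    profiles = []
    for pattern, _ in fixtures:
        center_pattern(pattern)
        profiles.append(azimuthal_profile(pattern, delta_phi))
    return profiles, set(EXPECTED_COUNTS[kind])


def four_region_suite(
    n_profiles: int,
    seed: int,
    delta_phi: float = 1.0,
    pattern_size: int = 49,
    noise: NoiseModel | None = NoiseModel(),
):
    """Fixture suites for all four region kinds, keyed by kind."""
    return {
        kind: region_fixture(
            kind,
            n_profiles,
            seed + offset,
            delta_phi=delta_phi,
            pattern_size=pattern_size,
            noise=noise,
        )
        for offset, kind in enumerate(REGION_KINDS)
    }


def phantom_preset(
    name: str, shape: tuple[int, int] = (8, 8), margin: int = 1
) -> Phantom:
    """Small labelled phantom: isotropic margin around a fiber region."""
    if name == "diffusor":
        return Phantom(
            label_map=np.zeros(shape, dtype=int),
            constellations={0: []},
            background_transmittance=1.0,
            center_amplitude=0.0,
        )
    constellations = {
        "parallel": [FiberBundle(direction=30.0)],
        "outofplane": [FiberBundle(direction=30.0, inclination=55.0)],
        "crossing2": [FiberBundle(direction=0.0), FiberBundle(direction=90.0)],
        "crossing3": [
            FiberBundle(direction=30.0),
            FiberBundle(direction=90.0),
            FiberBundle(direction=150.0),
        ],
    }
    if name not in constellations:
        raise SyntheticError(f"unknown phantom preset {name!r}")
    label_map = np.zeros(shape, dtype=int)
    label_map[margin : shape[0] - margin, margin : shape[1] - margin] = 1
    return Phantom(
        label_map=label_map,
        constellations={0: [], 1: constellations[name]},
    )


def ground_truth_directions(phantom: Phantom) -> dict[int, list[float]]:
    """In-plane direction angles per label, for sidecar files and tests."""
    return {
        label: sorted(b.direction for b in bundles)
        for label, bundles in phantom.constellations.items()
    }
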