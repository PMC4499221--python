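"""Synthetic dental-arch scenes with known per-body ground truth.

A scene emulates an occlusal photograph of a plaster cast: fourteen convex,
partially overlapping tooth-like bodies (seven per side, mirrored about the
central vertical axis) sit on a flat base and are arranged along a parabolic
arch.  Each body is a flat-topped cap of a configurable height profile; the
scene is rendered under a directional light (Lambertian shading plus hard cast
shadows) so that a set of captures taken with different illumination azimuths
and elevations can feed the fusion/segmentation pipeline, while the per-body
support masks provide pixel-exact ground truth for evaluation.

Illumination geometry: the light direction is given by an azimuth ``phi``
measured in the image plane (0 deg = source to the left of the scene,
90 deg = above the top edge, 180 deg = to the right) and an elevation
``theta`` in (0, 90] deg above the base plane (90 deg = straight down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NoiseSpec",
    "SceneSpec",
    "Body",
    "IlluminatedCapture",
    "SceneTruth",
    "STANDARD_ILLUMINATION",
    "build_height_map",
    "render_capture",
    "render_standard_set",
    "cast_shadow_mask",
]

#: Tag, azimuth (deg) and elevation (deg) of the four standard captures:
#: two top lights at wide/narrow grazing angle and one light per side.
STANDARD_ILLUMINATION = (
    ("top_wide", 90.0, 75.0),
    ("top_narrow", 90.0, 50.0),
    ("left", 0.0, 35.0),
    ("right", 180.0, 35.0),
)

_AMBIENT = 0.15          # fraction of albedo reachable without direct light
_SHADOW_ATTENUATION = 0.35  # multiplicative darkening inside a cast shadow
_BODY_ALBEDO = 0.92      # reflectance of the bodies (plaster crown)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor-noise model applied after shading.

    ``gaussian_sd`` is the standard deviation of additive Gaussian read
    noise; ``poisson_scaling`` emulates shot noise as additive Gaussian
    noise whose variance is proportional to the local intensity; and
    ``speckle_var`` is the variance of multiplicative speckle.  Order of
    application: additive terms, then speckle, then clipping to [0, 1].
    """

    gaussian_sd: float = 0.02
    speckle_var: float = 0.02
    poisson_scaling: float = 0.01

    def validate(self) -> None:
        for name in ("gaussian_sd", "speckle_var", "poisson_scaling"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise parameter {name} must be >= 0")

    @property
    def is_zero(self) -> bool:
        return self.gaussian_sd == 0 and self.speckle_var == 0 and self.poisson_scaling == 0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic arch scene.

    ``body_radii`` gives the in-plane semi-axis (circular footprint radius,
    pixels) of bodies 1 (central incisor position) through
    ``n_bodies_per_side`` (most distal); the left and right sides are
    mirror images.  Consecutive bodies along the arch overlap by
    ``overlap_fraction`` of the smaller of their two radii.  The arch is the
    parabola ``row = arch_apex_row + arch_curvature * t**2`` with ``t`` the
    signed column offset from the central vertical axis.  ``body_height``
    and ``body_profile_power`` set the cap profile
    ``h(d) = body_height * (1 - (d / r) ** body_profile_power)``: a large
    power yields a flat occlusal surface with a steep rim, which is what
    gives the rendered rim its dark ring.  ``pixel_scale`` converts pixel
    distances to millimetres (default 0.6 mm/px, chosen so mirrored-pair
    distances of the default arch span roughly 15-200 mm at a 384x512
    image size).
    """

    image_shape: tuple[int, int] = (384, 512)
    n_bodies_per_side: int = 7
    arch_apex_row: float = 80.0
    arch_curvature: float = 0.005
    body_radii: tuple[float, ...] = (15.0, 16.0, 17.0, 18.0, 20.0, 22.0, 24.0)
    body_profile_power: float = 8.0
    overlap_fraction: float = 0.15
    base_level: float = 0.55
    body_height: float = 6.0
    pixel_scale: float = 0.6
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_bodies_per_side < 1:
            raise ValueError("n_bodies_per_side must be >= 1")
        if len(self.body_radii) != self.n_bodies_per_side:
            raise ValueError(
                "body_radii must list one radius per body "
                f"({self.n_bodies_per_side} expected, got {len(self.body_radii)})"
            )
        if any(r <= 0 for r in self.body_radii):
            raise ValueError("all body radii must be > 0")
        if not (0.0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must lie in [0, 0.5)")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        if not (0.0 <= self.base_level <= 1.0):
            raise ValueError("base_level must lie in [0, 1]")
        if self.body_height <= 0:
            raise ValueError("body_height must be > 0")
        if self.body_profile_power < 2:
            raise ValueError("body_profile_power must be >= 2")
        M, N = self.image_shape
        if M < 2 or N < 2:
            raise ValueError("image_shape must be at least 2x2")
        self.noise.validate()


@dataclass(frozen=True)
class Body:
    """One tooth-like body: arch side, position index and truth mask."""

    side: str               # "L" or "R"
    index: int              # 1 (central) .. n (most distal)
    center: tuple[float, float]  # (row, col) of the footprint centre
    radius: float
    mask: np.ndarray        # boolean support of the body's cap

    @property
    def label(self) -> str:
        return f"{self.index}{self.side}"


@dataclass(frozen=True)
class IlluminatedCapture:
    """A grey image together with the light direction it was taken under."""

    image: np.ndarray
    azimuth_deg: float
    elevation_deg: float
    tag: str = ""


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of a synthetic scene.

    Holds the height map the renderer shades, one :class:`Body` per tooth
    position (masks come from the height map's support only and are
    independent of illumination), the standard illumination parameters and
    the pixel scale.
    """

    height_map: np.ndarray
    bodies: tuple[Body, ...]
    illum_params: tuple[tuple[str, float, float], ...]
    pixel_scale: float
    spec: SceneSpec

    @property
    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.height_map.shape, dtype=bool)
        for b in self.bodies:
            out |= b.mask
        return out


def _arc_positions(spec: SceneSpec) -> np.ndarray:
    """Arc-length offsets of the body centres from the arch apex (one side)."""
    r = np.asarray(spec.body_radii, dtype=float)
    f = spec.overlap_fraction
    s = np.empty(spec.n_bodies_per_side)
    # bodies 1L and 1R face each other across the midline: their centre
    # separation along the arch is 2*s[0] = r0 + r0 - f*r0
    s[0] = r[0] * (2.0 - f) / 2.0
    for k in range(1, spec.n_bodies_per_side):
        s[k] = s[k - 1] + r[k - 1] + r[k] - f * min(r[k - 1], r[k])
    return s


def _arc_to_param(spec: SceneSpec, arc: np.ndarray) -> np.ndarray:
    """Invert the parabola arc length: arc-length offsets -> column offsets."""
    q = spec.arch_curvature
    t_grid = np.linspace(0.0, float(spec.image_shape[1]), 8 * spec.image_shape[1])
    ds = np.sqrt(1.0 + (2.0 * q * t_grid) ** 2)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(t_grid))))
    if arc.max() > cum[-1]:
        raise ValueError("arch is longer than the image can hold")
    return np.interp(arc, cum, t_grid)


def build_height_map(spec: SceneSpec) -> SceneTruth:
    """Lay the bodies out along the arch and build the scene height map.

    Bodies are mirrored left/right about the central column; consecutive
    bodies overlap by ``overlap_fraction`` of the smaller radius (measured
    along the arch).  Raises ``ValueError`` if any body would extend outside
    the image.
    """
    spec.validate()
    M, N = spec.image_shape
    c0 = (N - 1) / 2.0
    q = spec.arch_curvature
    t = _arc_to_param(spec, _arc_positions(spec))

    rows = np.arange(M, dtype=float)[:, None]
    cols = np.arange(N, dtype=float)[None, :]

    height = np.zeros((M, N))
    bodies: list[Body] = []
    p = spec.body_profile_power
    for side, sign in (("L", -1.0), ("R", 1.0)):
        for k in range(spec.n_bodies_per_side):
            r = float(spec.body_radii[k])
            cr = spec.arch_apex_row + q * t[k] ** 2
            cc = c0 + sign * t[k]
            if cr - r < 0 or cr + r > M - 1 or cc - r < 0 or cc + r > N - 1:
                raise ValueError(
                    f"body {k + 1}{side} (centre {cr:.1f},{cc:.1f}, radius {r}) "
                    "extends outside the image"
                )
            d2 = ((rows - cr) ** 2 + (cols - cc) ** 2) / r**2
            inside = d2 < 1.0
            hk = np.where(inside, spec.body_height * (1.0 - d2 ** (p / 2.0)), 0.0)
            height = np.maximum(height, hk)
            bodies.append(Body(side=side, index=k + 1, center=(cr, cc), radius=r, mask=inside))
    return SceneTruth(
        height_map=height,
        bodies=tuple(bodies),
        illum_params=tuple(STANDARD_ILLUMINATION),
        pixel_scale=spec.pixel_scale,
        spec=spec,
    )


def _light_vector(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector pointing from the surface toward the source, (row, col, up)."""
    phi = math.radians(azimuth_deg)
    th = math.radians(elevation_deg)
    return np.array([-math.sin(phi) * math.cos(th), -math.cos(phi) * math.cos(th), math.sin(th)])


def cast_shadow_mask(height_map: np.ndarray, azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Hard cast-shadow mask: march 1-px steps along the ray toward the source.

    A pixel is shadowed when any sampled terrain height along the ray
    exceeds the ray height at that step.  Rays leaving the image meet no
    blocker.  At 90 deg elevation nothing is shadowed.
    """
    if not (0.0 < elevation_deg <= 90.0):
        raise ValueError("elevation must lie in (0, 90] degrees")
    M, N = height_map.shape
    shadow = np.zeros((M, N), dtype=bool)
    if elevation_deg == 90.0:
        return shadow
    s = _light_vector(azimuth_deg, elevation_deg)
    horiz = math.hypot(s[0], s[1])
    u = (s[0] / horiz, s[1] / horiz)
    slope = math.tan(math.radians(elevation_deg))
    hmax = float(height_map.max())
    if hmax <= 0:
        return shadow
    n_steps = int(math.ceil(hmax / slope)) + 1
    rr0 = np.arange(M)[:, None]
    cc0 = np.arange(N)[None, :]
    for step in range(1, n_steps + 1):
        dr = int(np.rint(step * u[0]))
        dc = int(np.rint(step * u[1]))
        rr = rr0 + dr
        cc = cc0 + dc
        valid = (rr >= 0) & (rr < M) & (cc >= 0) & (cc < N)
        sampled = np.where(valid, height_map[rr.clip(0, M - 1), cc.clip(0, N - 1)], -np.inf)
        ray_h = height_map + step * slope
        shadow |= sampled > ray_h + 1e-9
    return shadow


def render_capture(
    truth: SceneTruth,
    azimuth_deg: float,
    elevation_deg: float,
    noise: NoiseSpec | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
) -> IlluminatedCapture:
    """Render one capture of the scene under a directional light.

    Shading is Lambertian -- the dot product of the height-map surface
    normal (central finite differences; one-sided at the borders, which is
    what :func:`numpy.gradient` computes) with the unit vector toward the
    source, clamped at zero -- on top of a small ambient floor, multiplied
    by an albedo map (``base_level`` on the base, a fixed brighter albedo on
    the bodies).  Cast shadows attenuate the result multiplicatively.
    Noise is applied after shading.  Grey values are clipped to [0, 1];
    identical inputs and seed reproduce the image bit-exactly.
    """
    if not (0.0 < elevation_deg <= 90.0):
        raise ValueError("elevation must lie in (0, 90] degrees")
    h = truth.height_map
    if not np.all(np.isfinite(h)):
        raise ValueError("height map must be finite")
    gr, gc = np.gradient(h)
    s = _light_vector(azimuth_deg, elevation_deg)
    norm = np.sqrt(gr**2 + gc**2 + 1.0)
    lambert = np.clip((-gr * s[0] - gc * s[1] + s[2]) / norm, 0.0, None)
    albedo = np.where(truth.union_mask, _BODY_ALBEDO, truth.spec.base_level)
    img = albedo * (_AMBIENT + (1.0 - _AMBIENT) * lambert)
    shadow = cast_shadow_mask(h, azimuth_deg, elevation_deg)
    img = np.where(shadow, img * _SHADOW_ATTENUATION, img)

    if noise is not None and not noise.is_zero:
        rng = np.random.default_rng(rng_seed)
        if noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, noise.gaussian_sd, img.shape)
        if noise.poisson_scaling > 0:
            sd = np.sqrt(np.clip(img, 0.0, None) * noise.poisson_scaling)
            img = img + sd * rng.standard_normal(img.shape)
        if noise.speckle_var > 0:
            img = img * (1.0 + math.sqrt(noise.speckle_var) * rng.standard_normal(img.shape))
    img = np.clip(img, 0.0, 1.0)
    return IlluminatedCapture(image=img, azimuth_deg=azimuth_deg, elevation_deg=elevation_deg)


def render_standard_set(
    truth: SceneTruth,
    noise: NoiseSpec | None = None,
    rng_seed: int | None = None,
) -> list[IlluminatedCapture]:
    """Render the four standard captures: two top lights, one per side.

    ``noise``/``rng_seed`` default to the generating spec's values; each
    capture gets an independent child seed so the noise fields differ
    between captures but the whole set is reproducible.
    """
    if noise is None:
        noise = truth.spec.noise
    if rng_seed is None:
        rng_seed = truth.spec.seed
    children = np.random.SeedSequence(rng_seed).spawn(len(truth.illum_params))
    captures = []
    for (tag, az, el), child in zip(truth.illum_params, children):
        cap = render_capture(truth, az, el, noise=noise, rng_seed=child)
        captures.append(replace(cap, tag=tag))
    return captures
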