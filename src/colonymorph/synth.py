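"""Synthetic phase-contrast well images with ground-truth colony masks.

Emulates the imaging geometry of an automated incubator-microscope:
8-bit grayscale tiles, nominally 1,000 x 1,000 px covering
2,000 x 2,000 um^2 (2 um/px).  Two colony phenotypes are modelled:

* ``esc_like`` -- round, tightly packed colony with a sharp bright halo
  around a darker textured interior (the healthy ESC-like morphology);
* ``collapsed_edge`` -- irregularly collapsed colony edge with a weak
  halo and a flat, low-contrast periphery (the "unhealthy" phenotype
  enriched in aberrant subclones).

The optics are deliberately phenomenological: a smooth background
gradient, a positive rim (halo) just outside the colony boundary, a
darker textured interior, additive Gaussian pixel noise, then 8-bit
quantization.  The colony boundary is a radius-modulated closed curve

    r(theta) = r0 * (1 + e * w(theta) + f(theta))

where ``w`` is a normalized low-order harmonic series scaled by
``edge_irregularity`` e, and ``f`` adds sparse narrow positive spikes
controlled by ``fibrousness``.  Boundary shape depends only on the
``ColonySpec`` fields (never on the scene seed), so ground truth is
identical across noise realizations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ColonySpec",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "render_rotated",
    "make_two_population_benchmark",
    "make_two_population_scene_specs",
    "COLLAPSED_EDGE_IRREGULARITY_FLOOR",
    "MIN_FOREGROUND_CONTRAST",
]

#: Minimum edge_irregularity for a colony declared ``collapsed_edge``.
COLLAPSED_EDGE_IRREGULARITY_FLOOR = 0.15

#: Guaranteed minimum |foreground - local background| intensity offset in a
#: noise-free render (interior texture noise is clipped at 2 sigma so the
#: interior depression of 28 grey levels is never fully cancelled for
#: interior_texture_sd <= 12).
MIN_FOREGROUND_CONTRAST = 3.0

_BACKGROUND_LEVEL = 100.0
_INTERIOR_DEPRESSION = 28.0
_HALO_WIDTH_PX = 6.0
#: Maximum tolerated pairwise mask overlap, as a fraction of the smaller
#: colony's area; beyond this the scene is rejected as over-occluded.
MAX_OCCLUSION_FRACTION = 0.10


@dataclass(frozen=True)
class ColonySpec:
    """Generative description of a single colony."""

    center_px: tuple[float, float]  # (row, col)
    base_radius_px: float
    edge_irregularity: float = 0.0
    fibrousness: float = 0.0
    halo_strength: float = 45.0
    interior_texture_sd: float = 6.0
    morph_class: str = "esc_like"

    def validate(self) -> None:
        if self.base_radius_px <= 0:
            raise ValueError("base_radius_px must be > 0")
        if not 0.0 <= self.edge_irregularity <= 1.0:
            raise ValueError("edge_irregularity must be in [0, 1]")
        if self.fibrousness < 0:
            raise ValueError("fibrousness must be >= 0")
        if self.morph_class not in ("esc_like", "collapsed_edge"):
            raise ValueError(f"unknown morph_class {self.morph_class!r}")
        if (
            self.morph_class == "collapsed_edge"
            and self.edge_irregularity < COLLAPSED_EDGE_IRREGULARITY_FLOOR
        ):
            raise ValueError(
                "collapsed_edge colonies require edge_irregularity >= "
                f"{COLLAPSED_EDGE_IRREGULARITY_FLOOR}"
            )


@dataclass(frozen=True)
class SceneSpec:
    """Full generative description of one synthetic well image."""

    image_size_px: tuple[int, int] = (1000, 1000)  # (rows, cols)
    um_per_px: float = 2.0
    colonies: tuple[ColonySpec, ...] = ()
    debris_count: int = 0
    background_gradient_amplitude: float = 10.0
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.image_size_px) <= 0:
            raise ValueError("image_size_px must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c in self.colonies:
            c.validate()

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "SceneSpec":
        d = json.loads(text)
        colonies = tuple(
            ColonySpec(**{**c, "center_px": tuple(c["center_px"])})
            for c in d.pop("colonies", [])
        )
        d["image_size_px"] = tuple(d["image_size_px"])
        return SceneSpec(colonies=colonies, **d)


@dataclass
class GroundTruth:
    """Label raster (0 = background) plus per-label class and spec."""

    label_image: np.ndarray
    class_of_label: dict[int, str] = field(default_factory=dict)
    specs: list[ColonySpec] = field(default_factory=list)

    @property
    def n_colonies(self) -> int:
        return len(self.class_of_label)

    def mask_of(self, label: int) -> np.ndarray:
        return self.label_image == label

    def area_of(self, label: int) -> int:
        return int(np.count_nonzero(self.label_image == label))


def _colony_rng(spec: ColonySpec) -> np.random.Generator:
    # Boundary shape must depend only on the colony spec so that ground
    # truth is invariant to the scene seed; hash the fields into a seed.
    key = repr(
        (
            tuple(np.round(spec.center_px, 6)),
            round(spec.base_radius_px, 6),
            round(spec.edge_irregularity, 6),
            round(spec.fibrousness, 6),
            round(spec.halo_strength, 6),
            round(spec.interior_texture_sd, 6),
            spec.morph_class,
        )
    ).encode()
    digest = hashlib.blake2b(key, digest_size=4).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def _boundary_radius(spec: ColonySpec, theta: np.ndarray) -> np.ndarray:
    """Boundary radius r(theta) for angles in radians."""
    r = np.full_like(theta, float(spec.base_radius_px))
    if spec.edge_irregularity == 0.0 and spec.fibrousness == 0.0:
        return r
    rng = _colony_rng(spec)
    # Low-order harmonics: the irregular, collapsed-edge look.
    ks = np.arange(2, 6)
    amps = rng.uniform(0.5, 1.0, size=ks.size) / ks
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)
    wave = np.zeros_like(theta)
    for k, a, p in zip(ks, amps, phases):
        wave += a * np.cos(k * theta + p)
    tgrid = np.linspace(0.0, 2 * np.pi, 2048)
    dense = np.zeros_like(tgrid)
    for k, a, p in zip(ks, amps, phases):
        dense += a * np.cos(k * tgrid + p)
    peak = np.abs(dense).max()
    if peak > 0:
        # Normalize so edge_irregularity is the max fractional radius
        # deviation contributed by the harmonic series.
        wave = wave / peak
    r = r * (1.0 + spec.edge_irregularity * wave)
    # Sparse narrow spikes: fibrous protrusions of the outline.
    n_spikes = int(round(spec.fibrousness))
    if n_spikes > 0:
        centers = rng.uniform(0, 2 * np.pi, size=n_spikes)
        widths = rng.uniform(0.03, 0.05, size=n_spikes)
        heights = rng.uniform(0.06, 0.12, size=n_spikes)
        for c, w, h in zip(centers, widths, heights):
            d = np.angle(np.exp(1j * (theta - c)))
            r += spec.base_radius_px * h * np.exp(-0.5 * (d / w) ** 2)
    return r


def _paint_colony(
    scene: np.ndarray, spec: ColonySpec, rng: np.random.Generator
) -> np.ndarray:
    """Paint one colony onto ``scene`` in place; return its boolean mask."""
    nrow, ncol = scene.shape
    r_max = spec.base_radius_px * (1 + spec.edge_irregularity + 0.15) + _HALO_WIDTH_PX + 2
    cy, cx = spec.center_px
    r0 = max(int(np.floor(cy - r_max)), 0)
    r1 = min(int(np.ceil(cy + r_max)) + 1, nrow)
    c0 = max(int(np.floor(cx - r_max)), 0)
    c1 = min(int(np.ceil(cx + r_max)) + 1, ncol)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    rb = _boundary_radius(spec, theta)
    inside = rho <= rb

    # Interior: uniform depression plus clipped texture noise.  The
    # texture generator is seeded per colony so interiors are repeatable
    # only within one scene realization (they carry the scene seed).
    texture = np.clip(rng.standard_normal(inside.shape), -2.0, 2.0)
    interior = -_INTERIOR_DEPRESSION + spec.interior_texture_sd * texture
    # Slightly deeper core for the tight dark ESC-like interior.
    depth = np.clip(1.0 - rho / np.maximum(rb, 1e-9), 0.0, 1.0)
    if spec.morph_class == "esc_like":
        interior -= 6.0 * depth
    patch = scene[r0:r1, c0:c1]
    patch[inside] += interior[inside]

    # Halo: bright positive rim just outside the boundary, tapering out.
    halo_band = (rho > rb) & (rho <= rb + _HALO_WIDTH_PX)
    taper = np.clip(1.0 - (rho - rb) / _HALO_WIDTH_PX, 0.0, 1.0)
    patch[halo_band] += spec.halo_strength * taper[halo_band]

    mask = np.zeros(scene.shape, dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    nrow, ncol = spec.image_size_px
    scene = np.full((nrow, ncol), _BACKGROUND_LEVEL, dtype=float)
    if spec.background_gradient_amplitude != 0:
        angle = rng.uniform(0, 2 * np.pi)
        yy = np.linspace(-0.5, 0.5, nrow)[:, None]
        xx = np.linspace(-0.5, 0.5, ncol)[None, :]
        ramp = np.cos(angle) * yy + np.sin(angle) * xx
        scene += spec.background_gradient_amplitude * ramp
    return scene


def _paint_debris(
    scene: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> None:
    """Small high-contrast specks, well below the noise-reduction gate."""
    nrow, ncol = scene.shape
    for _ in range(spec.debris_count):
        cy = rng.uniform(5, nrow - 5)
        cx = rng.uniform(5, ncol - 5)
        rad = rng.uniform(2.0, 8.0)  # area <= ~200 px << 2,046 px
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(30.0, 60.0)
        r0, r1 = int(cy - rad - 1), int(cy + rad + 2)
        c0, c1 = int(cx - rad - 1), int(cx + rad + 2)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, nrow), min(c1, ncol)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        blob = np.hypot(yy - cy, xx - cx) <= rad
        scene[r0:r1, c0:c1][blob] += amp


def _render_float(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Noise-free float scene plus ground truth."""
    spec.validate()
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    scene = _background(spec, rng)
    masks = []
    for colony in spec.colonies:
        masks.append(_paint_colony(scene, colony, rng))
    # Occlusion check and label resolution.
    label_image = np.zeros(scene.shape, dtype=np.uint16)
    areas = [int(m.sum()) for m in masks]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            overlap = int((masks[i] & masks[j]).sum())
            smaller = min(areas[i], areas[j])
            if smaller and overlap / smaller > MAX_OCCLUSION_FRACTION:
                raise ValueError(
                    f"colonies {i} and {j} overlap by {overlap} px "
                    f"(> {MAX_OCCLUSION_FRACTION:.0%} of the smaller colony); "
                    "rejecting over-occluded scene"
                )
    # Later colonies win small overlaps; labels are consecutive 1..n.
    class_of_label: dict[int, str] = {}
    for i, (mask, colony) in enumerate(zip(masks, spec.colonies), start=1):
        label_image[mask] = i
        class_of_label[i] = colony.morph_class
    _paint_debris(scene, spec, rng)
    gt = GroundTruth(
        label_image=label_image,
        class_of_label=class_of_label,
        specs=list(spec.colonies),
    )
    return scene, gt


def _quantize(scene: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        scene = scene + noise_sd * rng.standard_normal(scene.shape)
    return np.clip(np.rint(scene), 0, 255).astype(np.uint8)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic well image.

    Returns an 8-bit grayscale image and the :class:`GroundTruth` whose
    label raster is the colony boundary before optics and noise.
    Identical specs (including seed) give bit-identical output.
    """
    scene, gt = _render_float(spec)
    noise_rng = np.random.default_rng(np.random.PCG64(spec.seed).jumped(1))
    return _quantize(scene, spec.noise_sd, noise_rng), gt


def render_rotated(spec: SceneSpec, half_turn: bool) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene as if the plate were physically rotated 180 deg.

    The noise-free optical scene is rotated, then fresh pixel noise is
    drawn (a re-imaged plate does not reuse the original shot noise).
    Ground-truth labels correspond to the unrotated labels under the
    rotation map.
    """
    if not half_turn:
        return render_scene(spec)
    scene, gt = _render_float(spec)
    scene = scene[::-1, ::-1].copy()
    gt.label_image = gt.label_image[::-1, ::-1].copy()
    noise_rng = np.random.default_rng(np.random.PCG64(spec.seed).jumped(2))
    return _quantize(scene, spec.noise_sd, noise_rng), gt


# ---------------------------------------------------------------------------
# Two-population benchmark
# ---------------------------------------------------------------------------

#: Class-contrast parameters at effect = 1 (see docs/methods.md).  The
#: esc_like base values are shared by both classes; ``effect`` scales the
#: collapsed_edge deltas, so effect = 0 makes the class distributions
#: coincide.
_BENCH_IMAGE_SIZE = (960, 960)
_BENCH_RADIUS_RANGE = (255.0, 285.0)
_BENCH_EDGE_BASE = (0.03, 0.06)
_BENCH_EDGE_DELTA = (0.26, 0.34)
_BENCH_FIB_DELTA = (5.0, 8.0)
_BENCH_HALO_BASE = 45.0
_BENCH_HALO_DELTA = -25.0
_BENCH_TEXTURE_BASE = 6.0
_BENCH_TEXTURE_DELTA = 5.0


def _benchmark_colony(
    morph_class: str, effect: float, rng: np.random.Generator,
    image_size: tuple[int, int],
) -> ColonySpec:
    nrow, ncol = image_size
    radius = rng.uniform(*_BENCH_RADIUS_RANGE)
    jitter = rng.uniform(-10, 10, size=2)
    edge = rng.uniform(*_BENCH_EDGE_BASE)
    fib = 0.0
    halo = _BENCH_HALO_BASE
    tex = _BENCH_TEXTURE_BASE
    if morph_class == "collapsed_edge":
        edge += effect * rng.uniform(*_BENCH_EDGE_DELTA)
        fib += effect * rng.uniform(*_BENCH_FIB_DELTA)
        halo += effect * _BENCH_HALO_DELTA
        tex += effect * _BENCH_TEXTURE_DELTA
    if effect == 0:
        morph_class = "esc_like"  # distributions coincide at the null
    return ColonySpec(
        center_px=(nrow / 2 + jitter[0], ncol / 2 + jitter[1]),
        base_radius_px=radius,
        edge_irregularity=min(edge, 1.0),
        fibrousness=fib,
        halo_strength=halo,
        interior_texture_sd=tex,
        morph_class=morph_class,
    )


def make_two_population_scene_specs(
    n_per_class: int,
    effect: float,
    seed: int,
    image_size: tuple[int, int] = _BENCH_IMAGE_SIZE,
    noise_sd: float = 3.0,
    debris_count: int = 0,
) -> list[SceneSpec]:
    """Scene specs for the two-population benchmark (without rendering).

    ``2 * n_per_class`` single-colony scenes, alternating esc_like /
    collapsed_edge, deterministic given ``seed``.  ``effect`` scales the
    class separation; at 0 the two classes' spec distributions coincide.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(np.random.PCG64(seed).jumped(7))
    specs = []
    for _ in range(n_per_class):
        for morph_class in ("esc_like", "collapsed_edge"):
            colony = _benchmark_colony(morph_class, effect, rng, image_size)
            scene_seed = int(rng.integers(0, 2**31 - 1))
            specs.append(
                SceneSpec(
                    image_size_px=image_size,
                    colonies=(colony,),
                    debris_count=debris_count,
                    background_gradient_amplitude=10.0,
                    noise_sd=noise_sd,
                    seed=scene_seed,
                )
            )
    return specs


def make_two_population_benchmark(
    n_per_class: int,
    effect: float,
    seed: int,
    image_size: tuple[int, int] = _BENCH_IMAGE_SIZE,
    noise_sd: float = 3.0,
    debris_count: int = 0,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Rendered two-population benchmark scenes (see scene-spec variant)."""
    return [
        render_scene(spec)
        for spec in make_two_population_scene_specs(
            n_per_class, effect, seed, image_size, noise_sd, debris_count
        )
    ]
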