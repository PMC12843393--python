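"""Seeded synthetic desert-farmland scenes with exact ground truth.

Real benchmark imagery of sparse desert agriculture is rarely shareable, so
the package ships a generator that emulates the statistical structure such
scenes stress a segmenter with:

* a sandy, low-saturation background (hue ~20-50°) with smooth low-frequency
  brightness variation,
* sparse green vegetation blobs (hue ~90-150°, high saturation) carrying
  high-frequency canopy speckle on the value channel,
* optional *distractors*: green-hued but texture-flat rectangles (painted
  equipment, roofs) that overlap vegetation in hue yet are excluded from the
  truth mask — color alone cannot separate them, texture can,
* shadows applied as a multiplicative reduction of V crossing both classes
  (hue is untouched, which is exactly the property that motivates HSV),
* additive Gaussian sensor noise in the 8-bit RGB domain.

Every scene is fully determined by its seed. ``generate_benchmark`` writes a
directory of scenes with a 70/30 image-level train/test split manifest
(84/36 at the reference size of 120 scenes), guaranteeing no image appears
in both partitions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .color import hsv_to_rgb, quantize_u8
from .exceptions import ParameterError
from . import imgio as dio

__all__ = [
    "SceneParams",
    "easy_scene_params",
    "discriminating_scene_params",
    "generate_scene",
    "generate_benchmark",
]


@dataclass(frozen=True)
class SceneParams:
    """The stated world of one synthetic scene (all ranges inclusive)."""

    size: tuple[int, int] = (256, 256)
    vegetation_fraction_target: float = 0.2
    blob_radius: tuple[float, float] = (8.0, 20.0)
    max_blobs: int = 500
    vegetation_hue: tuple[float, float] = (90.0, 150.0)
    soil_hue: tuple[float, float] = (20.0, 50.0)
    vegetation_saturation: tuple[float, float] = (0.55, 0.9)
    soil_saturation: tuple[float, float] = (0.12, 0.35)
    vegetation_value: tuple[float, float] = (0.35, 0.6)
    soil_value: tuple[float, float] = (0.55, 0.85)
    vegetation_texture_amplitude: float = 0.16
    soil_texture_amplitude: float = 0.02
    shadow_count: int = 2
    shadow_value_multiplier: float = 0.55
    distractor_count: int = 0
    distractor_side: tuple[int, int] = (18, 40)
    #: per-scene global brightness factor range (time-of-day diversity);
    #: multiplies V, so hue and saturation are unaffected
    illumination_range: tuple[float, float] = (0.75, 1.05)
    #: per-scene per-channel white-balance gain range (color-temperature /
    #: auto-white-balance drift between captures); shifts RGB clusters
    #: scene-to-scene while hue, a channel ratio, moves only slightly
    color_cast_range: tuple[float, float] = (0.92, 1.08)
    noise_sigma: float = 3.0
    seed: int | tuple[int, ...] = 0

    def __post_init__(self):
        h, w = self.size
        if h < 32 or w < 32:
            raise ParameterError("scene must be at least 32x32")
        if not 0.0 < self.vegetation_fraction_target < 0.6:
            raise ParameterError(
                "vegetation_fraction_target must lie in (0, 0.6), got "
                f"{self.vegetation_fraction_target}"
            )
        for name in (
            "blob_radius",
            "vegetation_hue",
            "soil_hue",
            "vegetation_saturation",
            "soil_saturation",
            "vegetation_value",
            "soil_value",
            "distractor_side",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ParameterError(f"{name} range must be non-degenerate, got {lo, hi}")
        if not 0.0 < self.shadow_value_multiplier < 1.0:
            raise ParameterError("shadow_value_multiplier must lie in (0, 1)")
        if not 0.0 < self.illumination_range[0] <= self.illumination_range[1]:
            raise ParameterError("illumination_range must be positive and ordered")
        if not 0.0 < self.color_cast_range[0] <= self.color_cast_range[1]:
            raise ParameterError("color_cast_range must be positive and ordered")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")
        if np.pi * self.blob_radius[0] ** 2 > 0.6 * h * w:
            raise ParameterError("smallest blob exceeds the feasible vegetation area")


def easy_scene_params(**overrides) -> SceneParams:
    """The easy benchmark: no distractors, no shadows, moderate sensor noise.

    Vegetation and soil separate cleanly in hue; only boundary mixing from
    the preprocessing chain and the additive noise stand in the way.
    """
    overrides.setdefault("distractor_count", 0)
    overrides.setdefault("shadow_count", 0)
    return SceneParams(**overrides)


def discriminating_scene_params(**overrides) -> SceneParams:
    """The discriminating benchmark: deep shadows + green texture-flat distractors.

    Deep shadows (umbra multiplier 0.35) collapse the Euclidean separation of
    dark vegetation and dark soil in raw RGB while hue remains informative,
    and the distractors overlap vegetation in hue while lacking its texture —
    so color-only and texture-blind models each have a designed failure mode.
    """
    # many small distractors with independent colors: the color-overlap
    # confusion they create is then statistically stable across scenes
    # instead of hinging on where a few large rectangles land in color space
    overrides.setdefault("distractor_count", 8)
    overrides.setdefault("distractor_side", (12, 24))
    overrides.setdefault("shadow_count", 3)
    overrides.setdefault("shadow_value_multiplier", 0.35)
    return SceneParams(**overrides)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Low-frequency random field rescaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


#: within-scene spatial wobble as a fraction of a soil parameter's range;
#: the rest of the range expresses *between*-scene diversity (soil color and
#: brightness differ from image to image in real surveys)
_SOIL_SPATIAL_FRACTION = 0.35


def _soil_field(rng: np.random.Generator, shape, sigma: float, bounds) -> np.ndarray:
    """Per-scene base level plus smooth spatial variation, clipped to bounds."""
    lo, hi = bounds
    base = rng.uniform(lo, hi)
    wobble = (_smooth_field(rng, shape, sigma) - 0.5) * _SOIL_SPATIAL_FRACTION * (hi - lo)
    return np.clip(base + wobble, lo, hi)


def _speckle(rng: np.random.Generator, shape, amplitude: float) -> np.ndarray:
    """High-frequency (band-passed) texture with zero mean."""
    n = rng.standard_normal(shape)
    hp = n - ndimage.gaussian_filter(n, 2.0, mode="reflect")
    return amplitude * hp / max(hp.std(), 1e-12)


def _ellipse_mask(shape, cy, cx, ry, rx, theta) -> np.ndarray:
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    yc, xc = y - cy, x - cx
    u = np.cos(theta) * xc + np.sin(theta) * yc
    v = -np.sin(theta) * xc + np.cos(theta) * yc
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _sample(rng: np.random.Generator, rng_pair) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi))


def generate_scene(params: SceneParams) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one scene; returns (RGB uint8 image, boolean truth mask, metadata).

    The metadata carries the exact vegetation fraction, the shadow and
    distractor masks, and the pre-noise float HSV composition (useful for
    asserting e.g. hue invariance under shadows).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.size
    n_px = h * w

    # --- soil background -------------------------------------------------
    hue = _soil_field(rng, (h, w), 24, params.soil_hue)
    sat = _soil_field(rng, (h, w), 32, params.soil_saturation)
    val = _soil_field(rng, (h, w), 40, params.soil_value)
    val = val + _speckle(rng, (h, w), params.soil_texture_amplitude)

    # --- vegetation blobs -------------------------------------------------
    veg = np.zeros((h, w), dtype=bool)
    target_px = params.vegetation_fraction_target * n_px
    r_lo, r_hi = params.blob_radius
    for _ in range(params.max_blobs):
        deficit = target_px - veg.sum()
        if deficit <= 0:
            break
        # cap the radius by the remaining deficit to bound the overshoot
        r_cap = max(r_lo + 0.5, min(r_hi, np.sqrt(deficit / np.pi) + 1.0))
        ry = rng.uniform(r_lo, r_cap)
        rx = rng.uniform(r_lo, r_cap)
        cy = rng.uniform(ry, h - ry)
        cx = rng.uniform(rx, w - rx)
        theta = rng.uniform(0, np.pi)
        blob = _ellipse_mask((h, w), cy, cx, ry, rx, theta)
        veg |= blob
        hue[blob] = _sample(rng, params.vegetation_hue)
        sat[blob] = _sample(rng, params.vegetation_saturation)
        val[blob] = _sample(rng, params.vegetation_value)
    fraction = veg.mean()
    if fraction < params.vegetation_fraction_target * 0.7:
        raise ParameterError(
            f"could not reach vegetation fraction {params.vegetation_fraction_target} "
            f"(got {fraction:.3f}); enlarge the scene or the blob budget"
        )
    # canopy speckle on V inside vegetation only
    val = np.where(
        veg, val + _speckle(rng, (h, w), params.vegetation_texture_amplitude), val
    )

    # --- green texture-flat distractors ----------------------------------
    distractor = np.zeros((h, w), dtype=bool)
    for _ in range(params.distractor_count):
        for _try in range(50):
            sy = int(rng.integers(params.distractor_side[0], params.distractor_side[1]))
            sx = int(rng.integers(params.distractor_side[0], params.distractor_side[1]))
            y0 = int(rng.integers(0, max(1, h - sy)))
            x0 = int(rng.integers(0, max(1, w - sx)))
            region = (slice(y0, y0 + sy), slice(x0, x0 + sx))
            if not veg[region].any():
                hue[region] = _sample(rng, params.vegetation_hue)
                sat[region] = _sample(rng, params.vegetation_saturation)
                val[region] = _sample(rng, params.vegetation_value)
                distractor[region] = True
                break
    # distractors are never vegetation, even if placement had to overlap
    veg &= ~distractor

    # --- global illumination (time of day): V scaled, hue untouched -------
    val = val * rng.uniform(*params.illumination_range)
    # per-scene white-balance gains, applied later in the RGB domain
    cast = rng.uniform(*params.color_cast_range, size=3)

    # --- shadows: multiplicative V reduction, hue untouched ---------------
    # soft (penumbral) edges: the multiplier varies continuously between 1
    # outside and shadow_value_multiplier in the umbra, as cast shadows do
    # in real imagery; H and S are untouched by construction
    shadow = np.zeros((h, w), dtype=bool)
    for _ in range(params.shadow_count):
        ry = rng.uniform(0.12 * h, 0.3 * h)
        rx = rng.uniform(0.12 * w, 0.3 * w)
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        theta = rng.uniform(0, np.pi)
        shadow |= _ellipse_mask((h, w), cy, cx, ry, rx, theta)
    if shadow.any():
        depth = ndimage.gaussian_filter(shadow.astype(np.float64), 6.0, mode="reflect")
        peak = depth.max()
        if peak > 0:
            depth /= peak
        val = val * (1.0 - (1.0 - params.shadow_value_multiplier) * depth)

    hsv = np.stack(
        [np.mod(hue, 360.0), np.clip(sat, 0.0, 1.0), np.clip(val, 0.02, 1.0)], axis=-1
    )
    rgb = quantize_u8(hsv_to_rgb(hsv).astype(np.float64) * cast)
    if params.noise_sigma > 0:
        rgb = quantize_u8(
            rgb.astype(np.float64) + rng.normal(0.0, params.noise_sigma, rgb.shape)
        )

    meta = {
        "vegetation_fraction": float(veg.mean()),
        "shadow_mask": shadow,
        "distractor_mask": distractor,
        "hsv_prenoise": hsv,
        "params": asdict(params),
    }
    return rgb, veg, meta


def generate_benchmark(
    n_scenes: int,
    params: SceneParams | None = None,
    seed: int = 0,
    out_dir: str | Path = "benchmark",
) -> dict:
    """Write ``n_scenes`` scenes plus a 70/30 image-level split manifest.

    Scene ``i`` is generated from the derived seed ``(seed, i)``, so any
    scene can be regenerated without the others. Returns the manifest dict
    (also written to ``manifest.json``): scene ids under ``"train"`` and
    ``"test"``, disjoint by construction.
    """
    if n_scenes < 2:
        raise ParameterError(f"need at least 2 scenes, got {n_scenes}")
    params = params or SceneParams()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    scene_meta = {}
    ids = []
    for i in range(n_scenes):
        sid = f"scene_{i:03d}"
        ids.append(sid)
        rgb, mask, meta = generate_scene(replace(params, seed=(seed, i)))
        dio.write_rgb(out / "images" / f"{sid}.png", rgb)
        dio.write_mask(out / "masks" / f"{sid}.png", mask)
        scene_meta[sid] = {
            "seed": [seed, i],
            "vegetation_fraction": meta["vegetation_fraction"],
        }

    order = np.random.default_rng(seed).permutation(n_scenes)
    n_train = int(np.floor(0.7 * n_scenes + 0.5))
    n_train = min(max(n_train, 1), n_scenes - 1)
    manifest = {
        "train": sorted(ids[i] for i in order[:n_train]),
        "test": sorted(ids[i] for i in order[n_train:]),
        "seed": seed,
        "n_scenes": n_scenes,
        "params": asdict(params),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "metadata.json", "w") as fh:
        json.dump(scene_meta, fh, indent=2)
    return manifest
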