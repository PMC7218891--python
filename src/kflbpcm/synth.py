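"""Synthetic plant-scene generator.

Renders labeled RGB images that emulate the structure of testbed crop/weed
datasets: a soil-textured background and one or two green plants whose
species differ in leaf-margin morphology (lobed, serrated, grass blade)
and venation texture but deliberately share very similar hue — color alone
is designed to be uninformative, which is exactly the regime the contour
feature branch targets.  Growth stages are emulated by rendered scale,
and every image is fully determined by an integer seed.

The generator makes no attempt at photorealism: no occlusion physics, no
shadows, no statistical match to any real dataset.  It supplies the
geometry and texture contrasts that the feature pipeline is supposed to
exploit, at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.color import hsv2rgb
from skimage.draw import polygon as draw_polygon

from ._exceptions import ConfigError, DataError
from .imaging import PlantImage, read_image

__all__ = [
    "SpeciesSpec",
    "SceneSpec",
    "STAGE_SCALES",
    "default_species",
    "background_spec",
    "render_scene",
    "generate_dataset",
    "load_dataset",
]

#: Growth stage → fraction of the frame the plant occupies.  Stage 4 fills
#: (and its lobes overflow) the frame; earlier stages sit fully in frame.
STAGE_SCALES: dict[int, float] = {1: 0.30, 2: 0.45, 3: 0.70, 4: 1.00}

#: Discrete capture rotations emulated by the generator.
ROTATION_ANGLES = tuple(float(a) for a in range(45, 361, 45))

DEFAULT_SIZE = (228, 228)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """Geometry and texture of one synthetic species.

    ``margin`` is the leaf-edge style: ``"smooth"``, ``"lobed"`` (with
    ``lobe_depth``/``lobe_count`` and optional fine serration), ``"blade"``
    (grass), or ``"none"`` (bare-soil background class).  ``base_hue`` is
    an HSV hue in the green range; ``texture_freq`` is the venation stripe
    frequency in cycles per pixel, which is independent of rendered scale.
    """

    name: str
    margin: str = "lobed"
    n_leaflets: int = 3
    base_hue: float = 0.30
    texture_freq: float = 0.06
    lobe_depth: float = 0.0
    lobe_count: int = 0
    serration_depth: float = 0.0
    serration_count: int = 0

    def __post_init__(self) -> None:
        if self.margin not in ("smooth", "lobed", "blade", "none"):
            raise ConfigError(f"unknown margin style {self.margin!r}")
        if self.margin != "none" and self.n_leaflets < 1:
            raise ConfigError("n_leaflets must be >= 1")
        if not (0.0 <= self.base_hue <= 1.0):
            raise ConfigError("base_hue must be an HSV hue in [0, 1]")

    def morphology_signature(self) -> tuple:
        """Everything except color — used to enforce that species never
        differ only in hue."""
        return (self.margin, self.n_leaflets, self.texture_freq,
                self.lobe_depth, self.lobe_count,
                self.serration_depth, self.serration_count)


def default_species() -> dict[str, SpeciesSpec]:
    """Three species of near-identical hue but distinct margins/texture.

    * ``canola_like`` — broad leaves with shallow, smooth lobes;
    * ``radish_like`` — deeply lobed, finely serrated margin;
    * ``barley_like`` — narrow grass blades.
    """
    return {
        "canola_like": SpeciesSpec(
            name="canola_like", margin="lobed", n_leaflets=3,
            base_hue=0.300, texture_freq=0.050,
            lobe_depth=0.08, lobe_count=7,
        ),
        "radish_like": SpeciesSpec(
            name="radish_like", margin="lobed", n_leaflets=3,
            base_hue=0.315, texture_freq=0.110,
            lobe_depth=0.35, lobe_count=5,
            serration_depth=0.15, serration_count=36,
        ),
        "barley_like": SpeciesSpec(
            name="barley_like", margin="blade", n_leaflets=7,
            base_hue=0.330, texture_freq=0.080,
        ),
    }


def background_spec() -> SpeciesSpec:
    """The bare-soil class: no plant is drawn."""
    return SpeciesSpec(name="background", margin="none", n_leaflets=1)


@dataclass(frozen=True)
class SceneSpec:
    """One rendered scene: species (0–2 of them), stage, pose, lighting.

    ``stage_scale`` defaults to the :data:`STAGE_SCALES` mapping of
    ``stage`` and must be monotone in it.  ``seed`` fully determines the
    rendered pixels.
    """

    species: tuple[SpeciesSpec, ...] = ()
    stage: int = 3
    stage_scale: float | None = None
    rotation_deg: float = 0.0
    illumination_gain: float = 1.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) > 2:
            raise ConfigError("a scene holds at most 2 species")
        if self.stage < 1:
            raise ConfigError("stage must be >= 1")
        scale = self.stage_scale
        if scale is None:
            scale = STAGE_SCALES.get(self.stage, 1.0)
            object.__setattr__(self, "stage_scale", scale)
        if not (0.0 < scale <= 1.0):
            raise ConfigError(f"stage_scale must be in (0, 1], got {scale}")
        if self.illumination_gain <= 0:
            raise ConfigError("illumination_gain must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    @property
    def label(self) -> str:
        if not self.species:
            return "background"
        return "+".join(s.name for s in self.species)


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------

def _soil(H: int, W: int, rng: np.random.Generator) -> np.ndarray:
    """Brown soil texture in float RGB [0, 1]: smooth blobs + fine grain."""
    blobs = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (H, W)), sigma=4.0)
    grain = rng.normal(0.0, 1.0, (H, W))
    hue = 0.08 + 0.01 * blobs
    sat = np.clip(0.50 + 0.10 * blobs + 0.03 * grain, 0.0, 1.0)
    val = np.clip(0.36 + 0.10 * blobs + 0.05 * grain, 0.02, 1.0)
    return hsv2rgb(np.stack([np.clip(hue, 0, 1), sat, val], axis=-1))


def _margin_terms(sp: SpeciesSpec, rng: np.random.Generator
                  ) -> tuple[list[tuple[float, int, float]], float]:
    """(amplitude, harmonic, phase) terms of the radial margin modulation,
    plus the normalization keeping expected area constant across species
    (so that plant area is not a hue-free confound)."""
    terms = [(0.05, 2, rng.uniform(0, 2 * np.pi)),   # low-order individuality
             (0.03, 3, rng.uniform(0, 2 * np.pi))]
    if sp.margin == "lobed":
        if sp.lobe_depth > 0:
            terms.append((sp.lobe_depth, sp.lobe_count, rng.uniform(0, 2 * np.pi)))
        if sp.serration_depth > 0:
            terms.append((sp.serration_depth, sp.serration_count, rng.uniform(0, 2 * np.pi)))
    norm = np.sqrt(1.0 + 0.5 * sum(a * a for a, _, _ in terms))
    return terms, norm


def _leaf_mask(mask: np.ndarray, center: np.ndarray, radius: float,
               axis: float, sp: SpeciesSpec, rng: np.random.Generator) -> None:
    """Fill a lobed elliptical leaf into ``mask`` in place.

    The margin is a positive radial function r(θ), so the leaf is
    star-shaped and can be rasterized exactly by the test ρ ≤ r(θ) on the
    bounding-box pixel grid; the elliptical base (1.25 × 0.8, area
    preserving) is rotated to the leaf axis.
    """
    H, W = mask.shape
    terms, norm = _margin_terms(sp, rng)
    r_bound = radius * 1.25 * (1.0 + sum(a for a, _, _ in terms)) / norm + 2.0
    r0 = max(int(center[0] - r_bound), 0)
    r1 = min(int(center[0] + r_bound) + 1, H)
    c0 = max(int(center[1] - r_bound), 0)
    c1 = min(int(center[1] + r_bound) + 1, W)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dr, dc = yy - center[0], xx - center[1]
    ca, sa = np.cos(axis), np.sin(axis)
    # inverse of (rows, cols) = center + (x·sa + y·ca, x·ca − y·sa)
    x = dr * sa + dc * ca
    y = dr * ca - dc * sa
    u, v = x / 1.25, y / 0.80
    theta = np.arctan2(v, u)
    rho = np.hypot(u, v)
    mod = np.ones_like(theta)
    for a, h, phase in terms:
        mod += a * np.cos(h * theta + phase)
    r_theta = radius * np.clip(mod / norm, 0.05, None)
    mask[r0:r1, c0:c1] |= rho <= r_theta


def _blade_polygon(center: np.ndarray, radius: float, axis: float,
                   rng: np.random.Generator,
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    length = radius * rng.uniform(0.9, 1.15)
    width = max(0.10 * radius, 2.5)
    bend = rng.normal(0.0, 0.15)
    u = np.array([np.sin(axis), np.cos(axis)])          # along the blade
    v = np.array([np.cos(axis), -np.sin(axis)])         # across the blade
    tip = center + length * u + bend * length * v
    mid = center + 0.5 * length * u + 0.5 * bend * length * v
    pts = np.array([
        center - 0.5 * width * v,
        center + 0.5 * width * v,
        mid + 0.45 * width * v,
        tip + 0.10 * width * v,
        tip - 0.10 * width * v,
        mid - 0.45 * width * v,
    ])
    return draw_polygon(pts[:, 0], pts[:, 1], shape=shape)


def _plant_mask(H: int, W: int, center: np.ndarray, scale: float,
                sp: SpeciesSpec, rot_rad: float,
                rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((H, W), dtype=bool)
    R_plant = 0.40 * min(H, W) * scale
    n = sp.n_leaflets
    for i in range(n):
        axis = rot_rad + 2.0 * np.pi * i / n + rng.normal(0.0, 0.06)
        if sp.margin == "blade":
            rr, cc = _blade_polygon(center, 1.05 * R_plant, axis, rng, (H, W))
            mask[rr, cc] = True
        else:
            if n == 1:
                c, r_leaf = center, R_plant
            else:
                offset = 0.35 * R_plant * np.array([np.sin(axis), np.cos(axis)])
                c, r_leaf = center + offset, 0.68 * R_plant
            _leaf_mask(mask, c, r_leaf, axis, sp, rng)
    return mask


def _leaf_color(H: int, W: int, sp: SpeciesSpec, rot_rad: float,
                rng: np.random.Generator) -> np.ndarray:
    """Green leaf sheet with venation stripes at ``texture_freq`` cy/px."""
    yy, xx = np.mgrid[0:H, 0:W]
    beta = rot_rad + rng.normal(0.0, 0.2)
    coord = xx * np.cos(beta) + yy * np.sin(beta)
    stripes = np.sin(2.0 * np.pi * sp.texture_freq * coord + rng.uniform(0, 2 * np.pi))
    hue = sp.base_hue + rng.normal(0.0, 0.006) + 0.004 * rng.normal(0.0, 1.0, (H, W))
    sat = np.clip(0.62 + 0.05 * stripes, 0.0, 1.0)
    val = np.clip(0.52 * (1.0 + 0.16 * stripes + 0.04 * rng.normal(0.0, 1.0, (H, W))),
                  0.05, 1.0)
    return hsv2rgb(np.stack([np.clip(hue, 0, 1), sat, val], axis=-1))


def render_scene(spec: SceneSpec, size: tuple[int, int] = DEFAULT_SIZE) -> PlantImage:
    """Render one scene deterministically from its seed.

    Soil background, then each species' leaf polygons composited on top
    with venation texture, then global illumination gain and additive
    Gaussian pixel noise.
    """
    H, W = int(size[0]), int(size[1])
    if H < 16 or W < 16:
        raise ConfigError(f"degenerate render size {size}")
    rng = np.random.default_rng(spec.seed)
    img = _soil(H, W, rng)
    rot = np.deg2rad(spec.rotation_deg)
    centers: list[np.ndarray]
    if len(spec.species) == 2:
        centers = [np.array([H / 2 + rng.normal(0, 2), W * 0.30 + rng.normal(0, 2)]),
                   np.array([H / 2 + rng.normal(0, 2), W * 0.70 + rng.normal(0, 2)])]
        scale = spec.stage_scale * 0.70
    else:
        centers = [np.array([H / 2 + rng.normal(0, 3), W / 2 + rng.normal(0, 3)])]
        scale = spec.stage_scale
    for sp, center in zip(spec.species, centers):
        if sp.margin == "none":
            continue
        mask = _plant_mask(H, W, center, scale, sp, rot, rng)
        color = _leaf_color(H, W, sp, rot, rng)
        img = np.where(mask[..., None], color, img)
    img = img * spec.illumination_gain
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd / 255.0, img.shape)
    pixels = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    return PlantImage(pixels, label=spec.label, stage=spec.stage,
                      rotation_deg=spec.rotation_deg)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

ClassEntry = "SpeciesSpec | tuple[SpeciesSpec, SpeciesSpec]"


def _normalize_entry(entry) -> tuple[str, tuple[SpeciesSpec, ...]]:
    if isinstance(entry, SpeciesSpec):
        if entry.margin == "none":
            return entry.name, ()
        return entry.name, (entry,)
    pair = tuple(entry)
    if len(pair) != 2 or not all(isinstance(s, SpeciesSpec) for s in pair):
        raise ConfigError("a class entry is a SpeciesSpec or a pair of them")
    return "+".join(s.name for s in pair), pair


def _check_species_distinct(specs: Sequence[SpeciesSpec]) -> None:
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            if a.margin == "none" or b.margin == "none":
                continue
            if a.morphology_signature() == b.morphology_signature():
                raise ConfigError(
                    f"species {a.name!r} and {b.name!r} differ only in hue; "
                    "classes must differ in margin and/or texture"
                )


def generate_dataset(specs: Sequence, n_per_class: int = 50,
                     stages: Sequence[int] = (2, 3, 4), seed: int = 0,
                     size: tuple[int, int] = DEFAULT_SIZE,
                     out_dir: str | Path | None = None,
                     ) -> tuple[pd.DataFrame, list[PlantImage]]:
    """Render a balanced labeled dataset.

    Each class entry is a :class:`SpeciesSpec` (``margin="none"`` or
    :func:`background_spec` for the soil class) or a pair of specs for a
    mixed two-species class.  Every requested stage appears for every
    class; rotation is drawn from the eight 45° capture angles and the
    illumination gain from [0.75, 1.25].  The manifest records
    (path, label, stage, rotation, seed) per image; with ``out_dir`` set
    the images are also written as PNG next to a ``manifest.csv``.
    """
    if n_per_class < 10:
        raise ConfigError(f"n_per_class must be >= 10, got {n_per_class}")
    if not stages:
        raise ConfigError("at least one stage is required")
    entries = [_normalize_entry(e) for e in specs]
    labels = [lab for lab, _ in entries]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate class names in {labels}")
    flat = [s for _, sp in entries for s in sp]
    _check_species_distinct(flat)

    rng = np.random.default_rng(seed)
    rows, images = [], []
    for label, species in entries:
        for j in range(n_per_class):
            stage = int(stages[j % len(stages)])
            rotation = float(rng.choice(ROTATION_ANGLES)) % 360.0
            gain = float(rng.uniform(0.75, 1.25))
            scene_seed = int(rng.integers(2 ** 31))
            scene = SceneSpec(species=species, stage=stage,
                              rotation_deg=rotation,
                              illumination_gain=gain, seed=scene_seed)
            img = render_scene(scene, size=size)
            img.label = label
            path = f"{label}_s{stage}_{j:04d}.png"
            rows.append({"path": path, "label": label, "stage": stage,
                         "rotation": rotation, "seed": scene_seed})
            images.append(img)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for row, img in zip(rows, images):
            Image.fromarray(img.pixels).save(out / row["path"])
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, images


def load_dataset(data_dir: str | Path) -> list[PlantImage]:
    """Load an image directory through its ``manifest.csv``.

    The manifest needs at least (path, label, stage) columns; paths are
    relative to the directory.
    """
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.csv"
    if not manifest_path.exists():
        raise DataError(f"no manifest.csv in {data_dir}")
    manifest = pd.read_csv(manifest_path)
    for col in ("path", "label", "stage"):
        if col not in manifest.columns:
            raise DataError(f"manifest is missing the {col!r} column")
    images = []
    for row in manifest.itertuples(index=False):
        path = data_dir / str(row.path)
        if not path.exists():
            raise DataError(f"image file not found: {path}")
        rotation = float(getattr(row, "rotation", 0.0))
        images.append(read_image(path, label=str(row.label),
                                 stage=int(row.stage), rotation_deg=rotation))
    return images
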