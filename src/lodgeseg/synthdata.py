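"""Seeded synthetic 4-class crop-lodging scenes, dataset I/O, tiling.

Real lodging imagery consists of spatially contiguous canopy regions: upright
crop (NL) as dark-green, high-frequency speckle; half-lodged crop (HL) as
intermediate oblique streaking where stems lean; fully lodged crop (L) as
smooth, yellowish directional streaks of flattened canopy; plus background
(BG: soil, paths).  Lodged area is rare relative to upright crop, so the
default class priors are imbalanced (BG 0.25, NL 0.45, HL 0.20, L 0.10).

The label mask is built by thresholding a Gaussian-smoothed random field at
the cumulative prior quantiles with classes ordered BG < NL < HL < L along the
field value.  Because level sets of a smooth field are nested, the HL band
automatically borders both NL and L regions — mimicking the fact that lodged
patches grade into half-lodged crop at their edges.  Per-class textures are
rendered on top and pixel noise added; every byte is determined by the seed.

Masks are written as single-channel paletted PNGs with labels {0..3}
(lossless, the standard for segmentation datasets); images as RGB PNGs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneParams",
    "LodgingScene",
    "CLASS_NAMES",
    "generate_scene",
    "generate_dataset",
    "load_manifest",
    "load_scene",
    "save_scene",
    "tile_and_rescale",
    "rasterize_labelme",
]

CLASS_NAMES = ("BG", "NL", "HL", "L")

# palette: brown soil, green upright, yellow-green half-lodged, straw lodged
_MASK_PALETTE = [105, 85, 60, 40, 110, 40, 150, 150, 50, 200, 180, 90]

_BASE_COLORS = np.array(
    [
        [105, 85, 60],  # BG: brown soil
        [40, 95, 35],  # NL: dark green canopy
        [95, 120, 50],  # HL: leaning, yellow-green
        [160, 148, 78],  # L: flattened straw
    ],
    dtype=float,
)


@dataclass(frozen=True)
class SceneParams:
    size: tuple[int, int] = (128, 128)
    class_prior: tuple[float, float, float, float] = (0.25, 0.45, 0.20, 0.10)
    blob_scale: float = 12.0
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("scene size must be at least 32x32")
        if len(self.class_prior) != 4 or any(p <= 0 for p in self.class_prior):
            raise ValueError("class_prior needs 4 strictly positive entries")
        total = float(sum(self.class_prior))
        if abs(total - 1.0) > 1e-6:
            raise ValueError("class_prior must sum to 1")


@dataclass(frozen=True)
class LodgingScene:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8 in {0..3}
    class_fractions: tuple[float, float, float, float]

    @staticmethod
    def from_arrays(image: np.ndarray, mask: np.ndarray) -> "LodgingScene":
        fracs = tuple(
            float(np.mean(mask == c)) for c in range(len(CLASS_NAMES))
        )
        return LodgingScene(image=image, mask=mask, class_fractions=fracs)


def _texture(cls: int, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Per-class luminance modulation field in [-1, 1]-ish units."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    if cls == 0:  # BG: faint smooth mottling
        return 0.3 * gaussian_filter(rng.standard_normal(shape), 4.0)
    if cls == 1:  # NL: high-frequency speckle (individual plants)
        return rng.standard_normal(shape)
    if cls == 2:  # HL: oblique medium-frequency streaks
        phase = 2.0 * np.pi * rng.random()
        streak = np.sin(2.0 * np.pi * (xx + yy) / 7.0 + phase)
        return 0.8 * streak + 0.3 * rng.standard_normal(shape)
    # L: smooth directional streaks of flattened stems
    phase = 2.0 * np.pi * rng.random()
    streak = np.sin(2.0 * np.pi * (xx - yy) / 18.0 + phase)
    return 0.9 * gaussian_filter(streak + 0.2 * rng.standard_normal(shape), 1.5)


_TEXTURE_GAIN = np.array([6.0, 18.0, 14.0, 12.0])


def generate_scene(params: SceneParams) -> LodgingScene:
    """Render one seeded scene (RGB image + label mask)."""
    h, w = params.size
    rng = np.random.default_rng(params.seed)

    raw = rng.standard_normal((h, w))
    fld = gaussian_filter(raw, params.blob_scale)
    cum = np.cumsum(params.class_prior)[:-1]
    thresholds = np.quantile(fld, cum)
    mask = np.digitize(fld, thresholds).astype(np.uint8)

    image = _BASE_COLORS[mask].astype(float)
    for cls in range(4):
        sel = mask == cls
        if not np.any(sel):
            continue
        tex = _texture(cls, (h, w), rng)
        image[sel] += (_TEXTURE_GAIN[cls] * tex[sel])[:, None]
    image += rng.normal(0.0, params.noise_sigma, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return LodgingScene.from_arrays(image, mask)


def save_scene(scene: LodgingScene, image_path: Path, mask_path: Path) -> None:
    Image.fromarray(scene.image, mode="RGB").save(image_path)
    mask_img = Image.fromarray(scene.mask, mode="P")
    mask_img.putpalette(_MASK_PALETTE)
    mask_img.save(mask_path)


def load_scene(image_path: Path, mask_path: Path) -> LodgingScene:
    image = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.uint8)
    mask = np.asarray(Image.open(mask_path), dtype=np.uint8)
    return LodgingScene.from_arrays(image, mask)


def generate_dataset(
    n_scenes: int,
    params: SceneParams,
    out_dir: Path | str,
    split: float = 0.75,
) -> dict:
    """Write n_scenes PNG pairs plus a train/val manifest; returns the manifest.

    The split is by scene: round(split * n) scenes go to training, assignment
    shuffled deterministically by the dataset seed.  Per-scene randomness uses
    independent child seeds of params.seed.
    """
    if n_scenes < 4:
        raise ValueError("need at least 4 scenes for a meaningful split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_train = round(split * n_scenes)
    order = np.random.default_rng(params.seed).permutation(n_scenes)
    train_set = set(int(i) for i in order[:n_train])

    entries = []
    for i in range(n_scenes):
        scene_params = SceneParams(
            size=params.size,
            class_prior=params.class_prior,
            blob_scale=params.blob_scale,
            noise_sigma=params.noise_sigma,
            seed=int(np.random.default_rng([params.seed, i]).integers(2**31)),
        )
        scene = generate_scene(scene_params)
        image_name = f"scene_{i:04d}.png"
        mask_name = f"scene_{i:04d}_mask.png"
        save_scene(scene, out_dir / image_name, out_dir / mask_name)
        entries.append(
            {
                "image": image_name,
                "mask": mask_name,
                "split": "train" if i in train_set else "val",
                "class_fractions": list(scene.class_fractions),
            }
        )
    manifest = {
        "n_scenes": n_scenes,
        "size": list(params.size),
        "class_prior": list(params.class_prior),
        "seed": params.seed,
        "split": split,
        "scenes": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(data_dir: Path | str) -> tuple[list[LodgingScene], list[LodgingScene]]:
    """Read a generated dataset back as (train scenes, val scenes)."""
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    train, val = [], []
    for entry in manifest["scenes"]:
        scene = load_scene(data_dir / entry["image"], data_dir / entry["mask"])
        (train if entry["split"] == "train" else val).append(scene)
    return train, val


def tile_and_rescale(
    image: np.ndarray,
    mask: np.ndarray,
    tile_sizes: tuple[int, ...] = (2048, 1024, 512),
    out_size: int = 512,
) -> list[LodgingScene]:
    """Cut non-overlapping tiles at each size and rescale all to out_size.

    Larger tiles are downscaled with bilinear interpolation for the image and
    nearest-neighbor for the mask (labels stay in {0..3}).  Tile sizes larger
    than the input are skipped with a warning.
    """
    h, w = mask.shape
    scenes: list[LodgingScene] = []
    for ts in sorted(set(tile_sizes), reverse=True):
        if ts > h or ts > w:
            warnings.warn(f"tile size {ts} exceeds image size ({h},{w}); skipped")
            continue
        for r in range(h // ts):
            for c in range(w // ts):
                img_t = image[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts]
                msk_t = mask[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts]
                if ts != out_size:
                    img_t = np.asarray(
                        Image.fromarray(img_t).resize((out_size, out_size), Image.BILINEAR)
                    )
                    msk_t = np.asarray(
                        Image.fromarray(msk_t).resize((out_size, out_size), Image.NEAREST)
                    )
                scenes.append(LodgingScene.from_arrays(img_t, msk_t))
    return scenes


def rasterize_labelme(annotation: dict, size: tuple[int, int]) -> np.ndarray:
    """Rasterize polygon annotations (Labelme-style JSON) to a label mask.

    ``annotation["shapes"]`` is a list of {"label": name, "points": [[x, y]..]};
    later polygons overwrite earlier ones; unannotated pixels are BG.
    """
    h, w = size
    img = Image.new("L", (w, h), 0)
    draw = ImageDraw.Draw(img)
    for shape in annotation.get("shapes", []):
        label = shape["label"]
        if label not in CLASS_NAMES:
            raise ValueError(
                f"unknown class label {label!r}; expected one of {list(CLASS_NAMES)}"
            )
        cls = CLASS_NAMES.index(label)
        points = [(float(x), float(y)) for x, y in shape["points"]]
        draw.polygon(points, fill=cls)
    return np.asarray(img, dtype=np.uint8)
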