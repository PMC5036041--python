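"""Six-step colony recognition from raw phase-contrast images.

The pipeline mirrors a standard colony-recognition recipe for tiled
phase-contrast well images:

1. flatten the background (local median estimate, restored to a fixed
   grey level);
2. per-pixel texture recognition with a trained classifier, choosing
   the best of ``n_candidates`` randomized training configurations;
3. noise reduction -- remove connected components smaller than
   ``noise_min_px`` (default 2,046 px);
4. object filling -- fill enclosed background holes up to
   ``fill_hole_px`` (default 30 px);
5. manual object cleansing -- exposed as an exclusion list of labels,
   never automated;
6. size gate -- keep components strictly larger than ``colony_min_px``
   (default 30,000 px), then optionally restrict to mature colonies
   with equivalent-circle diameter > 1 mm.

Conventions: raster row/column coordinates, 0-based, origin top-left;
foreground components are 8-connected, holes 4-connected; areas in
pixels, physical lengths via ``um_per_px``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import rank
from skimage.measure import block_reduce
from skimage.morphology import disk
from sklearn.linear_model import LogisticRegression

__all__ = [
    "SegmentationConfig",
    "ColonyObject",
    "TextureModel",
    "flatten_background",
    "texture_features",
    "train_texture_model",
    "recognize",
    "reduce_noise",
    "fill_objects",
    "extract_colonies",
    "select_mature",
    "segment_image",
]

_FG_STRUCTURE = np.ones((3, 3), dtype=bool)  # 8-connected foreground
_HOLE_STRUCTURE = np.array(
    [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool
)  # 4-connected holes


@dataclass(frozen=True)
class SegmentationConfig:
    flatten_kernel_px: int = 7
    flatten_grey: int = 90
    noise_min_px: int = 2046
    fill_hole_px: int = 30
    colony_min_px: int = 30000
    mature_min_diameter_um: float = 1000.0
    probability_threshold: float = 0.5

    def validate(self) -> None:
        for name in (
            "flatten_kernel_px",
            "flatten_grey",
            "noise_min_px",
            "fill_hole_px",
            "colony_min_px",
            "mature_min_diameter_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.fill_hole_px < self.noise_min_px < self.colony_min_px:
            raise ValueError(
                "expected fill_hole_px < noise_min_px < colony_min_px"
            )


@dataclass
class ColonyObject:
    """One segmented colony in full-frame coordinates."""

    label: int
    mask: np.ndarray
    area_px: int
    centroid_px: tuple[float, float]
    source_image_id: str = ""

    def equivalent_diameter_um(self, um_per_px: float) -> float:
        return 2.0 * np.sqrt(self.area_px * um_per_px**2 / np.pi)

    def touches_border(self) -> bool:
        m = self.mask
        return bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())


def flatten_background(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Step 1: subtract a local median background, restore a fixed grey.

    The local median over a ``flatten_kernel_px`` square tracks slowly
    varying illumination; the output is ``image - background + grey``
    clipped to [0, 255], so a constant image maps to the configured grey
    level and ramps varying slower than the kernel scale are removed.
    """
    if image.ndim != 2:
        raise ValueError("expected a single-channel image")
    k = cfg.flatten_kernel_px
    if k > min(image.shape):
        raise ValueError("flatten kernel larger than image")
    background = ndimage.median_filter(image.astype(np.int16), size=k, mode="reflect")
    out = image.astype(np.int16) - background + int(cfg.flatten_grey)
    return np.clip(out, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Texture recognition
# ---------------------------------------------------------------------------

_FEATURE_SCALES = (5, 15)  # window sizes, px
FEATURE_NAMES = tuple(
    f"{stat}_w{w}"
    for w in _FEATURE_SCALES
    for stat in ("local_mean", "local_sd", "gradient")
) + ("entropy_r4_half", "intensity")


def texture_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel texture feature stack, shape (H, W, n_features).

    Local mean / SD and smoothed gradient magnitude at two window
    scales, a half-resolution local entropy, and the raw intensity.
    All windows are centro-symmetric, so a 180 deg image rotation
    rotates the feature planes.
    """
    img = image.astype(np.float64)
    planes = []
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    grad = np.hypot(gy, gx)
    for w in _FEATURE_SCALES:
        mean = ndimage.uniform_filter(img, size=w, mode="reflect")
        sq = ndimage.uniform_filter(img * img, size=w, mode="reflect")
        sd = np.sqrt(np.clip(sq - mean * mean, 0.0, None))
        gmean = ndimage.uniform_filter(grad, size=w, mode="reflect")
        planes.extend([mean, sd, gmean])
    # Local entropy on a 2x2-block-averaged image (cheap, then upsampled
    # by pixel replication; for even image sizes this commutes with a
    # half-turn rotation).
    small = block_reduce(image, (2, 2), np.mean).astype(np.uint8)
    ent = rank.entropy(small, disk(4)).astype(np.float64)
    ent_full = np.kron(ent, np.ones((2, 2)))[: img.shape[0], : img.shape[1]]
    planes.append(ent_full)
    planes.append(img)
    return np.stack(planes, axis=-1)


@dataclass
class TextureModel:
    """Best-of-``n_candidates`` per-pixel texture classifier."""

    feature_names: tuple[str, ...]
    feature_subset: tuple[int, ...]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    classifier: LogisticRegression
    training_report: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Foreground probability per pixel for a (H, W, F) stack."""
        h, w, _ = features.shape
        x = features[..., self.feature_subset].reshape(h * w, -1)
        x = (x - self.scaler_mean) / self.scaler_sd
        p = self.classifier.predict_proba(x)[:, 1]
        return p.reshape(h, w)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TextureModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TextureModel):
            raise TypeError("file does not contain a TextureModel")
        return model


def _sample_training_pixels(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    cfg: SegmentationConfig,
    per_class_per_image: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for image, mask in zip(images, masks):
        flat = flatten_background(image, cfg)
        feats = texture_features(flat)
        mask = mask.astype(bool)
        for cls, sel in ((1, mask), (0, ~mask)):
            idx = np.flatnonzero(sel.ravel())
            if idx.size == 0:
                continue
            take = min(per_class_per_image, idx.size)
            chosen = rng.choice(idx, size=take, replace=False)
            xs.append(feats.reshape(-1, feats.shape[-1])[chosen])
            ys.append(np.full(take, cls, dtype=np.int8))
    if not xs:
        raise ValueError("no training pixels")
    return np.concatenate(xs), np.concatenate(ys)


def train_texture_model(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    n_candidates: int = 50,
    seed: int = 0,
    cfg: SegmentationConfig | None = None,
    per_class_per_image: int = 2500,
) -> TextureModel:
    """Step 2 training: pick the best of ``n_candidates`` randomized fits.

    Each candidate draws a random feature subset and regularization
    strength for a logistic per-pixel classifier; candidates are scored
    on a held-out third of the sampled pixels and the highest held-out
    accuracy wins (first in candidate order on ties).  Deterministic
    given ``seed``.
    """
    cfg = cfg or SegmentationConfig()
    if len(images) != len(masks) or not images:
        raise ValueError("images and masks must be aligned and non-empty")
    rng = np.random.default_rng(np.random.PCG64(seed))
    x, y = _sample_training_pixels(images, masks, cfg, per_class_per_image, rng)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    n = len(y)
    perm = rng.permutation(n)
    split = int(n * 2 / 3)
    train_idx, val_idx = perm[:split], perm[split:]
    n_features = x.shape[1]

    best = None
    for cand in range(n_candidates):
        size = int(rng.integers(3, n_features + 1))
        subset = tuple(sorted(rng.choice(n_features, size=size, replace=False)))
        c_reg = 10.0 ** rng.uniform(-2, 2)
        xt = x[train_idx][:, subset]
        mu = xt.mean(axis=0)
        sd = xt.std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(C=c_reg, max_iter=300)
        clf.fit((xt - mu) / sd, y[train_idx])
        xv = (x[val_idx][:, subset] - mu) / sd
        acc = float(np.mean(clf.predict(xv) == y[val_idx]))
        if best is None or acc > best[0]:
            best = (acc, cand, subset, mu, sd, c_reg, clf)

    acc, cand, subset, mu, sd, c_reg, clf = best
    return TextureModel(
        feature_names=FEATURE_NAMES,
        feature_subset=subset,
        scaler_mean=mu,
        scaler_sd=sd,
        classifier=clf,
        training_report={
            "held_out_accuracy": acc,
            "chosen_candidate": cand,
            "n_candidates": n_candidates,
            "C": c_reg,
            "n_training_pixels": int(split),
            "n_validation_pixels": int(n - split),
        },
    )


def recognize(
    image: np.ndarray,
    model: TextureModel,
    cfg: SegmentationConfig | None = None,
    flattened: bool = False,
) -> np.ndarray:
    """Step 2: per-pixel foreground decision at probability 0.5."""
    cfg = cfg or SegmentationConfig()
    flat = image if flattened else flatten_background(image, cfg)
    prob = model.predict_proba(texture_features(flat))
    return prob > cfg.probability_threshold


def reduce_noise(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Step 3: drop 8-connected components smaller than ``noise_min_px``.

    A component of exactly ``noise_min_px`` pixels survives (the stated
    setting is the smallest surviving size).
    """
    labels, n = ndimage.label(mask, structure=_FG_STRUCTURE)
    if n == 0:
        return mask.astype(bool).copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= cfg.noise_min_px
    keep[0] = False
    return keep[labels]


def fill_objects(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Step 4: fill enclosed holes of area <= ``fill_hole_px``."""
    mask = mask.astype(bool)
    inv_labels, n = ndimage.label(~mask, structure=_HOLE_STRUCTURE)
    if n == 0:
        return mask.copy()
    areas = np.bincount(inv_labels.ravel())
    border = np.unique(
        np.concatenate(
            [
                inv_labels[0],
                inv_labels[-1],
                inv_labels[:, 0],
                inv_labels[:, -1],
            ]
        )
    )
    fill = np.zeros(n + 1, dtype=bool)
    fill[1:] = areas[1:] <= cfg.fill_hole_px
    fill[border] = False  # background reaching the frame edge is not a hole
    return mask | fill[inv_labels]


def extract_colonies(
    mask: np.ndarray,
    cfg: SegmentationConfig,
    image_id: str = "",
    exclude_labels: Sequence[int] = (),
) -> list[ColonyObject]:
    """Steps 5+6: label objects, apply the manual exclusion list, and keep
    components strictly larger than ``colony_min_px``.

    Labels follow raster-scan order of each component's first pixel.
    ``exclude_labels`` reproduces manual object cleansing and refers to
    the labels assigned here.
    """
    labels, n = ndimage.label(mask, structure=_FG_STRUCTURE)
    out: list[ColonyObject] = []
    if n == 0:
        return out
    areas = np.bincount(labels.ravel())
    centroids = ndimage.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    excluded = set(int(e) for e in exclude_labels)
    for lab in range(1, n + 1):
        if lab in excluded:
            continue
        if areas[lab] <= cfg.colony_min_px:  # strict > gate
            continue
        out.append(
            ColonyObject(
                label=lab,
                mask=labels == lab,
                area_px=int(areas[lab]),
                centroid_px=tuple(float(c) for c in centroids[lab - 1]),
                source_image_id=image_id,
            )
        )
    return out


def select_mature(
    colonies: Sequence[ColonyObject],
    um_per_px: float,
    cfg: SegmentationConfig,
) -> list[ColonyObject]:
    """Keep colonies with equivalent-circle diameter strictly > 1 mm."""
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    return [
        c
        for c in colonies
        if c.equivalent_diameter_um(um_per_px) > cfg.mature_min_diameter_um
    ]


def segment_image(
    image: np.ndarray,
    model: TextureModel,
    cfg: SegmentationConfig | None = None,
    image_id: str = "",
    um_per_px: float = 2.0,
    exclude_labels: Sequence[int] = (),
    mature_only: bool = True,
) -> list[ColonyObject]:
    """Run the full recognition pipeline on one image."""
    cfg = cfg or SegmentationConfig()
    cfg.validate()
    fg = recognize(image, model, cfg)
    fg = reduce_noise(fg, cfg)
    fg = fill_objects(fg, cfg)
    colonies = extract_colonies(fg, cfg, image_id, exclude_labels)
    if mature_only:
        colonies = select_mature(colonies, um_per_px, cfg)
    return colonies
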