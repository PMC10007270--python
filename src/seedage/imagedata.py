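"""Image I/O, seed isolation, and the synthetic seed-image generator.

Images are numpy ``(H, W, 3)`` uint8 arrays in RGB channel order; masks are
boolean ``(H, W)`` arrays.  A dataset is a directory of per-seed PNGs plus a
CSV manifest (sample_id, image_path, variety, harvest_year, split).

The synthetic generator stands in for a photographed single-seed dataset of
six rice varieties (Akitakomachi, Fusaotome, Hatsuboshi, Koshihikari,
Okiniiri and Yang Dao-8) harvested in 2012, 2016 or 2020, with two of the
sixteen (variety, year) cells absent.  Each rendered seed is a rotated
ellipse whose length and aspect ratio are variety-specific (Yang Dao-8 is
the most elongated), on a contrasting uniform background; harvest age shows
up as pericarp darkening and multiplicative speckle texture, mirroring how
aging darkens and roughens real seed coats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import draw as skdraw
from skimage import measure, morphology

__all__ = [
    "VARIETIES",
    "YEARS",
    "EXCLUDED_CLASSES",
    "TABLE_COUNTS",
    "SeedCrop",
    "SyntheticSpec",
    "EmptyForegroundError",
    "remove_background",
    "crop_seed",
    "generate_seed_image",
    "generate_dataset",
    "load_image",
    "save_image",
    "load_manifest",
    "save_manifest",
    "valid_classes",
]

VARIETIES = (
    "Akitakomachi",
    "Fusaotome",
    "Hatsuboshi",
    "Koshihikari",
    "Okiniiri",
    "YangDao8",
)
YEARS = (2012, 2016, 2020)
# two (variety, year) combinations were never collected
EXCLUDED_CLASSES = frozenset({("Okiniiri", 2020), ("YangDao8", 2016)})

# per-class sample counts of the emulated dataset
TABLE_COUNTS: dict[tuple[str, int], int] = {
    ("Akitakomachi", 2012): 306, ("Akitakomachi", 2016): 279, ("Akitakomachi", 2020): 366,
    ("Fusaotome", 2012): 325, ("Fusaotome", 2016): 416, ("Fusaotome", 2020): 482,
    ("Hatsuboshi", 2012): 376, ("Hatsuboshi", 2016): 495, ("Hatsuboshi", 2020): 499,
    ("Koshihikari", 2012): 340, ("Koshihikari", 2016): 348, ("Koshihikari", 2020): 509,
    ("Okiniiri", 2012): 345, ("Okiniiri", 2016): 292,
    ("YangDao8", 2012): 343, ("YangDao8", 2020): 261,
}

MANIFEST_COLUMNS = ["sample_id", "image_path", "variety", "harvest_year", "split"]


def valid_classes() -> list[tuple[str, int]]:
    """All (variety, year) classes, in deterministic order."""
    return [
        (v, y) for v in VARIETIES for y in YEARS if (v, y) not in EXCLUDED_CLASSES
    ]


class EmptyForegroundError(ValueError):
    pass


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("image smaller than 8x8")
    if image.dtype != np.uint8:
        raise ValueError("expected uint8 intensities in [0, 255]")
    return image


@dataclass
class SeedCrop:
    """A tight crop around one isolated seed plus its binary mask."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) bool, True = seed pixel

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3 \
                or self.image.dtype != np.uint8:
            raise ValueError("crop image must be (H, W, 3) uint8")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask/image shape mismatch")
        if int(self.mask.sum()) < 16:
            raise ValueError("foreground has fewer than 16 pixels")
        if measure.label(self.mask, connectivity=2).max() != 1:
            raise ValueError("mask must have exactly one connected component")


# ---------------------------------------------------------------------------
# background removal and cropping
# ---------------------------------------------------------------------------

def remove_background(
    image: np.ndarray, threshold: float = 40.0, closing_radius: int = 2
) -> np.ndarray:
    """Segment the seed by color distance from the border background.

    The background color is estimated as the per-channel median of the
    one-pixel border frame; pixels farther than ``threshold`` (Euclidean
    RGB distance) are foreground candidates.  The largest connected
    component is kept and closed with a disk of radius ``closing_radius``.
    """
    image = _check_image(image)
    border = np.concatenate([
        image[0, :], image[-1, :], image[:, 0], image[:, -1]
    ]).astype(np.float64)
    bg = np.median(border, axis=0)
    dist = np.sqrt(((image.astype(np.float64) - bg) ** 2).sum(axis=2))
    fg = dist > threshold
    if not fg.any():
        raise EmptyForegroundError(
            f"no foreground pixel beyond color-distance threshold {threshold}"
        )
    labels = measure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    return mask.astype(bool)


def crop_seed(image: np.ndarray, mask: np.ndarray, margin: int = 2) -> SeedCrop:
    """Tight bounding-box crop of image and mask with a clipped margin."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyForegroundError("cannot crop an empty mask")
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        warnings.warn("mask has multiple components; keeping the largest")
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = labels == largest
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(rows[0] - margin, 0)
    r1 = min(rows[-1] + margin + 1, mask.shape[0])
    c0 = max(cols[0] - margin, 0)
    c1 = min(cols[-1] + margin + 1, mask.shape[1])
    return SeedCrop(image[r0:r1, c0:c1], mask[r0:r1, c0:c1])


# ---------------------------------------------------------------------------
# synthetic generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic seed-image generator.

    Shape (seed length in px and major/minor aspect ratio) separates the
    varieties; darkening and speckle amplitude separate the harvest ages.
    ``darkening`` multiplies foreground luminance by (1 - factor), so older
    seeds render darker; ``speckle`` is the relative sd of the shared
    multiplicative per-pixel texture noise.
    """

    canvas_size: int = 128  # post-crop resolution of the source data is not
    #                         documented anywhere; 128 px is a working guess
    seed_length: dict = field(default_factory=lambda: {
        "Akitakomachi": 52.0, "Fusaotome": 56.0, "Hatsuboshi": 50.0,
        "Koshihikari": 60.0, "Okiniiri": 55.0, "YangDao8": 72.0,
    })
    aspect_ratio: dict = field(default_factory=lambda: {
        "Akitakomachi": 1.90, "Fusaotome": 2.05, "Hatsuboshi": 2.20,
        "Koshihikari": 1.75, "Okiniiri": 2.35, "YangDao8": 3.10,
    })
    length_jitter: float = 0.05   # relative sd of per-seed length
    aspect_jitter: float = 0.05   # relative sd of per-seed aspect ratio
    darkening: dict = field(default_factory=lambda: {
        2012: 0.30, 2016: 0.15, 2020: 0.0,
    })
    speckle: dict = field(default_factory=lambda: {
        2012: 0.14, 2016: 0.08, 2020: 0.03,
    })
    hue_shift_deg: dict = field(default_factory=lambda: {
        2012: 0.0, 2016: 0.0, 2020: 0.0,
    })
    base_color: tuple = (180, 150, 110)     # tan pericarp
    background_color: tuple = (40, 70, 45)  # dark green belt
    counts: dict = field(default_factory=lambda: dict(TABLE_COUNTS))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for v in VARIETIES:
            if self.aspect_ratio[v] <= 1:
                raise ValueError("aspect ratio must be > 1")
        if not (0 <= self.length_jitter <= 1 and 0 <= self.aspect_jitter <= 1):
            raise ValueError("jitter fractions must lie in [0, 1]")
        for y, f in self.darkening.items():
            if not 0 <= f <= 1:
                raise ValueError(f"darkening factor for {y} outside [0, 1]")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative sample count")

    @classmethod
    def easy(cls, rng_seed: int = 0) -> "SyntheticSpec":
        """Wide class separation: nearly disjoint shapes and age effects."""
        return cls(
            seed_length={
                "Akitakomachi": 46.0, "Fusaotome": 52.0, "Hatsuboshi": 58.0,
                "Koshihikari": 64.0, "Okiniiri": 70.0, "YangDao8": 80.0,
            },
            aspect_ratio={
                "Akitakomachi": 1.50, "Fusaotome": 1.90, "Hatsuboshi": 2.30,
                "Koshihikari": 2.70, "Okiniiri": 3.20, "YangDao8": 4.00,
            },
            length_jitter=0.015,
            aspect_jitter=0.015,
            darkening={2012: 0.40, 2016: 0.20, 2020: 0.0},
            speckle={2012: 0.20, 2016: 0.10, 2020: 0.02},
            rng_seed=rng_seed,
        )


def _shift_hue(rgb: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate the hue of a single float RGB color (0-255 scale)."""
    if degrees == 0.0:
        return rgb
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(rgb[None, None, :] / 255.0)
    hsv[..., 0] = (hsv[..., 0] + degrees / 360.0) % 1.0
    return hsv2rgb(hsv)[0, 0] * 255.0


def generate_seed_image(
    spec: SyntheticSpec, variety: str, harvest_year: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Render one seed image; returns (RGB image, ground-truth mask).

    Deterministic given the generator state: the same ``rng`` state always
    yields bit-identical output.
    """
    if (variety, harvest_year) in EXCLUDED_CLASSES or variety not in VARIETIES \
            or harvest_year not in YEARS:
        raise ValueError(f"invalid class ({variety}, {harvest_year})")
    rng = np.random.default_rng(rng)
    n = spec.canvas_size

    length = spec.seed_length[variety] * (
        1.0 + spec.length_jitter * np.clip(rng.standard_normal(), -2.5, 2.5)
    )
    aspect = spec.aspect_ratio[variety] * (
        1.0 + spec.aspect_jitter * np.clip(rng.standard_normal(), -2.5, 2.5)
    )
    aspect = max(aspect, 1.05)
    a = min(length / 2.0, n / 2.0 - 4)  # semi-major, kept inside the canvas
    b = max(a / aspect, 2.0)
    angle = rng.uniform(0.0, np.pi)
    cy = n / 2.0 + rng.uniform(-4.0, 4.0)
    cx = n / 2.0 + rng.uniform(-4.0, 4.0)

    rr, cc = skdraw.ellipse(cy, cx, b, a, shape=(n, n), rotation=angle)
    mask = np.zeros((n, n), dtype=bool)
    mask[rr, cc] = True

    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background_color, dtype=np.float64)
    color = _shift_hue(
        np.asarray(spec.base_color, dtype=np.float64),
        spec.hue_shift_deg[harvest_year],
    )
    # shared multiplicative speckle (clipped so channel clipping stays
    # symmetric and the configured darkening survives as the mean-luminance
    # ratio between ages)
    amp = spec.speckle[harvest_year]
    texture = np.clip(1.0 + amp * rng.standard_normal(mask.sum()), 0.6, 1.4)
    shade = 1.0 - spec.darkening[harvest_year]
    img[mask] = color[None, :] * texture[:, None] * shade
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def _scaled_count(count: int, scale: float) -> int:
    return int(np.floor(count * scale + 0.5))  # round half away from zero


def generate_dataset(
    spec: SyntheticSpec,
    out_dir,
    scale: float = 1.0,
    write_masks: bool = False,
    jpeg_quality: int | None = None,
) -> pd.DataFrame:
    """Write per-seed images plus a CSV manifest; returns the manifest.

    Per-class counts are ``round(spec.counts * scale)`` (half away from
    zero).  Images are written losslessly as PNG unless ``jpeg_quality``
    is set, which re-compresses to JPEG for realism testing.  Reproducible:
    the same spec and rng_seed give identical manifest and image bytes.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    if write_masks:
        (out_dir / "masks").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    ext = "jpg" if jpeg_quality is not None else "png"
    records = []
    for variety, year in valid_classes():
        count = _scaled_count(spec.counts.get((variety, year), 0), scale)
        for i in range(count):
            image, mask = generate_seed_image(spec, variety, year, rng)
            sample_id = f"{variety}_{year}_{i:04d}"
            rel = f"images/{sample_id}.{ext}"
            save_image(image, out_dir / rel, jpeg_quality=jpeg_quality)
            if write_masks:
                Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(
                    out_dir / "masks" / f"{sample_id}.png"
                )
            records.append((sample_id, rel, variety, year, "unassigned"))
    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return _check_image(np.asarray(im.convert("RGB")))
    except OSError as exc:
        raise OSError(f"failed to read image {path}: {exc}") from exc


def save_image(image: np.ndarray, path, jpeg_quality: int | None = None) -> None:
    path = Path(path)
    try:
        im = Image.fromarray(_check_image(image), mode="RGB")
        if jpeg_quality is not None:
            im.save(path, quality=jpeg_quality)
        else:
            im.save(path)
    except OSError as exc:
        raise OSError(f"failed to write image {path}: {exc}") from exc


def load_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    if list(manifest.columns) != MANIFEST_COLUMNS:
        raise ValueError(f"manifest columns must be {MANIFEST_COLUMNS}")
    if manifest["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids")
    bad = [
        (v, y) for v, y in zip(manifest["variety"], manifest["harvest_year"])
        if (v, y) in EXCLUDED_CLASSES or v not in VARIETIES or y not in YEARS
    ]
    if bad:
        raise ValueError(f"invalid (variety, year) classes present: {sorted(set(bad))[:3]}")
    return manifest


def save_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest).to_csv(path, index=False)


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "image_path": str,
                                  "variety": str, "split": str})
    df["harvest_year"] = df["harvest_year"].astype(int)
    return validate_manifest(df)


def with_scaled_counts(spec: SyntheticSpec, scale: float) -> SyntheticSpec:
    """A copy of ``spec`` with all class counts pre-scaled."""
    counts = {k: _scaled_count(v, scale) for k, v in spec.counts.items()}
    return replace(spec, counts=counts)
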