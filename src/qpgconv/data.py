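"""Synthetic organ/tumor segmentation samples and dataset I/O.

Real abdominal CT slices for kidney-tumor work arrive as single-channel
images with a bright, roughly elliptical organ on a darker background and a
smaller, irregular, usually hypodense tumor nested inside the organ.  The
generator emulates that contract — and only that contract — so the training
and metric machinery can be exercised without any download: each sample is
a smooth elliptical organ blob with intensity contrast over a noisy
background, plus an irregular (perturbed-boundary) tumor blob strictly
inside the organ.  Geometry keeps the organ fully in frame with an area
fraction between roughly 6% and 25% of the image.

The organ task uses full frames; the tumor task crops the tight bounding
box of organ ∪ tumor and resizes back, mimicking the ROI-cropping
preprocessing used for tumor slices.  Splits follow the 9:1 convention:
the first floor(0.9 n) samples train, the rest test.

Everything is deterministic per seed: the same seed reproduces a sample
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage.filters import gaussian
from skimage.transform import resize

__all__ = ["SegmentationSample", "DatasetManifest", "generate_sample",
           "build_dataset", "crop_to_roi", "dataset_arrays",
           "save_sample_npz", "load_sample_npz",
           "save_sample_png", "load_sample_png",
           "save_manifest", "load_manifest"]


@dataclass(frozen=True)
class SegmentationSample:
    """One image with nested binary organ and tumor masks."""

    image: np.ndarray = field(repr=False)
    organ_mask: np.ndarray = field(repr=False)
    tumor_mask: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self):
        img = np.asarray(self.image, dtype=np.float64)
        organ = np.asarray(self.organ_mask).astype(bool)
        tumor = np.asarray(self.tumor_mask).astype(bool)
        if not (img.shape == organ.shape == tumor.shape) or img.ndim != 2:
            raise ValueError("image and masks must share one 2-D shape")
        if np.any(tumor & ~organ):
            raise ValueError("tumor mask must be contained in the organ mask")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "organ_mask", organ)
        object.__setattr__(self, "tumor_mask", tumor)

    def mask_for(self, task: str) -> np.ndarray:
        if task == "organ":
            return self.organ_mask
        if task == "tumor":
            return self.tumor_mask
        raise ValueError(f"unknown task {task!r}")


@dataclass(frozen=True)
class DatasetManifest:
    n_samples: int
    size: int = 32
    seed: int = 0
    task: str = "organ"
    noise_sigma: float = 0.03
    split_ratio: float = 0.9

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples for a 9:1 split")
        if self.size < 16:
            raise ValueError("image size must be at least 16")
        if self.task not in ("organ", "tumor"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def n_train(self) -> int:
        return int(self.split_ratio * self.n_samples)

    @property
    def n_test(self) -> int:
        return self.n_samples - self.n_train


def generate_sample(seed: int, size: int = 32,
                    noise_sigma: float = 0.03) -> SegmentationSample:
    """Deterministically generate one organ/tumor sample.

    The organ is an ellipse with random center (within the central band so
    it never clips the frame), semi-axes 0.14-0.28 of the image side, and
    random orientation.  The tumor boundary is a base circle in the organ's
    ellipse coordinates, modulated by low-order angular harmonics and
    intersected with the organ.  Intensities: dark background, bright organ,
    hypodense tumor, mild illumination ramp, light smoothing, then i.i.d.
    Gaussian pixel noise of the configured sigma, clipped to [0, 1].
    """
    if size < 16:
        raise ValueError("image size must be at least 16")
    rng = np.random.default_rng(seed)

    cx, cy = rng.uniform(0.38, 0.62, size=2) * size
    a = rng.uniform(0.14, 0.28) * size
    b = rng.uniform(0.14, 0.28) * size
    phi = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size] + 0.5
    u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    organ = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    # tumor: irregular blob around a point well inside the ellipse
    tc_u = rng.uniform(-0.4, 0.4) * a
    tc_v = rng.uniform(-0.4, 0.4) * b
    radius = rng.uniform(0.3, 0.5) * min(a, b)
    amp = rng.uniform(-0.15, 0.15, size=3)
    phase = rng.uniform(0.0, 2 * np.pi, size=3)
    du, dv = u - tc_u, v - tc_v
    ang = np.arctan2(dv, du)
    wobble = 1.0 + sum(amp[m] * np.cos((m + 2) * ang + phase[m]) for m in range(3))
    tumor = (np.hypot(du, dv) <= radius * wobble) & organ
    if not tumor.any():
        # guarantee a nonempty tumor at coarse resolutions: mark the pixel
        # nearest the tumor center (it lies inside the organ by construction)
        flat = np.argmin(du ** 2 + dv ** 2)
        tumor = np.zeros_like(organ)
        tumor.flat[flat] = True
        tumor &= organ

    background = rng.uniform(0.20, 0.30)
    organ_level = rng.uniform(0.60, 0.75)
    tumor_level = organ_level + rng.uniform(-0.25, -0.10)
    gx, gy = rng.uniform(-0.05, 0.05, size=2)
    ramp = gx * (xx / size - 0.5) + gy * (yy / size - 0.5)
    clean = np.where(tumor, tumor_level, np.where(organ, organ_level, background))
    clean = gaussian(clean + ramp, sigma=0.7, preserve_range=True)
    image = clean
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=clean.shape)
    return SegmentationSample(image=np.clip(image, 0.0, 1.0),
                              organ_mask=organ, tumor_mask=tumor,
                              seed=int(seed))


def crop_to_roi(sample: SegmentationSample, size: int) -> SegmentationSample:
    """Crop the tight bounding box of organ ∪ tumor and resize to `size`.

    Image resizing is bilinear; masks use nearest-neighbour order and are
    re-binarized, preserving tumor ⊆ organ.
    """
    roi = sample.organ_mask | sample.tumor_mask
    rows = np.flatnonzero(roi.any(axis=1))
    cols = np.flatnonzero(roi.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    img = resize(sample.image[r0:r1, c0:c1], (size, size),
                 order=1, preserve_range=True, anti_aliasing=False)
    organ = resize(sample.organ_mask[r0:r1, c0:c1].astype(float), (size, size),
                   order=0, preserve_range=True) >= 0.5
    tumor = resize(sample.tumor_mask[r0:r1, c0:c1].astype(float), (size, size),
                   order=0, preserve_range=True) >= 0.5
    return SegmentationSample(image=np.clip(img, 0.0, 1.0),
                              organ_mask=organ, tumor_mask=tumor & organ,
                              seed=sample.seed)


def build_dataset(manifest: DatasetManifest):
    """Generate all samples and split them 9:1 (first block trains).

    Returns (train_samples, test_samples) as lists of SegmentationSample.
    For the tumor task each sample is ROI-cropped and resized first.
    """
    rng = np.random.default_rng(manifest.seed)
    seeds = rng.integers(0, 2 ** 31, size=manifest.n_samples)
    samples = [generate_sample(int(s), manifest.size, manifest.noise_sigma)
               for s in seeds]
    if manifest.task == "tumor":
        samples = [crop_to_roi(s, manifest.size) for s in samples]
    n_train = manifest.n_train
    return samples[:n_train], samples[n_train:]


def dataset_arrays(samples, task: str = "organ"):
    """Stack samples into (n, 1, H, W) image and mask arrays for training."""
    images = np.stack([s.image for s in samples])[:, None, :, :]
    masks = np.stack([s.mask_for(task) for s in samples]).astype(np.float64)
    return images, masks[:, None, :, :]


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def save_sample_npz(sample: SegmentationSample, path) -> None:
    np.savez(path, image=sample.image, organ_mask=sample.organ_mask,
             tumor_mask=sample.tumor_mask, seed=np.int64(sample.seed))


def load_sample_npz(path) -> SegmentationSample:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such sample archive: {path}")
    with np.load(path) as data:
        return SegmentationSample(image=data["image"],
                                  organ_mask=data["organ_mask"],
                                  tumor_mask=data["tumor_mask"],
                                  seed=int(data["seed"]))


def save_sample_png(sample: SegmentationSample, prefix) -> None:
    """Write prefix_image.png (8-bit grayscale) and 0/255 mask PNGs."""
    prefix = Path(prefix)
    img = np.round(np.clip(sample.image, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(f"{prefix}_image.png")
    for name, mask in (("organ", sample.organ_mask), ("tumor", sample.tumor_mask)):
        Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(
            f"{prefix}_{name}.png")


def load_sample_png(prefix, seed: int = 0) -> SegmentationSample:
    prefix = Path(prefix)
    paths = {k: Path(f"{prefix}_{k}.png") for k in ("image", "organ", "tumor")}
    for p in paths.values():
        if not p.exists():
            raise FileNotFoundError(f"missing PNG file: {p}")
    image = np.asarray(Image.open(paths["image"]), dtype=np.float64) / 255.0
    organ = np.asarray(Image.open(paths["organ"])) > 127
    tumor = np.asarray(Image.open(paths["tumor"])) > 127
    return SegmentationSample(image=image, organ_mask=organ,
                              tumor_mask=tumor, seed=seed)


def save_manifest(manifest: DatasetManifest, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "n_samples": manifest.n_samples, "size": manifest.size,
        "seed": manifest.seed, "task": manifest.task,
        "noise_sigma": manifest.noise_sigma,
        "split_ratio": manifest.split_ratio,
    }, sort_keys=False))


def load_manifest(path) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    raw = yaml.safe_load(path.read_text())
    return DatasetManifest(**raw)


def load_nifti_slices(path):  # pragma: no cover - optional adapter stub
    """Optional adapter for real CT volumes (NIfTI), not part of the core.

    Left as a documented stub: the package's testbed is the synthetic
    generator above, which requires no download.  Users with nibabel and a
    segmentation volume can adapt this entry point.
    """
    raise NotImplementedError(
        "NIfTI ingestion is an optional adapter; load volumes with nibabel "
        "and wrap slices in SegmentationSample objects")
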