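"""Seeded synthetic thoracic-slice generator with exact ground truth.

The phantom emulates the appearance the segmentation method relies on: a
bright elliptical body on a dark background, two dark elliptical lung
fields with bright vessel-like inclusions, and additive Gaussian noise.
Non-lung (abdomen-like) slices and corrupted coarse masks — emulating a
detector that bounds but does not hug the lung wall — complete the fixture
surface so every stage of the pipeline is testable without patient data.

Default intensities mimic 16-bit stored CT ordering (background 0, body
1100, lung 250, vessels 1000, noise sd 40) without claiming Hounsfield
accuracy; the body/lung contrast is kept at >= 4 noise sd, which is the
contrast assumption the boundary refinement relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import DegenerateOutputError, SpecError
from .imgdata import BinaryMask, CTSlice, write_mask

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "generate_phantom",
    "generate_nonlung_phantom",
    "corrupt_mask",
    "generate_classification_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic slice.

    Axes are ellipse semi-axes in pixels as (row, col); ``lung_offset`` is
    the lateral displacement of each lung centre from the body centre.
    """

    image_size: int = 256
    body_axes: tuple[float, float] = (100.0, 115.0)
    lung_axes: tuple[float, float] = (55.0, 32.0)
    lung_offset: float = 48.0
    mu_background: float = 0.0
    mu_body: float = 1100.0
    mu_lung: float = 250.0
    sigma_noise: float = 40.0
    n_vessels: int = 4
    vessel_intensity: float = 1000.0
    seed: int = 0

    @classmethod
    def scaled(cls, image_size: int, seed: int = 0, **overrides) -> "PhantomSpec":
        """Default geometry scaled proportionally to ``image_size``."""
        f = image_size / 256.0
        base = dict(
            image_size=image_size,
            body_axes=(100.0 * f, 115.0 * f),
            lung_axes=(55.0 * f, 32.0 * f),
            lung_offset=48.0 * f,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.image_size < 64:
            raise SpecError("image_size must be >= 64")
        if self.mu_body - self.mu_lung < 4.0 * self.sigma_noise:
            raise SpecError("body/lung contrast below 4 noise sd")
        c = self.image_size / 2.0
        if self.body_axes[0] >= c or self.body_axes[1] >= c:
            raise SpecError("body ellipse touches the image border")
        if (self.lung_offset + self.lung_axes[1] >= self.body_axes[1]
                or self.lung_axes[0] >= self.body_axes[0]):
            raise SpecError("lung ellipses extend outside the body")


@dataclass(frozen=True)
class CorruptionSpec:
    """How to degrade a ground-truth mask into a detector-like coarse mask."""

    mode: str = "erode"  # erode | dilate | shift | blocky
    magnitude: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("erode", "dilate", "shift", "blocky"):
            raise SpecError(f"unknown corruption mode {self.mode!r}")
        if self.magnitude < 1:
            raise SpecError("corruption magnitude must be >= 1")


def _ellipse_mask(size: int, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def _lung_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    c = spec.image_size / 2.0
    left = _ellipse_mask(spec.image_size, (c, c - spec.lung_offset), spec.lung_axes)
    right = _ellipse_mask(spec.image_size, (c, c + spec.lung_offset), spec.lung_axes)
    return left, right


def generate_phantom(spec: PhantomSpec) -> tuple[CTSlice, BinaryMask]:
    """Render one lung-bearing slice and its exact ground-truth mask.

    The ground truth is the union of the two lung ellipses; vessels are
    lung tissue and stay inside the mask. Bit-identical output for a
    given spec (the seed drives vessel placement and noise).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    c = size / 2.0

    body = _ellipse_mask(size, (c, c), spec.body_axes)
    left, right = _lung_masks(spec)
    lungs = left | right

    img = np.full((size, size), spec.mu_background, dtype=np.float64)
    img[body] = spec.mu_body
    img[lungs] = spec.mu_lung

    # vessels: small bright ellipses fully inside each lung field
    for lung_center_col in (c - spec.lung_offset, c + spec.lung_offset):
        for _ in range(spec.n_vessels):
            vr = rng.uniform(1.5, 3.5)
            vc = rng.uniform(1.5, 3.5)
            dr = rng.uniform(-0.6, 0.6) * spec.lung_axes[0]
            dc = rng.uniform(-0.6, 0.6) * spec.lung_axes[1]
            vessel = _ellipse_mask(size, (c + dr, lung_center_col + dc), (vr, vc))
            img[vessel & lungs] = spec.vessel_intensity

    if spec.sigma_noise > 0:
        img = img + rng.normal(0.0, spec.sigma_noise, img.shape)
        np.clip(img, 0.0, None, out=img)

    ct = CTSlice(pixels=img, source_id=f"phantom(seed={spec.seed})")
    return ct, BinaryMask(lungs.astype(np.uint8))


def generate_nonlung_phantom(spec: PhantomSpec) -> CTSlice:
    """Render an abdomen-like slice: body ellipse with no dark lung fields."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    c = size / 2.0

    body = _ellipse_mask(size, (c, c), spec.body_axes)
    img = np.full((size, size), spec.mu_background, dtype=np.float64)
    img[body] = spec.mu_body
    if spec.sigma_noise > 0:
        img = img + rng.normal(0.0, spec.sigma_noise, img.shape)
        np.clip(img, 0.0, None, out=img)
    return CTSlice(pixels=img, source_id=f"nonlung-phantom(seed={spec.seed})")


def corrupt_mask(gt: BinaryMask, c: CorruptionSpec) -> BinaryMask:
    """Degrade an exact mask the way a coarse detector would.

    erode/dilate use a disc of radius ``magnitude``; shift translates by
    (magnitude, magnitude) with zero fill; blocky replaces the shape with
    its filled bounding box eroded by ``magnitude``. Raises
    :class:`DegenerateOutputError` if the corruption empties the mask.
    """
    c.validate()
    if gt.area == 0:
        raise DegenerateOutputError("cannot corrupt an empty mask")
    m = gt.as_bool()
    if c.mode == "erode":
        out = ndi.binary_erosion(m, structure=disk(c.magnitude))
    elif c.mode == "dilate":
        out = ndi.binary_dilation(m, structure=disk(c.magnitude))
    elif c.mode == "shift":
        out = np.zeros_like(m)
        k = c.magnitude
        if k < m.shape[0] and k < m.shape[1]:
            out[k:, k:] = m[:-k, :-k]
    else:  # blocky
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        box = np.zeros_like(m)
        box[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1] = True
        out = ndi.binary_erosion(box, structure=disk(c.magnitude))
    if not out.any():
        raise DegenerateOutputError(f"corruption {c.mode}({c.magnitude}) emptied the mask")
    return BinaryMask(out.astype(np.uint8))


def generate_classification_dataset(
    n_lung: int,
    n_nonlung: int,
    spec: PhantomSpec | None = None,
) -> tuple[list[CTSlice], np.ndarray]:
    """Build a labelled slice set for the lung-presence gate.

    Geometry and intensities are jittered per slice from the spec seed, so
    the classes are realistic rather than pixel-identical; labels are 1
    for lung-bearing slices, 0 otherwise. Deterministic for a given spec.
    """
    if n_lung < 1 or n_nonlung < 1:
        raise SpecError("need at least one slice per class")
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)

    def jittered(seed: int) -> PhantomSpec:
        return replace(
            spec,
            body_axes=(spec.body_axes[0] * rng.uniform(0.9, 1.05),
                       spec.body_axes[1] * rng.uniform(0.9, 1.05)),
            lung_axes=(spec.lung_axes[0] * rng.uniform(0.8, 1.1),
                       spec.lung_axes[1] * rng.uniform(0.8, 1.1)),
            lung_offset=spec.lung_offset * rng.uniform(0.9, 1.1),
            mu_body=spec.mu_body * rng.uniform(0.95, 1.05),
            mu_lung=spec.mu_lung * rng.uniform(0.9, 1.1),
            seed=seed,
        )

    slices: list[CTSlice] = []
    labels = np.array([1] * n_lung + [0] * n_nonlung, dtype=int)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_lung + n_nonlung)
    for i in range(n_lung):
        ct, _ = generate_phantom(jittered(int(sub_seeds[i])))
        slices.append(ct)
    for i in range(n_lung, n_lung + n_nonlung):
        slices.append(generate_nonlung_phantom(jittered(int(sub_seeds[i]))))
    return slices, labels


def write_dataset(
    out_dir: str | Path,
    n_lung: int,
    n_nonlung: int,
    spec: PhantomSpec | None = None,
    with_masks: bool = True,
    corruption: CorruptionSpec | None = None,
) -> Path:
    """Emit a phantom set as 16-bit PNGs + mask PNGs + a CSV manifest.

    Returns the manifest path. Columns: path, label, seed, mask_path,
    coarse_path (empty where not applicable).
    """
    import imageio.v3 as iio
    import pandas as pd

    spec = spec or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_lung + n_nonlung)
    for i in range(n_lung + n_nonlung):
        label = 1 if i < n_lung else 0
        s = replace(spec, seed=int(sub_seeds[i]))
        name = f"slice_{i:04d}"
        img_path = out_dir / f"{name}.png"
        mask_path = ""
        coarse_path = ""
        if label:
            ct, gt = generate_phantom(s)
            if with_masks:
                write_mask(gt, out_dir / f"{name}_gt.png")
                mask_path = f"{name}_gt.png"
            if corruption is not None:
                coarse = corrupt_mask(gt, replace(corruption, seed=s.seed))
                write_mask(coarse, out_dir / f"{name}_coarse.png")
                coarse_path = f"{name}_coarse.png"
        else:
            ct = generate_nonlung_phantom(s)
        iio.imwrite(img_path, np.clip(ct.pixels, 0, 65535).astype(np.uint16))
        rows.append({"path": img_path.name, "label": label, "seed": s.seed,
                     "mask_path": mask_path, "coarse_path": coarse_path})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
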