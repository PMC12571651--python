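"""Dual-view radiograph preprocessing.

Window normalization of HU-valued arrays to 8-bit gray, bilinear resizing,
non-overlapping patchification, and seeded exact-count random masking.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "Radiograph",
    "PatchGrid",
    "PatchMask",
    "ViewPair",
    "window_normalize",
    "resize_bilinear",
    "patchify",
    "unpatchify",
    "sample_mask",
    "apply_mask",
    "mean_fill",
    "derive_mask_seed",
    "read_grayscale_png",
    "write_grayscale_png",
    "read_dicom",
    "save_masked_grid",
    "load_masked_grid",
]

VIEWS = ("frontal", "lateral")


@dataclass
class Radiograph:
    """A single-view 2-D intensity array, either HU-valued or 8-bit gray."""

    pixels: np.ndarray
    view: str = "frontal"
    units: str = "HU"  # "HU" or "gray8"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"pixels must be a nonempty 2-D array, "
                             f"got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.units not in ("HU", "gray8"):
            raise ValueError(f"units must be 'HU' or 'gray8', got {self.units!r}")


@dataclass
class PatchGrid:
    """Row-major patches of one image; patch j covers grid cell
    (j // cols, j % cols), top-left origin."""

    patches: np.ndarray  # (P, s*s)
    grid_shape: tuple[int, int]
    patch_side: int = 16

    def __post_init__(self):
        rows, cols = self.grid_shape
        if self.patches.shape != (rows * cols, self.patch_side**2):
            raise ValueError(
                f"patches shape {self.patches.shape} inconsistent with "
                f"grid {self.grid_shape} and patch side {self.patch_side}"
            )

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]


@dataclass
class PatchMask:
    """Binary retain/mask vector: 0 = masked, 1 = retained."""

    bits: np.ndarray
    rate: float
    seed: int

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0/1")

    @property
    def n_retained(self) -> int:
        return int(self.bits.sum())


@dataclass
class ViewPair:
    """One record: frontal + lateral radiographs and the paired report."""

    frontal: Radiograph
    lateral: Radiograph | None
    report: str
    record_id: str


def window_normalize(img: Radiograph, width: float = 1500.0,
                     level: float = -500.0) -> Radiograph:
    """Linearly map HU values in [level - width/2, level + width/2] to
    [0, 255], clipping outside the window; rounding is half-away-from-zero.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    if img.units != "HU":
        raise ValueError(f"window_normalize expects HU input, got {img.units}")
    lo = level - width / 2.0
    scaled = 255.0 * np.clip(img.pixels - lo, 0.0, width) / width
    out = np.floor(scaled + 0.5).astype(np.uint8)  # values are nonnegative
    return Radiograph(out, view=img.view, units="gray8")


def resize_bilinear(img: Radiograph, side: int = 224) -> Radiograph:
    """Bilinear resize to side×side (half-pixel centre convention)."""
    if min(img.pixels.shape) < 2:
        raise ValueError(f"source too small to resize: {img.pixels.shape}")
    out = _sk_resize(img.pixels.astype(float), (side, side), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return Radiograph(out, view=img.view, units=img.units)


def patchify(img: Radiograph | np.ndarray, patch_side: int = 16) -> PatchGrid:
    """Tile the image into non-overlapping patch_side² patches, row-major."""
    pixels = img.pixels if isinstance(img, Radiograph) else np.asarray(img)
    H, W = pixels.shape
    s = patch_side
    if H % s or W % s:
        raise ValueError(
            f"image dims {H}x{W} are not divisible by patch side {s}"
        )
    rows, cols = H // s, W // s
    patches = (
        pixels.reshape(rows, s, cols, s)
        .transpose(0, 2, 1, 3)
        .reshape(rows * cols, s * s)
    )
    return PatchGrid(patches=patches, grid_shape=(rows, cols), patch_side=s)


def unpatchify(grid: PatchGrid) -> np.ndarray:
    rows, cols = grid.grid_shape
    s = grid.patch_side
    return (
        grid.patches.reshape(rows, cols, s, s)
        .transpose(0, 2, 1, 3)
        .reshape(rows * s, cols * s)
    )


def sample_mask(P: int, rate: float, seed: int) -> PatchMask:
    """Mask exactly floor(rate*P) patches chosen uniformly without
    replacement; deterministic per (P, rate, seed)."""
    if not (0 <= rate < 1):
        raise ValueError(f"mask rate must lie in [0, 1), got {rate}")
    n_masked = int(np.floor(rate * P))
    rng = np.random.default_rng(seed)
    bits = np.ones(P, dtype=np.uint8)
    masked_idx = rng.choice(P, size=n_masked, replace=False)
    bits[masked_idx] = 0
    return PatchMask(bits=bits, rate=rate, seed=seed)


def apply_mask(grid: PatchGrid, mask: PatchMask):
    """Select retained patches; returns (visible_patches, visible_indices)
    with indices strictly increasing."""
    if len(mask.bits) != grid.n_patches:
        raise ValueError(
            f"mask length {len(mask.bits)} != patch count {grid.n_patches}"
        )
    visible_indices = np.flatnonzero(mask.bits)
    return grid.patches[visible_indices], visible_indices


def derive_mask_seed(base_seed: int, record_id: str, view: str,
                     epoch: int = 0) -> int:
    """Stable per-(record, view, epoch) seed so the two views of one record
    always get independent masks and masks can be resampled per epoch."""
    key = f"{base_seed}|{record_id}|{view}|{epoch}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big")


def mean_fill(pixels: np.ndarray, valid: np.ndarray,
              max_iter: int = 10_000) -> np.ndarray:
    """Fill invalid pixels with the mean of their valid 4-neighbours,
    iterating until no holes remain."""
    out = np.array(pixels, dtype=float)
    valid = np.asarray(valid, dtype=bool).copy()
    if valid.all():
        return out
    if not valid.any():
        raise ValueError("cannot fill an image with no valid pixels")
    kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    out[~valid] = 0.0
    for _ in range(max_iter):
        if valid.all():
            break
        nb_sum = ndimage.convolve(out * valid, kernel, mode="constant")
        nb_cnt = ndimage.convolve(valid.astype(float), kernel, mode="constant")
        fillable = (~valid) & (nb_cnt > 0)
        if not fillable.any():  # unreachable for 4-connected grids
            raise RuntimeError("mean_fill could not reach remaining holes")
        out[fillable] = nb_sum[fillable] / nb_cnt[fillable]
        valid |= fillable
    return out


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_grayscale_png(path, view: str = "frontal") -> Radiograph:
    """Read an 8- or 16-bit grayscale PNG as a gray8-scaled radiograph
    (16-bit inputs are rescaled to [0, 255])."""
    im = Image.open(path)
    arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint16:
        arr = (arr.astype(float) / 257.0)
        arr = np.floor(arr + 0.5).astype(np.uint8)
    return Radiograph(arr.astype(np.uint8), view=view, units="gray8")


def write_grayscale_png(path, img: Radiograph):
    if img.units != "gray8":
        raise ValueError("write_grayscale_png expects gray8 pixels")
    Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(path)


def read_dicom(path, view: str = "frontal") -> Radiograph:
    """Read a DICOM file into HU units via rescale slope/intercept.

    Requires the optional ``pydicom`` dependency.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM support requires the optional 'pydicom' package"
        ) from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return Radiograph(arr * slope + intercept, view=view, units="HU")


def save_masked_grid(path, visible_patches: np.ndarray,
                     visible_indices: np.ndarray, mask: PatchMask,
                     grid_shape: tuple[int, int], patch_side: int):
    """Persist the visible patches plus a JSON manifest of indices/seed/rate."""
    manifest = {
        "grid_shape": list(grid_shape),
        "patch_side": patch_side,
        "rate": mask.rate,
        "seed": mask.seed,
        "visible_indices": [int(i) for i in visible_indices],
    }
    import io

    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest))
        buf = io.BytesIO()
        np.save(buf, visible_patches, allow_pickle=False)
        zf.writestr("visible_patches.npy", buf.getvalue())


def load_masked_grid(path):
    import io

    with zipfile.ZipFile(path, "r") as zf:
        manifest = json.loads(zf.read("manifest.json"))
        patches = np.load(io.BytesIO(zf.read("visible_patches.npy")),
                          allow_pickle=False)
    return patches, manifest
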