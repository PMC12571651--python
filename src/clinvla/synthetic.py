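"""Synthetic dual-view chest-phantom generator with paired reports.

Each record carries one latent lesion whose position, size and intensity
depend on its class; the lateral view is a deterministic reprojection of
the frontal lesion plus independent noise.  Reports are templated with a
Findings and a Diagnosis section containing a class-specific keyword, so
the whole preprocessing and alignment pipeline is exercisable offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_pipeline import Radiograph, ViewPair

__all__ = ["SyntheticSpec", "CLASS_KEYWORDS", "generate_record",
           "generate_dataset", "write_dataset", "load_dataset"]

# one keyword per class, echoed in both report sections
CLASS_KEYWORDS = [
    "pneumonia", "effusion", "atelectasis", "cardiomegaly",
    "edema", "consolidation", "pneumothorax", "nodule",
]

_FINDINGS_TEMPLATES = [
    "Patchy {kw} pattern seen in the {side} {zone} lung zone.",
    "There is a focal opacity consistent with {kw} in the {side} {zone} region.",
    "Dual view assessment shows {kw} changes over the {side} {zone} field.",
]

_DIAGNOSIS_TEMPLATES = [
    "Findings most consistent with {kw}.",
    "Impression of {kw}; clinical correlation advised.",
    "Appearance typical of {kw}.",
]

_SIDES = ["right", "left"]
_ZONES = ["upper", "middle", "lower"]


@dataclass
class SyntheticSpec:
    n_classes: int = 8
    n_per_class: int = 8
    image_side: int = 224
    hu_background: tuple[float, float] = (-1024.0, -950.0)
    body_hu: float = -200.0
    lesion_hu_base: float = 100.0
    lesion_hu_step: float = 100.0
    noise_hu: float = 15.0
    lateral_noise_px: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_classes <= len(CLASS_KEYWORDS)):
            raise ValueError(
                f"n_classes must be in [1, {len(CLASS_KEYWORDS)}]"
            )
        if self.n_per_class < 1 or self.image_side < 32:
            raise ValueError("invalid synthetic spec dimensions")


def _class_geometry(class_id: int, spec: SyntheticSpec):
    """Deterministic class-dependent lesion parameter ranges."""
    # lesion centres rotate around the chest; radius and intensity step by class
    angle = 2 * np.pi * class_id / max(spec.n_classes, 1)
    c = spec.image_side / 2.0
    r = spec.image_side * 0.22
    cy = c + r * np.sin(angle)
    cx = c + r * np.cos(angle)
    size = spec.image_side * (0.06 + 0.015 * (class_id % 4))
    peak = spec.lesion_hu_base + spec.lesion_hu_step * class_id
    return cy, cx, size, peak


def _gaussian_ellipse(side: int, cy: float, cx: float, sy: float, sx: float,
                      theta: float, peak: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return peak * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def _body_mask(side: int) -> np.ndarray:
    """Soft torso ellipse occupying the middle of the frame."""
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    c = side / 2.0
    d2 = ((yy - c) / (0.45 * side)) ** 2 + ((xx - c) / (0.38 * side)) ** 2
    return np.clip(1.2 - d2, 0.0, 1.0)


def generate_record(class_id: int, spec: SyntheticSpec, seed: int) -> ViewPair:
    """One dual-view record; deterministic for a fixed (class_id, seed)."""
    if class_id >= spec.n_classes:
        raise ValueError(f"class_id {class_id} >= n_classes {spec.n_classes}")
    rng = np.random.default_rng(seed)
    side = spec.image_side
    cy, cx, size, peak = _class_geometry(class_id, spec)
    # per-record jitter around the class geometry
    cy += rng.normal(0, side * 0.02)
    cx += rng.normal(0, side * 0.02)
    sy = size * rng.uniform(0.8, 1.2)
    sx = size * rng.uniform(0.8, 1.2)
    theta = rng.uniform(0, np.pi)
    depth = rng.uniform(0.3, 0.7)  # latent anterior-posterior position

    bg_lo, bg_hi = spec.hu_background
    body = _body_mask(side)

    def view_image(lesion_cy, lesion_cx, noise_rng) -> np.ndarray:
        img = bg_lo + (bg_hi - bg_lo) * noise_rng.random((side, side))
        img = img + body * (spec.body_hu - bg_lo) * 0.9
        img = img + _gaussian_ellipse(side, lesion_cy, lesion_cx, sy, sx,
                                      theta, peak - spec.body_hu)
        img = img + noise_rng.normal(0, spec.noise_hu, (side, side))
        return np.clip(img, -1024.0, 1000.0)

    frontal = view_image(cy, cx, rng)
    # lateral: same row, column determined by the latent depth (deterministic
    # reprojection), plus independent jitter
    lat_cx = side * (0.2 + 0.6 * depth)
    jitter = rng.normal(0, spec.lateral_noise_px, 2) if spec.lateral_noise_px else (0, 0)
    lateral = view_image(cy + jitter[0], lat_cx + jitter[1], rng)

    kw = CLASS_KEYWORDS[class_id]
    t = int(rng.integers(len(_FINDINGS_TEMPLATES)))
    side_w = _SIDES[int(rng.integers(2))]
    zone_w = _ZONES[int(rng.integers(3))]
    report = (
        "FINDINGS: "
        + _FINDINGS_TEMPLATES[t].format(kw=kw, side=side_w, zone=zone_w)
        + " DIAGNOSIS: "
        + _DIAGNOSIS_TEMPLATES[t].format(kw=kw)
    )
    return ViewPair(
        frontal=Radiograph(frontal, view="frontal", units="HU"),
        lateral=Radiograph(lateral, view="lateral", units="HU"),
        report=report,
        record_id=f"c{class_id:02d}_s{seed}",
    )


def lesion_reprojection(depth: float, image_side: int) -> float:
    """Deterministic frontal→lateral column mapping of the lesion centre."""
    return image_side * (0.2 + 0.6 * depth)


def generate_dataset(spec: SyntheticSpec):
    """Class-balanced record list plus a manifest of
    {record_id, class_id, report} dicts."""
    records: list[ViewPair] = []
    manifest: list[dict] = []
    base = np.random.default_rng(spec.seed)
    for class_id in range(spec.n_classes):
        for j in range(spec.n_per_class):
            rec_seed = int(base.integers(0, 2**63 - 1))
            rec = generate_record(class_id, spec, rec_seed)
            rec.record_id = f"c{class_id:02d}_r{j:04d}"
            records.append(rec)
            manifest.append({
                "record_id": rec.record_id,
                "class_id": class_id,
                "report": rec.report,
            })
    return records, manifest


def write_dataset(out_dir, spec: SyntheticSpec, write_png: bool = True):
    """Materialize a dataset: windowed PNGs, raw HU arrays (.npy) and a
    JSONL manifest of reports."""
    from .image_pipeline import window_normalize, write_grayscale_png

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, manifest = generate_dataset(spec)
    with open(out_dir / "manifest.jsonl", "w") as fh:
        for row in manifest:
            fh.write(json.dumps(row) + "\n")
    for rec in records:
        for view_name in ("frontal", "lateral"):
            rad = getattr(rec, view_name)
            np.save(out_dir / f"{rec.record_id}_{view_name}_hu.npy", rad.pixels)
            if write_png:
                write_grayscale_png(
                    out_dir / f"{rec.record_id}_{view_name}.png",
                    window_normalize(rad),
                )
    return records, manifest


def load_dataset(data_dir):
    """Load a dataset written by :func:`write_dataset`."""
    data_dir = Path(data_dir)
    records, manifest = [], []
    with open(data_dir / "manifest.jsonl") as fh:
        for line in fh:
            if line.strip():
                manifest.append(json.loads(line))
    for row in manifest:
        rid = row["record_id"]
        frontal = np.load(data_dir / f"{rid}_frontal_hu.npy")
        lateral = np.load(data_dir / f"{rid}_lateral_hu.npy")
        records.append(ViewPair(
            frontal=Radiograph(frontal, view="frontal", units="HU"),
            lateral=Radiograph(lateral, view="lateral", units="HU"),
            report=row["report"],
            record_id=rid,
        ))
    return records, manifest
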