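"""Synthetic fetal-MRI-like phantom slices with exact ground-truth masks.

Each "patient" is a simple articulated fetus model — a body ellipse, an
overlapping head disc and a few limb capsules — whose overall scale stands in
for gestational age. The model is posed per slice with smooth slice-to-slice
drift in rotation and position, emulating a sagittal sweep. The image is the
foreground intensity profile plus dimmer maternal-tissue ellipses in the
background, modulated by a smooth low-order polynomial bias field and
corrupted by additive Gaussian (optionally Rician) noise. The mask is the
exact rasterized foreground: by construction there is no label noise.

The generator is fully seeded: the same configuration and seed reproduce the
dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import SliceSample, save_volume

__all__ = ["PhantomConfig", "generate_patient", "generate_dataset", "GA_RANGE"]

#: gestational-age span (weeks) the fetus scale range is mapped onto
GA_RANGE = (20.0, 37.0)

_MAX_POSE_RETRIES = 20


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 128
    n_patients: int = 5
    slices_per_patient: int = 119
    fetus_scale_range: tuple[float, float] = (0.15, 0.28)
    pose_range: float = 45.0  # max |rotation| of the base pose, degrees
    noise_sigma: float = 0.05
    bias_field_strength: float = 0.2
    background_structures: int = 3
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    seed: int = 0

    def __post_init__(self):
        if self.fetus_scale_range[0] > self.fetus_scale_range[1]:
            raise ValueError("fetus_scale_range must be (low, high)")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _rot(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _ellipse_mask(yy, xx, center, axes, angle_deg):
    R = _rot(-angle_deg)
    dy, dx = yy - center[0], xx - center[1]
    u = R[0, 0] * dx + R[0, 1] * dy
    v = R[1, 0] * dx + R[1, 1] * dy
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def _capsule_mask(yy, xx, p0, p1, radius):
    """Pixels within ``radius`` of the segment p0-p1 (a "limb")."""
    d = np.array(p1) - np.array(p0)
    L2 = d @ d
    py, px = yy - p0[0], xx - p0[1]
    t = np.clip((py * d[0] + px * d[1]) / max(L2, 1e-12), 0.0, 1.0)
    return (py - t * d[0]) ** 2 + (px - t * d[1]) ** 2 <= radius**2


def _fetus_mask(size, scale, angle, center, limb_angles, rng_free=None):
    """Rasterize the fetus model; returns (mask, body_center, extent_radius)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    a = scale * size  # body semi-major axis, pixels
    b = 0.62 * a
    body_c = np.asarray(center, dtype=float)
    mask = _ellipse_mask(yy, xx, body_c, (a, b), angle)
    # head: disc overlapping the body end along the major axis
    direction = np.array([-np.sin(np.deg2rad(angle)), np.cos(np.deg2rad(angle))])
    head_r = 0.48 * a
    head_c = body_c + direction * (a * 0.95)
    mask |= _ellipse_mask(yy, xx, head_c, (head_r, head_r), 0.0)
    # limbs: capsules rooted on the body boundary
    limb_len = 0.9 * a
    limb_r = 0.16 * a
    for la in limb_angles:
        u = np.array([-np.sin(np.deg2rad(angle + la)), np.cos(np.deg2rad(angle + la))])
        p0 = body_c + u * (0.8 * b)
        p1 = p0 + u * limb_len
        mask |= _capsule_mask(yy, xx, p0, p1, limb_r)
    extent = a * 1.95 + limb_len  # generous bound on fetus radius
    return mask, body_c, extent


def _bias_field(size, strength, rng):
    """Smooth multiplicative field 1 + strength * quadratic(x, y) in [-1, 1]."""
    y, x = np.mgrid[0:size, 0:size] / (size - 1) * 2.0 - 1.0
    coeffs = rng.uniform(-1, 1, size=6)
    p = (
        coeffs[0] * x
        + coeffs[1] * y
        + coeffs[2] * x * y
        + coeffs[3] * x**2
        + coeffs[4] * y**2
        + coeffs[5]
    )
    amp = np.abs(p).max()
    if amp > 0:
        p = p / amp
    return 1.0 + strength * p


def generate_patient(cfg: PhantomConfig, patient_index: int) -> list[SliceSample]:
    """Generate all slices for one synthetic patient.

    The per-patient scale (gestational-size proxy) and base pose are drawn
    once; per-slice pose drifts smoothly. Raises if a pose cannot be placed
    inside the field of view after a bounded number of retries.
    """
    rng = np.random.default_rng([cfg.seed, patient_index])
    size = cfg.image_size
    scale = rng.uniform(*cfg.fetus_scale_range)
    base_angle = rng.uniform(-cfg.pose_range, cfg.pose_range)
    n_limbs = int(rng.integers(2, 5))
    limb_angles = rng.uniform(60, 300, size=n_limbs)
    ga = float(
        GA_RANGE[0]
        + (scale - cfg.fetus_scale_range[0])
        / max(cfg.fetus_scale_range[1] - cfg.fetus_scale_range[0], 1e-12)
        * (GA_RANGE[1] - GA_RANGE[0])
    )
    pid = f"phantom{patient_index:03d}"

    # smooth slice-to-slice drift: sinusoids over the slice index
    t = np.arange(cfg.slices_per_patient) / max(cfg.slices_per_patient - 1, 1)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    angle_track = base_angle + 15.0 * np.sin(2 * np.pi * t + phases[0])
    cy_track = size / 2 + 0.06 * size * np.sin(2 * np.pi * t + phases[1])
    cx_track = size / 2 + 0.06 * size * np.sin(2 * np.pi * t + phases[2])

    bg_params = [
        (
            rng.uniform(0.1, 0.9, size=2) * size,  # center
            rng.uniform(0.12, 0.35, size=2) * size,  # axes
            rng.uniform(0, 180),  # angle
            rng.uniform(0.2, 0.45),  # intensity
        )
        for _ in range(cfg.background_structures)
    ]

    samples = []
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    for s in range(cfg.slices_per_patient):
        angle, center = angle_track[s], (cy_track[s], cx_track[s])
        for attempt in range(_MAX_POSE_RETRIES + 1):
            mask, body_c, extent = _fetus_mask(size, scale, angle, center, limb_angles)
            border = (
                mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any()
            )
            if not border and mask.any():
                break
            if attempt == _MAX_POSE_RETRIES:
                raise RuntimeError(
                    f"fetus at scale {scale:.3f} cannot be posed inside a "
                    f"{size}x{size} field of view"
                )
            angle = rng.uniform(-cfg.pose_range, cfg.pose_range)
            center = (
                size / 2 + rng.uniform(-0.05, 0.05) * size,
                size / 2 + rng.uniform(-0.05, 0.05) * size,
            )
        # foreground intensity: bright with a mild radial falloff
        r2 = ((yy - body_c[0]) ** 2 + (xx - body_c[1]) ** 2) / extent**2
        fg = 0.8 * (1.0 - 0.25 * np.clip(r2, 0.0, 1.0))
        image = np.zeros((size, size))
        for bc, axes, bang, inten in bg_params:
            bg_mask = _ellipse_mask(yy, xx, bc, axes, bang)
            image[bg_mask & ~mask] = inten
        image[mask] = fg[mask]
        if cfg.bias_field_strength > 0:
            image *= _bias_field(size, cfg.bias_field_strength, rng)
        if cfg.noise_sigma > 0:
            if cfg.noise_model == "rician":
                n1 = rng.normal(0, cfg.noise_sigma, image.shape)
                n2 = rng.normal(0, cfg.noise_sigma, image.shape)
                image = np.sqrt((image + n1) ** 2 + n2**2)
            else:
                image = image + rng.normal(0, cfg.noise_sigma, image.shape)
        image = np.clip(image, 0.0, None)
        samples.append(
            SliceSample(
                image=image.astype(np.float32),
                mask=mask.astype(np.uint8),
                patient_id=pid,
                slice_index=s,
                gestational_age=ga,
            )
        )
    return samples


def generate_dataset(cfg: PhantomConfig, out_dir) -> Path:
    """Write the phantom cohort as NIfTI image/mask pairs plus a manifest.

    Returns the path of the manifest JSON. Layout::

        out_dir/phantom000_image.nii.gz
        out_dir/phantom000_mask.nii.gz
        ...
        out_dir/manifest.json
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients = []
    for idx in range(cfg.n_patients):
        samples = generate_patient(cfg, idx)
        pid = samples[0].patient_id
        save_volume(
            np.stack([s.image for s in samples]), out_dir / f"{pid}_image.nii.gz"
        )
        save_volume(
            np.stack([s.mask for s in samples]), out_dir / f"{pid}_mask.nii.gz"
        )
        patients.append(
            {
                "patient_id": pid,
                "gestational_age": samples[0].gestational_age,
                "n_slices": len(samples),
                "image": f"{pid}_image.nii.gz",
                "mask": f"{pid}_mask.nii.gz",
            }
        )
    manifest = {
        "patients": patients,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
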