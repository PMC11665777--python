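"""Seeded colonoscopy-phantom generator: image/mask pairs without downloads.

Frames emulate the gross statistics of colonoscopy imagery that matter for
a segmentation exercise: a smooth reddish mucosal background with a
vignette, one to three blob-like lesions (ellipses perturbed by low-order
radial harmonics) of varying size, aspect ratio, rotation and contrast, an
optional specular highlight, and additive pixel noise.  Masks are rendered
from the same analytic boundary, so image and annotation agree exactly.

Every sample is a pure function of (spec.seed, index): regenerating a
dataset with the same spec reproduces identical files byte for byte.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .encoder import ConfigurationError


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 224
    n_lesions: tuple[int, int] = (1, 3)
    lesion_radius_frac: tuple[float, float] = (0.08, 0.35)
    aspect_ratio: tuple[float, float] = (0.4, 1.0)
    contrast: tuple[float, float] = (0.25, 0.6)
    noise_sd: float = 0.03
    background_smoothness: int = 6    # coarse-grid cells per side
    boundary_wobble: float = 0.08     # radial-harmonic amplitude
    highlight_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        for name in ("n_lesions", "lesion_radius_frac", "aspect_ratio", "contrast"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"empty range for {name}")
        if not (0 <= self.lesion_radius_frac[0] and self.lesion_radius_frac[1] <= 1):
            raise ConfigurationError("lesion_radius_frac must lie in [0,1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


@dataclass
class SamplePair:
    image: np.ndarray          # (H,W,3) float in [0,1]
    mask: np.ndarray           # (H,W) uint8 in {0,1}
    metadata: list = field(default_factory=list)


def _smooth_noise(rng, size, cells, channels=1):
    """Low-frequency texture: bilinear blow-up of a coarse random grid."""
    coarse = rng.random((cells + 1, cells + 1, channels))
    xs = np.linspace(0, cells, size)
    i = np.clip(xs.astype(int), 0, cells - 1)
    f = xs - i
    rows = (coarse[i] * (1 - f)[:, None, None] + coarse[i + 1] * f[:, None, None])
    cols = (rows[:, i] * (1 - f)[None, :, None] + rows[:, i + 1] * f[None, :, None])
    return cols


def _lesion_mask(size, cx, cy, r_major, aspect, angle, harmonics):
    yy, xx = np.mgrid[0:size, 0:size]
    x = (xx - cx)
    y = (yy - cy)
    ca, sa = np.cos(angle), np.sin(angle)
    u = (x * ca + y * sa) / r_major
    v = (-x * sa + y * ca) / (r_major * aspect)
    rr = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    bound = np.ones_like(theta)
    for k, (amp, phase) in enumerate(harmonics, start=2):
        bound += amp * np.cos(k * theta + phase)
    return rr <= bound, rr / np.maximum(bound, 1e-6)


def generate_sample(spec: PhantomSpec, index: int) -> SamplePair:
    """Deterministic phantom for (spec.seed, index)."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(index,)))
    s = spec.image_size

    # mucosal background: reddish base + low-frequency texture + vignette
    base = np.array([0.62, 0.33, 0.27])
    tex = _smooth_noise(rng, s, spec.background_smoothness, 3)
    img = base + (tex - 0.5) * 0.25
    yy, xx = np.mgrid[0:s, 0:s]
    r2 = ((xx - s / 2) ** 2 + (yy - s / 2) ** 2) / (s / 2) ** 2
    img *= (1.0 - 0.35 * r2)[..., None]

    mask = np.zeros((s, s), dtype=np.uint8)
    n = int(rng.integers(spec.n_lesions[0], spec.n_lesions[1] + 1))
    meta = []
    for _ in range(n):
        r_frac = rng.uniform(*spec.lesion_radius_frac)
        r = r_frac * s
        aspect = rng.uniform(*spec.aspect_ratio)
        angle = rng.uniform(0, np.pi)
        margin = r * (1 + spec.boundary_wobble) + 2
        cx = rng.uniform(margin, s - margin) if s > 2 * margin else s / 2
        cy = rng.uniform(margin, s - margin) if s > 2 * margin else s / 2
        nharm = 0 if spec.boundary_wobble == 0 else int(rng.integers(2, 4))
        harmonics = [(rng.uniform(0, spec.boundary_wobble), rng.uniform(0, 2 * np.pi))
                     for _ in range(nharm)]
        inside, rel = _lesion_mask(s, cx, cy, r, aspect, angle, harmonics)
        contrast = rng.uniform(*spec.contrast) * rng.choice([1.0, -0.6])
        profile = np.clip(1.0 - rel, 0, 1) ** 0.7
        tint = np.array([1.0, 0.55, 0.45]) if contrast > 0 else np.array([0.9, 1.0, 0.9])
        img += (contrast * profile)[..., None] * tint
        mask |= inside.astype(np.uint8)
        meta.append({"cx": cx, "cy": cy, "r": r, "aspect": aspect,
                     "angle": angle, "contrast": contrast})
        if rng.random() < spec.highlight_prob:
            hx = cx + rng.uniform(-0.3, 0.3) * r
            hy = cy + rng.uniform(-0.3, 0.3) * r
            hr = max(1.5, 0.12 * r)
            g = np.exp(-(((xx - hx) ** 2 + (yy - hy) ** 2) / (2 * hr * hr)))
            img += 0.5 * g[..., None]

    img += rng.normal(0, spec.noise_sd, img.shape)
    return SamplePair(image=np.clip(img, 0, 1).astype(np.float32),
                      mask=mask, metadata=meta)


def generate_dataset(spec: PhantomSpec, n: int, out_dir) -> Path:
    """Write n image/mask PNG pairs plus a CSV manifest; returns its path.

    Layout matches the public polyp datasets (`images/`, `masks/`) so real
    data drops in unchanged.  Masks are 8-bit single-channel {0,255} PNGs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "image", "mask", "n_lesions", "lesion_area_frac"])
        for i in range(n):
            pair = generate_sample(spec, i)
            img_p = out / "images" / f"phantom_{i:04d}.png"
            msk_p = out / "masks" / f"phantom_{i:04d}.png"
            iio.imwrite(img_p, (pair.image * 255).round().astype(np.uint8))
            iio.imwrite(msk_p, (pair.mask * 255).astype(np.uint8))
            wr.writerow([f"phantom_{i:04d}", str(img_p), str(msk_p),
                         len(pair.metadata),
                         f"{pair.mask.mean():.6f}"])
    return manifest
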