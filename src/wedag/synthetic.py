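"""Synthetic three-class brain-slice phantoms.

The generator emulates the kind of input the pipeline expects — a
skull-stripped, spatially normalised, Gaussian-smoothed 2D sagittal slice —
as an elliptical "brain" over a zero background, filled with a smooth base
intensity field plus band-limited stochastic texture and pixel noise.

Class structure (HC = healthy control, LHL/RHL = left/right-sided hearing
loss):

* every image carries two independent band-limited texture fields, one in a
  mid spatial-frequency annulus and one in a high annulus;
* in LHL phantoms the mid-band texture is spatially concentrated into a
  left mid-temporal focus, in RHL the high-band texture into a right one,
  with strength ``effect_size`` (HC texture stays spatially uniform);
* LHL/RHL additionally receive a hypointense Gaussian lesion of relative
  depth ``lesion_contrast`` at the corresponding focus.

Wavelet entropy is a global, location-insensitive statistic, so purely
mirror-image lesions with identical texture statistics would be nearly
indistinguishable to it.  The class contrast is therefore deliberately
encoded in *which frequency band* has its energy spatially concentrated
(concentration lowers the energy entropy of the matching subbands); the
left/right placement makes the phantoms look anatomically lateralised but
is not what the features respond to.  This is a documented property of the
feature, not of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "CohortIOError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

CLASS_NAMES = ("HC", "LHL", "RHL")


class CohortIOError(OSError):
    """Raised when a cohort directory is missing files it should contain."""


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level knobs; the defaults are the package's study conditions.

    ``effect_size`` in [0, 1] is the fraction of the class-specific texture
    band whose amplitude is moved under the focal envelope (0 = uniform,
    classes exchangeable).  ``lesion_contrast`` is the lesion depth relative
    to the [0, 1] base intensity scale.  ``noise_sd`` is the per-pixel
    Gaussian noise sigma and ``smoothing_sigma`` the final blur width in
    pixels, mimicking the smoothing step of a standard preprocessing chain.
    """

    image_size: tuple[int, int] = (256, 256)
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 20, "LHL": 15, "RHL": 14}
    )
    effect_size: float = 0.8
    lesion_contrast: float = 0.3
    noise_sd: float = 0.02
    smoothing_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size) < 16:
            raise ValueError("image_size must be at least 16 x 16")
        counts = dict(self.n_per_class)
        if set(counts) - set(CLASS_NAMES):
            raise ValueError(f"classes must be among {CLASS_NAMES}")
        if any(v < 0 for v in counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(counts.values()) == 0:
            raise ValueError("at least one class count must be > 0")
        for name in ("effect_size", "lesion_contrast", "noise_sd", "smoothing_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "n_per_class", counts)


def _ellipse_mask(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    r = (np.arange(rows) - rows / 2.0) / (0.4 * rows)
    c = (np.arange(cols) - cols / 2.0) / (0.4 * cols)
    return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0


def _annulus(shape: tuple[int, int], f_lo: float, f_hi: float) -> np.ndarray:
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    freq = np.hypot(fr, fc)
    return ((freq >= f_lo) & (freq < f_hi)).astype(float)

def _bandpass_noise(rng: np.random.Generator, shape, band: np.ndarray) -> np.ndarray:
    white = rng.standard_normal(shape)
    tex = np.fft.ifft2(np.fft.fft2(white) * band).real
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _gaussian_blob(shape, center_rc, sigma: float) -> np.ndarray:
    r = np.arange(shape[0])[:, None] - center_rc[0]
    c = np.arange(shape[1])[None, :] - center_rc[1]
    return np.exp(-(r**2 + c**2) / (2.0 * sigma**2))


def generate_cohort(cfg: PhantomConfig) -> tuple[list[np.ndarray], list[str]]:
    """Deterministically generate the labelled phantom cohort.

    Returns images (float64 in [0, 1], background exactly 0) and the aligned
    label list; output order is shuffled by the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.image_size)
    rows, cols = shape
    px = min(rows, cols) / 256.0  # geometry scales with resolution

    mask = _ellipse_mask(shape)
    rr = (np.arange(rows)[:, None] - rows / 2.0) / (0.4 * rows)
    cc = (np.arange(cols)[None, :] - cols / 2.0) / (0.4 * cols)
    radial = np.sqrt(rr**2 + cc**2)
    base = 0.55 + 0.15 * np.cos(1.4 * radial)

    band_mid = _annulus(shape, 0.05, 0.10)
    band_high = _annulus(shape, 0.12, 0.22)

    # mid-temporal foci; must lie inside the elliptical mask
    left_center = (int(round(0.60 * rows)), int(round(0.28 * cols)))
    right_center = (int(round(0.60 * rows)), int(round(0.72 * cols)))
    for ctr in (left_center, right_center):
        if not mask[ctr]:
            raise RuntimeError(f"lesion focus {ctr} fell outside the brain mask")
    env_left = _gaussian_blob(shape, left_center, 25.0 * px)
    env_right = _gaussian_blob(shape, right_center, 25.0 * px)
    lesion_left = _gaussian_blob(shape, left_center, 12.0 * px)
    lesion_right = _gaussian_blob(shape, right_center, 12.0 * px)

    tex_amp = 0.08

    def one_image(cls: str) -> np.ndarray:
        t_mid = _bandpass_noise(rng, shape, band_mid)
        t_high = _bandpass_noise(rng, shape, band_high)
        e = cfg.effect_size
        if cls == "LHL":
            t_mid = t_mid * ((1.0 - e) + 4.0 * e * env_left)
        elif cls == "RHL":
            t_high = t_high * ((1.0 - e) + 4.0 * e * env_right)
        img = base + tex_amp * (t_mid + t_high)
        if cls == "LHL":
            img = img - cfg.lesion_contrast * lesion_left
        elif cls == "RHL":
            img = img - cfg.lesion_contrast * lesion_right
        img = img + rng.normal(0.0, cfg.noise_sd, size=shape)
        if cfg.smoothing_sigma > 0:
            img = gaussian_filter(img, cfg.smoothing_sigma)
        img = np.clip(img, 0.0, 1.0)
        img[~mask] = 0.0
        return img

    images: list[np.ndarray] = []
    labels: list[str] = []
    for cls in CLASS_NAMES:
        for _ in range(cfg.n_per_class.get(cls, 0)):
            images.append(one_image(cls))
            labels.append(cls)
    order = rng.permutation(len(images))
    return [images[i] for i in order], [labels[i] for i in order]


def write_cohort(
    images: Sequence[np.ndarray], labels: Sequence[str], directory
) -> Path:
    """Write a cohort as 16-bit grayscale PNGs plus a ``manifest.csv``."""
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, label) in enumerate(zip(images, labels)):
        name = f"img_{i:03d}.png"
        arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
        iio.imwrite(directory / name, np.round(arr * 65535.0).astype(np.uint16))
        records.append({"filename": name, "label": label})
    pd.DataFrame(records).to_csv(directory / "manifest.csv", index=False)
    return directory


def read_cohort(directory) -> tuple[list[np.ndarray], list[str]]:
    """Read back a cohort directory; intensities return to the [0, 1] scale."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.is_file():
        raise CohortIOError(f"missing cohort manifest: {manifest}")
    table = pd.read_csv(manifest)
    images, labels = [], []
    for rec in table.itertuples():
        path = directory / rec.filename
        if not path.is_file():
            raise CohortIOError(f"missing cohort image: {path}")
        arr = np.asarray(iio.imread(path), dtype=float)
        images.append(arr / 65535.0)
        labels.append(str(rec.label))
    return images, labels
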