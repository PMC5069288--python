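"""Wavelet-entropy feature extraction.

A brain slice is reduced to a (3n+1)-element vector: the image is decomposed
into 3n+1 subbands with an n-level 2D DWT and a Shannon entropy is computed
on each subband.  The default (and recommended) entropy is the entropy of
the normalised coefficient-energy distribution

    p_i = c_i^2 / sum_j c_j^2,       H = -sum_i p_i log2(p_i)   [bits]

with the convention 0*log(0) = 0 and H = 0 for an all-zero subband.  This
statistic is invariant to rescaling the image and measures how evenly the
subband's energy is spread over its coefficients: H ranges from 0 (a single
coefficient carries everything) to log2(M) for M equally energetic
coefficients.

A gray-level histogram variant (entropy of a 256-bin coefficient-value
histogram) is available behind ``variant="histogram"``; it is not the
default and is not scale-invariant in general.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon

from .wavelet import FilterBank, Subband, subband_labels, wavedec2

__all__ = ["FeatureVector", "subband_entropy", "extract_we", "extract_batch"]

# Coefficients whose magnitude is below this fraction of the decomposition's
# largest coefficient are treated as exact zeros before the entropy is
# computed: filtering a flat region annihilates the high-pass branch only up
# to float round-off, and entropy of pure round-off noise is meaningless.
ZERO_FLOOR = 1e-12

_VARIANTS = ("energy", "histogram")


@dataclass(frozen=True)
class FeatureVector:
    """The wavelet-entropy vector of one image (entropies in bits)."""

    values: np.ndarray
    level: int
    wavelet_name: str
    subband_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (3 * self.level + 1,):
            raise ValueError(
                f"expected {3 * self.level + 1} entries for level {self.level}, "
                f"got shape {vals.shape}"
            )
        if len(self.subband_labels) != vals.size:
            raise ValueError("labels and values disagree in length")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "subband_labels", tuple(self.subband_labels))

    def __len__(self) -> int:
        return self.values.size


def subband_entropy(
    sb: Subband | np.ndarray,
    variant: str = "energy",
    zero_tol: float = 0.0,
) -> float:
    """Shannon entropy (bits) of one subband's coefficient distribution.

    ``zero_tol`` is an absolute magnitude below which coefficients are
    treated as zero (see :data:`ZERO_FLOOR`); callers that see the whole
    decomposition set it relative to the global coefficient scale.
    """
    coeffs = sb.coeffs if isinstance(sb, Subband) else np.asarray(sb, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        raise ValueError("empty subband")
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("subband contains non-finite coefficients")
    if variant not in _VARIANTS:
        raise ValueError(f"unknown entropy variant {variant!r}; choose from {_VARIANTS}")
    flat = coeffs.ravel()
    if zero_tol > 0.0:
        flat = np.where(np.abs(flat) < zero_tol, 0.0, flat)
    if variant == "energy":
        energies = flat**2
        total = energies.sum()
        if total == 0.0:
            return 0.0
        return float(_shannon(energies, base=2))
    counts, _ = np.histogram(flat, bins=256)
    return float(_shannon(counts, base=2))


def extract_we(
    img: np.ndarray, fb: FilterBank, level: int, variant: str = "energy"
) -> FeatureVector:
    """Decompose an image and return its (3n+1)-element wavelet-entropy vector."""
    dec = wavedec2(img, fb, level)
    scale = max(float(np.max(np.abs(sb.coeffs))) for sb in dec)
    tol = ZERO_FLOOR * scale
    values = np.array(
        [subband_entropy(sb, variant=variant, zero_tol=tol) for sb in dec]
    )
    return FeatureVector(
        values=values,
        level=level,
        wavelet_name=fb.name,
        subband_labels=tuple(dec.labels),
    )


def extract_batch(
    imgs: Iterable[np.ndarray],
    fb: FilterBank,
    level: int,
    variant: str = "energy",
) -> pd.DataFrame:
    """Feature table for a sequence of images (one row each, input order kept).

    Columns are the canonical subband labels; a failing image aborts the
    batch with its position identified.
    """
    rows = []
    for i, img in enumerate(imgs):
        try:
            rows.append(extract_we(img, fb, level, variant=variant).values)
        except Exception as exc:
            raise type(exc)(f"image {i}: {exc}") from exc
    labels = subband_labels(level)
    if not rows:
        return pd.DataFrame(columns=labels, dtype=float)
    return pd.DataFrame(np.vstack(rows), columns=labels)
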