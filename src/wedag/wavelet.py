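"""Biorthogonal filter banks and the n-level 2D dyadic discrete wavelet transform.

The transform used throughout the package is the separable, decimated 2D DWT
with half-sample symmetric boundary extension (the pixel at the border is
repeated when mirroring).  Under that convention a single analysis stage maps
an axis of length ``N`` filtered with a length-``L`` filter to
``floor((N + L - 1) / 2)`` coefficients, and the analysis low-pass branch has
a DC gain of sqrt(2): a constant image of value ``c`` has an LL1 subband that
is constant at ``2 c``.

Subband labels follow the "row-filter, column-filter" convention: ``HL2``
means the high-pass filter was applied along rows (axis 0) and the low-pass
filter along columns (axis 1) at decomposition level 2.  Coefficient grids
are stored row-major with the origin at the top-left, like the input raster.

The canonical subband ordering of an n-level decomposition is coarse to
fine::

    [LLn, HLn, LHn, HHn, HL(n-1), LH(n-1), HH(n-1), ..., HL1, LH1, HH1]

which contains ``3 n + 1`` subbands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

__all__ = [
    "FilterBank",
    "Subband",
    "WaveletDecomposition",
    "UnsupportedWaveletError",
    "ImageSizeError",
    "OverDecompositionError",
    "build_filter_bank",
    "dwt2_single_level",
    "wavedec2",
    "waverec2",
    "subband_labels",
]


class UnsupportedWaveletError(ValueError):
    """Raised for a wavelet identifier with no known filter bank."""


class ImageSizeError(ValueError):
    """Raised when an image is too small for the requested filtering."""


class OverDecompositionError(ValueError):
    """Raised when the requested level exceeds what the image size allows."""


@dataclass(frozen=True)
class FilterBank:
    """The four FIR filters of a (bi)orthogonal discrete wavelet.

    ``dec_lo``/``dec_hi`` are the analysis (decomposition) low/high-pass
    taps, ``rec_lo``/``rec_hi`` the synthesis (reconstruction) taps.  The
    taps follow the normalisation under which the analysis low-pass branch
    multiplies a constant signal by sqrt(2).
    """

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
            taps = np.asarray(getattr(self, attr), dtype=float)
            if taps.ndim != 1 or taps.size < 2:
                raise ValueError(f"{attr}: filter must be 1D with >= 2 taps")
            if not np.all(np.isfinite(taps)):
                raise ValueError(f"{attr}: non-finite filter tap")
            object.__setattr__(self, attr, taps)

    @property
    def dec_len(self) -> int:
        return max(self.dec_lo.size, self.dec_hi.size)

    def to_pywt(self) -> pywt.Wavelet:
        return pywt.Wavelet(
            self.name,
            filter_bank=[self.dec_lo, self.dec_hi, self.rec_lo, self.rec_hi],
        )


@dataclass(frozen=True)
class Subband:
    """One labelled coefficient grid of a 2D decomposition (e.g. ``"HL2"``)."""

    label: str
    coeffs: np.ndarray

    @property
    def level(self) -> int:
        return int(self.label[2:])

    @property
    def kind(self) -> str:
        return self.label[:2]


@dataclass(frozen=True)
class WaveletDecomposition:
    """The 3n+1 subbands of an n-level decomposition, in canonical order."""

    level: int
    subbands: tuple[Subband, ...]
    image_shape: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        expected = 3 * self.level + 1
        if len(self.subbands) != expected:
            raise ValueError(
                f"{len(self.subbands)} subbands for level {self.level}; "
                f"expected {expected}"
            )

    def __iter__(self):
        return iter(self.subbands)

    def __len__(self) -> int:
        return len(self.subbands)

    @property
    def labels(self) -> list[str]:
        return [sb.label for sb in self.subbands]


def subband_labels(level: int) -> list[str]:
    """Canonical coarse-to-fine label order for an n-level decomposition."""
    if level < 1:
        raise ValueError("level must be >= 1")
    labels = [f"LL{level}"]
    for lev in range(level, 0, -1):
        labels += [f"HL{lev}", f"LH{lev}", f"HH{lev}"]
    return labels


def build_filter_bank(name: str) -> FilterBank:
    """Return the filter bank of a named discrete wavelet (e.g. ``"bior5.5"``).

    Taps come from the standard published constructions (B-spline
    biorthogonal tables for the ``bior`` family) as distributed by
    PyWavelets, normalised to a sqrt(2) DC gain per analysis low-pass stage.
    """
    try:
        wav = pywt.Wavelet(name)
    except ValueError as exc:
        raise UnsupportedWaveletError(f"unknown or unsupported wavelet: {name!r}") from exc
    return FilterBank(
        name=name,
        dec_lo=np.asarray(wav.dec_lo),
        dec_hi=np.asarray(wav.dec_hi),
        rec_lo=np.asarray(wav.rec_lo),
        rec_hi=np.asarray(wav.rec_hi),
    )


def _as_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def dwt2_single_level(
    img: np.ndarray, fb: FilterBank
) -> tuple[Subband, Subband, Subband, Subband]:
    """One separable analysis stage: returns the (LL, HL, LH, HH) quadruple.

    Rows then columns are filtered with symmetric boundary extension and
    decimated by two; labels carry level index 1 regardless of where the
    stage sits in a recursion (callers relabel).
    """
    arr = _as_image(img)
    if min(arr.shape) < fb.dec_len:
        raise ImageSizeError(
            f"image shape {arr.shape} smaller than filter length {fb.dec_len}"
        )
    ll, (hl, lh, hh) = pywt.dwt2(arr, fb.to_pywt(), mode="symmetric")
    return (
        Subband("LL1", ll),
        Subband("HL1", hl),
        Subband("LH1", lh),
        Subband("HH1", hh),
    )


def wavedec2(img: np.ndarray, fb: FilterBank, level: int) -> WaveletDecomposition:
    """n-level dyadic decomposition: recursively split the running LL band."""
    arr = _as_image(img)
    if not isinstance(level, (int, np.integer)) or level < 1:
        raise ValueError(f"decomposition level must be a positive integer, got {level!r}")
    detail_stack: list[tuple[Subband, Subband, Subband]] = []
    ll = arr
    for lev in range(1, level + 1):
        if min(ll.shape) < fb.dec_len:
            raise OverDecompositionError(
                f"level {level} too deep: the level-{lev} input has shape "
                f"{ll.shape}, smaller than the filter length {fb.dec_len}"
            )
        ll_sb, hl, lh, hh = dwt2_single_level(ll, fb)
        ll = ll_sb.coeffs
        detail_stack.append(
            (
                Subband(f"HL{lev}", hl.coeffs),
                Subband(f"LH{lev}", lh.coeffs),
                Subband(f"HH{lev}", hh.coeffs),
            )
        )
    subbands: list[Subband] = [Subband(f"LL{level}", ll)]
    for hl, lh, hh in reversed(detail_stack):
        subbands += [hl, lh, hh]
    return WaveletDecomposition(
        level=level, subbands=tuple(subbands), image_shape=arr.shape
    )


def waverec2(dec: WaveletDecomposition, fb: FilterBank) -> np.ndarray:
    """Inverse of :func:`wavedec2`, exact up to boundary round-off.

    Used for self-verification of the filter bank; the feature pipeline
    itself only decomposes.
    """
    by_label = {sb.label: sb.coeffs for sb in dec.subbands}
    if sorted(by_label) != sorted(subband_labels(dec.level)):
        raise ValueError("decomposition does not carry the canonical subband set")
    wav = fb.to_pywt()
    ll = by_label[f"LL{dec.level}"]
    for lev in range(dec.level, 0, -1):
        hl = by_label[f"HL{lev}"]
        lh = by_label[f"LH{lev}"]
        hh = by_label[f"HH{lev}"]
        if not (hl.shape == lh.shape == hh.shape):
            raise ValueError(f"inconsistent detail shapes at level {lev}")
        # A coarser grid may carry one extra row/column relative to what the
        # detail grids at this level imply (odd-length parent); trim it.
        if ll.shape != hl.shape:
            if any(s - d not in (0, 1) for s, d in zip(ll.shape, hl.shape)):
                raise ValueError(
                    f"approximation shape {ll.shape} incompatible with detail "
                    f"shape {hl.shape} at level {lev}"
                )
            ll = ll[: hl.shape[0], : hl.shape[1]]
        ll = pywt.idwt2((ll, (hl, lh, hh)), wav, mode="symmetric")
    rows, cols = dec.image_shape
    if rows and cols:
        if any(s - d not in (0, 1) for s, d in zip(ll.shape, (rows, cols))):
            raise ValueError(
                f"reconstruction shape {ll.shape} incompatible with image "
                f"shape {(rows, cols)}"
            )
        ll = ll[:rows, :cols]
    return ll
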