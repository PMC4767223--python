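"""Stimulus image statistics: luminance, contrast, skew, and pairwise
power-spectrum differences.

These are the standard low-level statistics used to check that stimulus
classes are matched: mean pixel luminance, RMS contrast as SD divided by
mean, histogram skew as the third standardised moment, and — since no
single canonical spectrum-difference metric exists — the RMS difference
of log-amplitude radially-averaged Fourier spectra per image pair,
averaged over all unordered pairs (a full-2-D variant is available).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

_LOG_EPS = 1e-12


@dataclass
class ImageStats:
    mean_luminance: float
    contrast: float  # SD / mean, dimensionless
    skew: float      # third standardised moment; 0 for constant images


@dataclass
class SpectrumDiff:
    pair_ids: list[tuple[int, int]]
    differences: np.ndarray
    mean_difference: float


def image_stats(img: np.ndarray, mask: np.ndarray | None = None) -> ImageStats:
    """Mean, contrast and skew over an image's pixels.

    ``mask`` (boolean, same shape) restricts the statistics to a region,
    e.g. the object instead of the full frame. A uniform image has
    contrast 0 and, by convention, skew 0; a zero-mean image has no
    defined contrast and raises.
    """
    a = np.asarray(img, dtype=float)
    if a.size == 0:
        raise ValueError("empty image")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the image")
        a = a[mask]
        if a.size == 0:
            raise ValueError("mask selects no pixels")
    mean = float(a.mean())
    if mean == 0:
        raise ValueError("zero mean luminance; contrast undefined")
    sd = float(a.std())
    skew = float(((a - mean) ** 3).mean() / sd**3) if sd > 0 else 0.0
    return ImageStats(mean_luminance=mean, contrast=sd / mean, skew=skew)


def radial_profile(img: np.ndarray) -> np.ndarray:
    """Radially averaged log-amplitude Fourier spectrum of a 2-D image."""
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    amp = np.abs(np.fft.fftshift(np.fft.fft2(a)))
    log_amp = np.log10(amp + _LOG_EPS)
    h, w = a.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - h // 2, xx - w // 2).round().astype(int)
    nbins = r.max() + 1
    sums = np.bincount(r.ravel(), weights=log_amp.ravel(), minlength=nbins)
    counts = np.bincount(r.ravel(), minlength=nbins)
    return sums / counts


def spectrum_difference(
    images: list[np.ndarray], mode: str = "radial"
) -> SpectrumDiff:
    """Pairwise power-spectrum differences, averaged across image pairs.

    ``radial``: RMS difference of radially-averaged log-amplitude
    profiles per unordered pair. ``full``: RMS difference of the full
    2-D log-amplitude spectra. Both are symmetric, non-negative, zero
    for identical (or circularly translated) images.
    """
    if len(images) < 2:
        raise ValueError("need at least two images")
    shape = np.asarray(images[0]).shape
    for im in images[1:]:
        if np.asarray(im).shape != shape:
            raise ValueError("all images must share a shape")
    if mode == "radial":
        feats = [radial_profile(im) for im in images]
    elif mode == "full":
        feats = [
            np.log10(np.abs(np.fft.fft2(np.asarray(im, dtype=float))) + _LOG_EPS)
            for im in images
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pairs, diffs = [], []
    for i, j in itertools.combinations(range(len(images)), 2):
        d = float(np.sqrt(np.mean((feats[i] - feats[j]) ** 2)))
        pairs.append((i, j))
        diffs.append(d)
    diffs = np.array(diffs)
    return SpectrumDiff(pairs, diffs, float(diffs.mean()))


def stats_table(images: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-image statistics table (id, mean luminance, contrast, skew)."""
    rows = []
    for name, img in images.items():
        s = image_stats(img)
        rows.append(
            {
                "image": name,
                "mean_luminance": s.mean_luminance,
                "contrast": s.contrast,
                "skew": s.skew,
            }
        )
    return pd.DataFrame(rows)
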