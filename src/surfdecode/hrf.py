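"""Hemodynamic response kernels sampled on the TR grid.

Two shapes are provided:

``double_gamma``
    The canonical two-gamma BOLD impulse response (peak ~6 s, undershoot
    ~16 s, undershoot ratio 1/6), sampled at the repetition time and
    normalised to unit sum so that a sustained boxcar converges to a
    plateau of exactly the boxcar amplitude.

``delay``
    A pure shift of 4 s (two volumes at TR = 2 s) with no dispersion.
    Convolution with this kernel moves a boxcar rigidly in time, which
    makes the downstream 4-s extraction shift exactly cancel the
    hemodynamic delay — useful for validating the analysis window.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

HRF_DURATION_S = 32.0
DELAY_S = 4.0


def hrf_kernel(tr: float, kind: str = "double_gamma") -> np.ndarray:
    """Return a discrete unit-sum HRF kernel sampled every ``tr`` seconds.

    Parameters
    ----------
    tr : float
        Sampling interval (repetition time) in seconds.
    kind : {"double_gamma", "delay"}
        Kernel shape; see module docstring.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    if kind == "double_gamma":
        t = np.arange(0.0, HRF_DURATION_S + tr / 2, tr)
        h = stats.gamma.pdf(t, a=6.0) - stats.gamma.pdf(t, a=16.0) / 6.0
        s = h.sum()
        if s <= 0:  # pragma: no cover - cannot happen for sane TRs
            raise ValueError("degenerate HRF sampling")
        return h / s
    if kind == "delay":
        shift = DELAY_S / tr
        if abs(shift - round(shift)) > 1e-9:
            raise ValueError(
                f"pure-delay HRF needs the {DELAY_S}-s delay to be a "
                f"whole number of volumes; tr={tr} does not divide it"
            )
        k = np.zeros(int(round(shift)) + 1)
        k[-1] = 1.0
        return k
    raise ValueError(f"unknown HRF kind: {kind!r}")
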