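"""Canonical double-gamma hemodynamic response function.

The BOLD response to a brief neural event is modelled as the difference of
two gamma density functions: a positive lobe peaking ~5 s after the event
and a smaller, later undershoot.  The same kernel is used to generate
synthetic BOLD signal and, in Wiener deconvolution, as the delay model to
be inverted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["HRFKernel", "double_gamma_hrf"]


@dataclass(frozen=True)
class HRFKernel:
    """An HRF sampled at the acquisition rate.

    ``samples[k]`` is the response at ``t = k * tr_s``; the kernel is
    causal (zero response before the event) and its samples sum to a
    positive value.
    """

    samples: np.ndarray
    tr_s: float
    peak_delay_s: float
    undershoot_delay_s: float
    length_s: float

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.tr_s


def double_gamma_hrf(
    tr_s: float = 1.5,
    length_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    dispersion_s: float = 1.0,
    undershoot_dispersion_s: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> HRFKernel:
    """Sample the canonical double-gamma HRF at TR resolution.

    The kernel has ``ceil(length_s / tr_s) + 1`` samples at times
    ``0, tr_s, 2*tr_s, ...`` and is normalised to unit peak.  Shape
    parameters follow the common convention: gamma densities with shape
    ``delay / dispersion`` and scale ``dispersion`` for the peak and the
    undershoot, with the undershoot scaled by ``undershoot_ratio`` and
    subtracted.

    The response at t = 0 is exactly 0 and the sample closest to the true
    peak falls near 5--6 s for the default parameters.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if length_s <= 0:
        raise ValueError("length_s must be positive")
    n = math.ceil(length_s / tr_s) + 1
    t = np.arange(n) * tr_s
    peak = gamma_dist.pdf(t, peak_delay_s / dispersion_s, scale=dispersion_s)
    under = gamma_dist.pdf(
        t, undershoot_delay_s / undershoot_dispersion_s, scale=undershoot_dispersion_s
    )
    h = peak - undershoot_ratio * under
    h[0] = 0.0
    m = np.max(np.abs(h))
    if m > 0:
        h = h / m
    return HRFKernel(
        samples=h,
        tr_s=tr_s,
        peak_delay_s=peak_delay_s,
        undershoot_delay_s=undershoot_delay_s,
        length_s=length_s,
    )
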