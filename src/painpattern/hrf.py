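"""Canonical double-gamma hemodynamic response function.

One fixed analytic form (positive gamma peaking near 6 s minus an undershoot
gamma near 16 s, amplitude ratio 6) is used both by the synthetic-data
generator and by the GLM design builder, so amplitude recovery is exact in
the noise-free limit.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = ["double_gamma_hrf"]


def double_gamma_hrf(
    t: np.ndarray,
    peak_shape: float = 6.0,
    undershoot_shape: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Evaluate the canonical HRF at times ``t`` (seconds from event onset).

    Negative times map to 0. The curve is scaled so its maximum is 1, making
    injected event amplitudes directly interpretable in signal units.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, peak_shape) - _gamma.pdf(t, undershoot_shape) / ratio
    h = np.where(t < 0, 0.0, h)
    # peak of gamma.pdf(t, 6) sits at t = 5; normalize there
    peak = _gamma.pdf(peak_shape - 1.0, peak_shape) - _gamma.pdf(
        peak_shape - 1.0, undershoot_shape) / ratio
    return h / peak
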