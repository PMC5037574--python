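"""Small quantitative formulas from the accompanying cell and animal assays."""

from __future__ import annotations

import numpy as np

__all__ = [
    "tumor_volume",
    "endpoint_reached",
    "geometric_mean_intensity",
    "relative_viability",
]

ENDPOINT_VOLUME_MM3 = 300.0


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid-style caliper volume V = L * W^2 / 2 (mm^3).

    Caliper readings are orderless, so the two axes are auto-ordered with
    L the longer one before applying the asymmetric formula.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor measurements must be positive")
    L, W = max(length_mm, width_mm), min(length_mm, width_mm)
    return 0.5 * L * W**2


def endpoint_reached(volume_mm3: float, threshold: float = ENDPOINT_VOLUME_MM3) -> bool:
    """Survival end-point event: tumour volume at or above the threshold."""
    return volume_mm3 >= threshold


def geometric_mean_intensity(values) -> float:
    """Geometric mean of fluorescence intensities: exp(mean(log x)), x > 0."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty intensity list")
    if np.any(v <= 0):
        raise ValueError("geometric mean requires strictly positive intensities")
    return float(np.exp(np.mean(np.log(v))))


def relative_viability(treated_absorbances, control_absorbances) -> float:
    """Mean treated absorbance over mean vehicle-control absorbance."""
    t = np.asarray(treated_absorbances, dtype=float)
    c = np.asarray(control_absorbances, dtype=float)
    if c.size == 0 or not c.mean() > 0:
        raise ValueError("control mean absorbance must be positive")
    return float(t.mean() / c.mean())
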