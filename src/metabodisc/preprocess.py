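"""Spectral bucketing, water-region exclusion, and total-area normalization.

The pipeline order is fixed: bin -> exclude -> normalize. Bins are
left-closed half-open intervals of width 0.002 ppm anchored at the low end
of the spectral range (0.5-9.5 ppm by default); any final partial bin is
discarded so the bin count equals floor((high-low)/width). Each bin value
is the trapezoidal integral of intensity over the bin's ppm interval, which
makes binning linear in the spectrum and stable under changes of the axis
sampling density. Bins intersecting an excluded region (default the water
suppression window, 4.7-5.2 ppm) are dropped before each row is scaled to
unit total area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .simulate import Spectrum

__all__ = [
    "BinningConfig",
    "BinnedMatrix",
    "bin_spectrum",
    "exclude_regions",
    "normalize_total_area",
    "build_matrix",
    "bin_width_hz",
]

_TOL = 1e-9


@dataclass(frozen=True)
class BinningConfig:
    bin_width: float = 0.002
    range: tuple[float, float] = (0.5, 9.5)
    excluded_regions: tuple[tuple[float, float], ...] = ((4.7, 5.2),)

    def __post_init__(self) -> None:
        lo, hi = self.range
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not lo < hi:
            raise ValueError("range low must be < high")
        for rlo, rhi in self.excluded_regions:
            if not rlo < rhi:
                raise ValueError(f"excluded region ({rlo}, {rhi}) is empty")
            if rlo < lo - _TOL or rhi > hi + _TOL:
                raise ValueError(
                    f"excluded region ({rlo}, {rhi}) lies outside range {self.range}"
                )

    @property
    def n_bins(self) -> int:
        lo, hi = self.range
        return int(np.floor((hi - lo) / self.bin_width + _TOL))

    def edges(self) -> np.ndarray:
        """Bin edges (n_bins + 1,), anchored at range.low."""
        lo = self.range[0]
        return lo + self.bin_width * np.arange(self.n_bins + 1)


def bin_width_hz(config: BinningConfig, spectrometer_frequency: float) -> float:
    """Bucket width in Hz: ppm width times spectrometer frequency in MHz."""
    return config.bin_width * spectrometer_frequency


@dataclass
class BinnedMatrix:
    """Samples x bins matrix with bin-edge metadata and class labels.

    After :func:`normalize_total_area` each row sums to 1.
    """

    values: np.ndarray
    bin_edges: np.ndarray  # (n_bins, 2) left/right ppm
    sample_ids: list[str]
    class_labels: list[str]
    anchor: str = "low"  # bins anchored at range.low

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=np.round(self.bin_centers, 4)
        )


def bin_spectrum(
    spectrum: Spectrum, config: BinningConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a spectrum into fixed-width buckets.

    Returns (values, edges) where ``edges`` has shape (n_bins, 2). The
    spectrum's axis must cover the configured range.
    """
    ppm, y = spectrum.ppm, spectrum.intensity
    if ppm.ndim != 1 or ppm.shape != y.shape:
        raise ValueError("spectrum axis and intensity must be 1-D and equal length")
    if np.any(np.diff(ppm) <= 0):
        raise ValueError("spectrum ppm axis must be strictly increasing")
    edges = config.edges()
    if ppm[0] > edges[0] + _TOL or ppm[-1] < edges[-1] - _TOL:
        raise ValueError(
            f"spectrum axis [{ppm[0]:g}, {ppm[-1]:g}] does not cover the "
            f"binning interval [{edges[0]:g}, {edges[-1]:g}]"
        )
    # Cumulative trapezoidal integral evaluated at the bin edges; linear
    # interpolation of the cumulative integral is exact for edges between
    # axis points because the trapezoid rule is piecewise linear in x.
    cum = cumulative_trapezoid(y, ppm, initial=0.0)
    at_edges = np.interp(edges, ppm, cum)
    values = np.diff(at_edges)
    pairs = np.column_stack([edges[:-1], edges[1:]])
    return values, pairs


def exclude_regions(
    values: np.ndarray, edges: np.ndarray, config: BinningConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Drop every bin whose interval intersects any excluded region.

    Intersection is conservative: a bin is removed if it overlaps the region
    by any positive length. The order of the remaining bins is preserved.
    """
    keep = np.ones(len(values), dtype=bool)
    for rlo, rhi in config.excluded_regions:
        keep &= ~((edges[:, 0] < rhi - _TOL) & (edges[:, 1] > rlo + _TOL))
    if not keep.any():
        raise ValueError("no bins remain after region exclusion")
    return values[keep], edges[keep]


def normalize_total_area(values: np.ndarray) -> np.ndarray:
    """Scale a bin vector to unit total area; errors on non-positive total."""
    total = values.sum()
    if not total > 0:
        raise ValueError(f"cannot normalize: total bin area is {total:g}")
    return values / total


def build_matrix(
    spectra: list[Spectrum],
    sample_ids: list[str],
    class_labels: list[str],
    config: BinningConfig = BinningConfig(),
    normalize: bool = True,
) -> BinnedMatrix:
    """Bin, exclude and (optionally) normalize a cohort into one matrix."""
    if len(spectra) != len(sample_ids) or len(spectra) != len(class_labels):
        raise ValueError("spectra, sample_ids and class_labels must align")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicated sample ids")
    rows = []
    edges_kept = None
    for spec, sid in zip(spectra, sample_ids):
        vals, edges = bin_spectrum(spec, config)
        vals, kept = exclude_regions(vals, edges, config)
        if edges_kept is None:
            edges_kept = kept
        elif not np.allclose(kept, edges_kept):
            raise ValueError(f"sample {sid!r}: inconsistent bin edges across spectra")
        if normalize:
            vals = normalize_total_area(vals)
        rows.append(vals)
    return BinnedMatrix(
        values=np.vstack(rows),
        bin_edges=edges_kept,
        sample_ids=list(sample_ids),
        class_labels=list(class_labels),
    )
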