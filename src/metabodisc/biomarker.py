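"""Back-scaled loadings, correlation coefficients, and metabolite calls.

The discriminant model's loadings are back-transformed (multiplied by each
bin's scaling factor) so the loading plot recovers covariance-like
magnitudes and reads like a spectrum; each bin is colour-coded by |r|, its
Pearson correlation with the predictive score (a config option substitutes
the class vector). Significance uses the analytic cutoff

    r_crit = t_crit / sqrt(t_crit^2 + df)

with t_crit the two-tailed Student-t quantile. The default df = n - 1 with
n the per-group replicate count reproduces the conventional printed cutoff
0.602 at n = 10, alpha = 0.05; the textbook df = n_total - 2 is available
via the ``df`` argument.

A metabolite is called changed when the median |r| over its assigned bins
exceeds r_crit and all its significant bins agree in loading sign; the sign
maps through the class coding (positive -> increased in the +1 group).
Ties at |r| = r_crit are non-significant (strict inequality).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .opls import OplsModel, ScaledMatrix

__all__ = [
    "critical_r",
    "backscale_loadings",
    "correlation_coefficients",
    "coefficient_table",
    "call_metabolites",
    "render_coefficient_plot",
]


def critical_r(n: int, alpha: float = 0.05, df: int | None = None) -> float:
    """Critical Pearson |r| above which a bin's correlation is significant.

    ``n`` is the per-group replicate count; df defaults to n - 1.
    """
    if n < 3:
        raise ValueError("need n >= 3 replicates for a correlation cutoff")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df is None:
        df = n - 1
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def backscale_loadings(
    model: OplsModel, scaler: ScaledMatrix, basis: str = "loading"
) -> np.ndarray:
    """Multiply the predictive loading (or weight) by each column's scale.

    Restores covariance-like magnitudes so intense bins dominate the plot.
    Constant columns get exactly zero.
    """
    vec = model.p_pred if basis == "loading" else model.w
    if vec.shape[0] != scaler.column_scales.shape[0]:
        raise ValueError("model and scaler disagree on variable count")
    out = vec * scaler.column_scales
    out[scaler.constant_mask] = 0.0
    return out


def correlation_coefficients(
    X_scaled: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every column against the target (t_pred or coded y).

    Returns (r, constant_mask); constant columns carry r = 0.
    """
    X = np.asarray(X_scaled, dtype=float)
    t = np.asarray(target, dtype=float)
    if X.shape[0] != t.shape[0]:
        raise ValueError("row count mismatch between X and target")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlation coefficients")
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    constant = sx <= 1e-12
    denom = np.where(constant, 1.0, sx * st)
    r = (Xc.T @ tc) / denom
    r[constant] = 0.0
    return np.clip(r, -1.0, 1.0), constant


def coefficient_table(
    model: OplsModel,
    scaler: ScaledMatrix,
    bin_centers: np.ndarray,
    r_crit: float,
    corr_basis: str = "t_pred",
    y_coded: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bin back-scaled loadings, correlation coefficients, significance flags."""
    if corr_basis == "t_pred":
        target = model.t_pred
    elif corr_basis == "y":
        if y_coded is None:
            raise ValueError("corr_basis='y' requires y_coded")
        target = np.asarray(y_coded, dtype=float)
    else:
        raise ValueError(f"unknown correlation basis {corr_basis!r}")
    r, constant = correlation_coefficients(scaler.values, target)
    loading = backscale_loadings(model, scaler)
    return pd.DataFrame(
        {
            "ppm": np.asarray(bin_centers, dtype=float),
            "loading": loading,
            "r": r,
            "abs_r": np.abs(r),
            "significant": np.abs(r) > r_crit,
            "constant": constant,
        }
    )


def call_metabolites(
    coeffs: pd.DataFrame,
    assignments: dict[str, list[tuple[float, float]]],
    r_crit: float,
    positive_group: str = "ER",
) -> pd.DataFrame:
    """Aggregate bin-level coefficients into per-metabolite change calls.

    A metabolite is called when the median |r| over its assigned bins exceeds
    ``r_crit`` AND every significant assigned bin agrees in loading sign.
    Direction maps the shared sign through the class coding: positive loading
    means increased in the +1-coded (``positive_group``) class.

    Returns a DataFrame of the called metabolites only, sorted by median |r|.
    """
    ppm = coeffs["ppm"].to_numpy()
    rows = []
    for name, windows in assignments.items():
        mask = np.zeros(len(ppm), dtype=bool)
        for lo, hi in windows:
            in_win = (ppm >= lo) & (ppm <= hi)
            if not in_win.any():
                raise ValueError(
                    f"assignment window ({lo}, {hi}) for {name!r} overlaps no retained bin"
                )
            mask |= in_win
        sub = coeffs.loc[mask]
        median_abs_r = float(sub["abs_r"].median())
        sig = sub.loc[sub["significant"]]
        if median_abs_r <= r_crit or len(sig) == 0:
            continue
        signs = np.sign(sig["loading"].to_numpy())
        if not (np.all(signs > 0) or np.all(signs < 0)):
            continue  # conflicting directions within one metabolite: no call
        direction = "increase" if signs[0] > 0 else "decrease"
        rows.append(
            {
                "metabolite": name,
                "direction": direction,
                "median_abs_r": median_abs_r,
                "n_significant_bins": int(len(sig)),
                "positive_group": positive_group,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["metabolite", "direction", "median_abs_r",
                 "n_significant_bins", "positive_group"],
    )
    return out.sort_values("median_abs_r", ascending=False).reset_index(drop=True)


def render_coefficient_plot(
    coeffs: pd.DataFrame, r_crit: float, path: str, dpi: int = 150
) -> None:
    """Back-scaled loading vs ppm, line colour mapped to |r|, cutoff annotated.

    The ppm axis runs high-to-low (NMR display convention).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    if len(coeffs) == 0:
        raise ValueError("empty coefficient table")
    ppm = coeffs["ppm"].to_numpy()
    loading = coeffs["loading"].to_numpy()
    absr = np.clip(coeffs["abs_r"].to_numpy(), 0.0, 1.0)

    fig, ax = plt.subplots(figsize=(10, 4))
    if len(coeffs) > 1:
        pts = np.column_stack([ppm, loading]).reshape(-1, 1, 2)
        segs = np.concatenate([pts[:-1], pts[1:]], axis=1)
        lc = LineCollection(segs, cmap="jet", norm=plt.Normalize(0, 1), linewidth=0.8)
        lc.set_array((absr[:-1] + absr[1:]) / 2)
        ax.add_collection(lc)
        ax.set_xlim(ppm.max(), ppm.min())
        lo, hi = loading.min(), loading.max()
        pad = 0.05 * (hi - lo or 1.0)
        ax.set_ylim(lo - pad, hi + pad)
        fig.colorbar(lc, ax=ax, label="|r|")
    else:
        ax.scatter(ppm, loading, c=absr, cmap="jet", vmin=0, vmax=1)
        ax.invert_xaxis()
    ax.axhline(0.0, color="0.6", linewidth=0.5)
    ax.set_xlabel(r"$\delta$ (ppm)")
    ax.set_ylabel("back-scaled loading")
    ax.set_title(f"OPLS-DA coefficients (|r| cutoff = {r_crit:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
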