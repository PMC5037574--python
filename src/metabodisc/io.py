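"""Tabular text IO: wide spectra CSV, metadata, bin matrices, assignments.

Spectra travel as a wide CSV whose first column is the ppm axis and every
further column one sample. Files written here may start with ``#`` comment
lines carrying the run seed and config hash; readers skip them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import BinnedMatrix
from .simulate import GroundTruth, Spectrum

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_metadata_csv",
    "read_metadata_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_ground_truth_csv",
    "read_assignments_csv",
    "write_assignments_csv",
]


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    items = " ".join(f"{k}={v}" for k, v in provenance.items())
    return f"# {items}\n"


def write_spectra_csv(
    path,
    spectra: list[Spectrum],
    sample_ids: list[str],
    provenance: dict | None = None,
) -> None:
    if len(spectra) != len(sample_ids):
        raise ValueError("spectra/sample_ids length mismatch")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicated sample ids")
    ppm = spectra[0].ppm
    for s in spectra[1:]:
        if not np.array_equal(s.ppm, ppm):
            raise ValueError("all spectra must share one ppm axis")
    df = pd.DataFrame({"ppm": ppm})
    for sid, s in zip(sample_ids, spectra):
        df[sid] = s.intensity
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(provenance))
        df.to_csv(fh, index=False)


def read_spectra_csv(path, frequency_mhz: float = 600.0) -> tuple[list[Spectrum], list[str]]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = [c.strip() for c in line.rstrip("\n").split(",")]
                break
        else:
            raise ValueError(f"{path}: empty file")
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicated sample ids in header")
    df = pd.read_csv(path, comment="#")
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: expected a ppm column plus at least one sample")
    if df.columns[0] != "ppm":
        raise ValueError(f"{path}: first column must be 'ppm', got {df.columns[0]!r}")
    ppm = df["ppm"].to_numpy(dtype=float)
    if np.any(np.diff(ppm) <= 0):
        raise ValueError(f"{path}: ppm column must be strictly increasing")
    sample_ids = list(df.columns[1:])
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicated sample ids")
    spectra = [
        Spectrum(ppm=ppm, intensity=df[sid].to_numpy(dtype=float), frequency_mhz=frequency_mhz)
        for sid in sample_ids
    ]
    return spectra, sample_ids


def write_metadata_csv(path, sample_ids, labels, provenance=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(provenance))
        pd.DataFrame({"sample": sample_ids, "group": labels}).to_csv(fh, index=False)


def read_metadata_csv(path) -> tuple[list[str], list[str]]:
    df = pd.read_csv(path, comment="#")
    if not {"sample", "group"}.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs 'sample' and 'group' columns")
    return df["sample"].astype(str).tolist(), df["group"].astype(str).tolist()


def write_matrix_csv(path, matrix: BinnedMatrix, provenance=None) -> None:
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.sample_ids, name="sample"),
        columns=[f"{c:.4f}" for c in matrix.bin_centers],
    )
    df.insert(0, "group", matrix.class_labels)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(provenance))
        df.to_csv(fh)


def read_matrix_csv(path, bin_width: float = 0.002) -> BinnedMatrix:
    df = pd.read_csv(path, comment="#", index_col=0)
    labels = df.pop("group").astype(str).tolist()
    centers = np.array([float(c) for c in df.columns])
    half = bin_width / 2
    edges = np.column_stack([centers - half, centers + half])
    return BinnedMatrix(
        values=df.to_numpy(dtype=float),
        bin_edges=edges,
        sample_ids=[str(s) for s in df.index],
        class_labels=labels,
    )


def write_ground_truth_csv(path, truth: GroundTruth, sample_ids, provenance=None) -> None:
    levels = pd.DataFrame(
        truth.levels, index=pd.Index(sample_ids, name="sample"),
        columns=truth.metabolite_names,
    )
    perturbed = dict(truth.perturbed_set)
    header = pd.DataFrame(
        {name: [perturbed.get(name, "")] for name in truth.metabolite_names},
        index=pd.Index(["__direction__"], name="sample"),
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(provenance))
        pd.concat([header, levels]).to_csv(fh)


def write_assignments_csv(path, assignments: dict[str, list[tuple[float, float]]]) -> None:
    rows = [
        {"metabolite": name, "window_low_ppm": lo, "window_high_ppm": hi}
        for name, wins in assignments.items()
        for lo, hi in wins
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignments_csv(path) -> dict[str, list[tuple[float, float]]]:
    df = pd.read_csv(path, comment="#")
    need = {"metabolite", "window_low_ppm", "window_high_ppm"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: assignment table needs columns {sorted(need)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["metabolite"]), []).append(
            (float(row["window_low_ppm"]), float(row["window_high_ppm"]))
        )
    return out
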