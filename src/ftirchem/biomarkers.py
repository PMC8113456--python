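"""Spectral biomarker extraction from model coefficient vectors.

Candidate biomarkers are the local extrema of a PLS-DA regression
coefficient vector (or of a PCA loading vector), ranked by absolute value.
Under the 0/1 class encoding used by :func:`ftirchem.model_selection.train_plsda`,
a positive coefficient extremum marks a band whose absorbance is elevated
in the positive (active-disease) class, a negative one a band elevated in
the reference class.

Extracted peaks are annotated against a lookup table of tentative
mid-infrared band assignments for biofluids (nucleic-acid carbonyl and
phosphate bands, protein Amide I/II, lipid ester bands, phosphodiester
region); the shipped table can be extended from TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "BiomarkerPeak",
    "AssignmentTable",
    "rank_coefficient_peaks",
    "assign_bands",
    "default_assignment_table",
]


@dataclass(frozen=True)
class BiomarkerPeak:
    wavenumber: float          # cm^-1, on the analysis grid
    value: float               # coefficient (or loading) at the extremum
    direction: str             # "up" / "down" in the positive class
    rank: int                  # 1 = largest |value|
    assignment: str | None = None


# Tentative band assignments for plasma biofluid spectra, keyed by cm^-1.
_DEFAULT_ASSIGNMENTS: dict[float, str] = {
    1778.0: "nu(C=C) lipids",
    1748.0: "nu(C=C) lipids",
    1716.0: "nu(C=O) DNA/RNA",
    1701.0: "nu(C=O) thymine",
    1698.0: "C2=O guanine",
    1662.0: "Amide I",
    1654.0: "C=O, C=N, N-H of adenine, thymine, guanine, cytosine",
    1620.0: "base carbonyl stretching and ring breathing mode of nucleic acids",
    1612.0: "adenine vibration in DNA",
    1558.0: "ring base mode",
    1540.0: "protein Amide II beta-sheet",
    1509.0: "in-plane delta(CH) phenyl ring",
    1481.0: "Amide II",
    1415.0: "CH deformation",
    1408.0: "delta(CH3)",
    1358.0: "nu(C-O), delta(CH), delta(NH)",
    1230.0: "nu_as(PO2-)",
    1040.0: "symmetric PO2- stretching in RNA/DNA",
    948.0: "phosphodiester region (collagen and glycogen)",
    914.0: "phosphodiester region (collagen and glycogen)",
}


@dataclass
class AssignmentTable:
    """Wavenumber -> tentative assignment lookup with a match tolerance."""

    entries: dict[float, str] = field(default_factory=dict)
    tolerance: float = 4.0  # cm^-1; one default grid spacing

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ConfigError("tolerance must be > 0")
        self.entries = {float(k): str(v) for k, v in self.entries.items()}

    def lookup(self, wavenumber: float) -> str:
        if not self.entries:
            return "unassigned"
        centers = np.array(sorted(self.entries))
        i = int(np.argmin(np.abs(centers - wavenumber)))
        if abs(centers[i] - wavenumber) <= self.tolerance:
            return self.entries[float(centers[i])]
        return "unassigned"

    @classmethod
    def from_tsv(cls, path, tolerance: float = 4.0) -> "AssignmentTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            entries=dict(zip(df["wavenumber_cm-1"].astype(float), df["assignment"])),
            tolerance=tolerance,
        )

    def to_tsv(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"wavenumber_cm-1": sorted(self.entries),
             "assignment": [self.entries[w] for w in sorted(self.entries)]}
        ).to_csv(path, sep="\t", index=False)
        return path


def default_assignment_table(tolerance: float = 4.0) -> AssignmentTable:
    return AssignmentTable(entries=dict(_DEFAULT_ASSIGNMENTS), tolerance=tolerance)


def rank_coefficient_peaks(coef: np.ndarray, grid_values: np.ndarray,
                           top_n: int = 10) -> list[BiomarkerPeak]:
    """Local extrema of a coefficient vector, ranked by absolute value.

    An interior point is an extremum when the first difference changes sign
    across it (strict sign change, so flat stretches yield no peak). Ties
    in |value| rank by grid position. A zero vector has no extrema. If
    fewer than ``top_n`` extrema exist, all are returned with a warning.
    """
    coef = np.asarray(coef, dtype=float).ravel()
    grid_values = np.asarray(grid_values, dtype=float).ravel()
    if coef.size != grid_values.size:
        raise DataError("coefficient vector length must equal the grid length")
    d = np.diff(coef)
    is_ext = d[:-1] * d[1:] < 0
    idx = np.where(is_ext)[0] + 1
    if idx.size == 0:
        return []
    order = sorted(range(idx.size), key=lambda k: (-abs(coef[idx[k]]), k))
    if top_n > idx.size:
        warnings.warn(
            f"requested top_n={top_n} but only {idx.size} extrema exist",
            stacklevel=2,
        )
    peaks = []
    for rank, k in enumerate(order[:top_n], start=1):
        i = idx[k]
        peaks.append(
            BiomarkerPeak(
                wavenumber=float(grid_values[i]),
                value=float(coef[i]),
                direction="up" if coef[i] > 0 else "down",
                rank=rank,
            )
        )
    return peaks


def assign_bands(peaks: list[BiomarkerPeak],
                 table: AssignmentTable | None = None) -> list[BiomarkerPeak]:
    """Annotate peaks with the nearest assignment within tolerance."""
    table = table or default_assignment_table()
    return [replace(p, assignment=table.lookup(p.wavenumber)) for p in peaks]


def peaks_to_frame(peaks: list[BiomarkerPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [p.rank for p in peaks],
            "wavenumber_cm-1": [p.wavenumber for p in peaks],
            "coefficient": [p.value for p in peaks],
            "direction": [p.direction for p in peaks],
            "assignment": [p.assignment for p in peaks],
        }
    )
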