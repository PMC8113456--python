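"""Spectral dataset containers and I/O.

The central container is :class:`SpectrumSet`: a validated wavenumber grid,
an ``(n_spectra, n_points)`` absorbance matrix and a per-spectrum metadata
table. Datasets are exchanged as wide CSV/TSV matrices (with an optional
metadata sidecar TSV) or, for single spectra, as JCAMP-DX 4.24 files with
AFFN-encoded ``##XYDATA``/``##XYPOINTS`` blocks.

Mid-infrared spectra are conventionally stored on a descending grid
(e.g. 1800 -> 900 cm^-1, matching how instruments plot them); every
algorithm in the package is orientation-agnostic and the orientation is
recorded on the grid object.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GridError, MetadataError

__all__ = [
    "WavenumberGrid",
    "SpectrumSet",
    "SampleTable",
    "read_csv_matrix",
    "write_csv_matrix",
    "read_jcamp",
    "write_jcamp",
    "read_metadata",
    "write_metadata",
]

#: relative tolerance on grid-spacing uniformity
GRID_SPACING_RTOL = 1e-6

META_COLUMNS = ["spectrum_id", "sample_id", "replicate_index", "class_label", "biofluid"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniformly spaced wavenumber axis in cm^-1, stored ascending or descending."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavenumber values")
        if np.any(v <= 0):
            raise GridError("wavenumbers must be strictly positive")
        d = np.diff(v)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            pass
        else:
            raise GridError("grid must be strictly monotone")
        step = d[0]
        if np.any(np.abs(d - step) > GRID_SPACING_RTOL * abs(step)):
            raise GridError(
                "grid spacing is not uniform within tolerance "
                f"(rel tol {GRID_SPACING_RTOL:g})"
            )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def ascending(self) -> bool:
        return bool(self.values[1] > self.values[0])

    @property
    def spacing(self) -> float:
        """Absolute nominal spacing in cm^-1."""
        return float(abs(self.values[1] - self.values[0]))

    @property
    def signed_spacing(self) -> float:
        return float(self.values[1] - self.values[0])


def _default_meta(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "sample_id": [f"s{i}" for i in range(n)],
            "replicate_index": np.ones(n, dtype=int),
            "class_label": [None] * n,
            "biofluid": [None] * n,
        }
    )


@dataclass
class SpectrumSet:
    """A set of spectra on a common grid with per-spectrum metadata.

    ``meta`` always carries the columns ``spectrum_id``, ``sample_id``,
    ``replicate_index``, ``class_label`` and ``biofluid`` (plus any extra
    columns); unmatched metadata fields are ``None`` rather than an error so
    that I/O is fail-soft and modelling fails hard later.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self):
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != self.grid.n:
            raise MetadataError(
                f"absorbance has {self.absorbance.shape[1]} columns "
                f"but the grid has {self.grid.n} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise MetadataError("absorbance matrix contains non-finite values")
        if self.meta is None:
            self.meta = _default_meta(self.n_spectra)
        self.meta = self.meta.reset_index(drop=True)
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = None if col != "replicate_index" else 1
        if len(self.meta) != self.n_spectra:
            raise MetadataError(
                f"{len(self.meta)} metadata rows for {self.n_spectra} spectra"
            )
        ids = self.meta["spectrum_id"]
        if ids.duplicated().any():
            raise MetadataError("spectrum_id values must be unique")
        rep = pd.to_numeric(self.meta["replicate_index"], errors="coerce")
        if (rep.fillna(1) < 1).any():
            raise MetadataError("replicate_index must be >= 1")

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def spectrum_ids(self) -> list[str]:
        return list(self.meta["spectrum_id"])

    def copy_with(self, absorbance=None, grid=None, meta=None) -> "SpectrumSet":
        return SpectrumSet(
            grid=grid if grid is not None else self.grid,
            absorbance=absorbance if absorbance is not None else self.absorbance.copy(),
            meta=(meta if meta is not None else self.meta).copy(),
        )


@dataclass
class SampleTable:
    """Per-sample metadata: class label plus typed clinical variables.

    ``variable_types`` declares every clinical column as ``"continuous"``
    or ``"categorical"``; downstream correlation code refuses undeclared
    variables.
    """

    data: pd.DataFrame
    variable_types: dict[str, str] = field(default_factory=dict)
    label_set: tuple[str, ...] = ()

    def __post_init__(self):
        if "sample_id" not in self.data.columns or "class_label" not in self.data.columns:
            raise MetadataError("SampleTable needs sample_id and class_label columns")
        if self.data["sample_id"].duplicated().any():
            raise MetadataError("sample_id values must be unique")
        for name, kind in self.variable_types.items():
            if name not in self.data.columns:
                raise MetadataError(f"declared clinical variable {name!r} missing")
            if kind not in ("continuous", "categorical"):
                raise MetadataError(f"unknown variable type {kind!r} for {name!r}")
        if self.label_set:
            labels = self.data["class_label"].dropna()
            bad = set(labels) - set(self.label_set)
            if bad:
                raise MetadataError(f"class labels {sorted(bad)} outside declared set")

    def variable(self, name: str) -> pd.Series:
        if name not in self.variable_types:
            raise MetadataError(f"variable {name!r} has no declared type")
        return self.data.set_index("sample_id")[name]


# ---------------------------------------------------------------------------
# CSV / TSV matrices
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.tsv")


def _fmt(x: float) -> str:
    return repr(float(x))


def read_csv_matrix(path, orientation_hint: str = "columns") -> SpectrumSet:
    """Read a wide spectral matrix.

    ``orientation_hint="columns"``: first column holds wavenumbers
    (header ``wavenumber_cm-1``), one column per spectrum.
    ``orientation_hint="rows"``: first column holds spectrum ids, header row
    holds wavenumbers. A ``<name>.meta.tsv`` sidecar, if present, is joined
    on ``spectrum_id``; unmatched spectra keep null metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # ragged rows, bad tokens
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if orientation_hint == "columns":
        wn = pd.to_numeric(df.iloc[:, 0], errors="coerce")
        if wn.isna().any():
            raise FormatError("non-numeric wavenumber column")
        ids = [str(c) for c in df.columns[1:]]
        body = df.iloc[:, 1:].to_numpy(dtype=float).T
        grid = WavenumberGrid(wn.to_numpy())
    elif orientation_hint == "rows":
        try:
            wn = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise FormatError("header row is not numeric wavenumbers") from exc
        ids = [str(x) for x in df.iloc[:, 0]]
        body = df.iloc[:, 1:].to_numpy(dtype=float)
        grid = WavenumberGrid(wn)
    else:
        raise FormatError(f"unknown orientation_hint {orientation_hint!r}")
    if not np.all(np.isfinite(body)):
        raise FormatError("spectral matrix contains missing/non-numeric cells")
    meta = _default_meta(len(ids))
    meta["spectrum_id"] = ids
    meta["sample_id"] = ids
    sc = _sidecar_path(path)
    if sc.exists():
        side = read_metadata(sc)
        if len(side) and len(meta):
            meta = meta[["spectrum_id"]].merge(side, on="spectrum_id", how="left")
            if "sample_id" in meta.columns:
                meta["sample_id"] = meta["sample_id"].fillna(meta["spectrum_id"])
    return SpectrumSet(grid=grid, absorbance=body, meta=meta)


def write_csv_matrix(sset: SpectrumSet, path, write_sidecar: bool = True) -> Path:
    """Write in ``columns`` orientation, wavenumbers in stored grid order.

    Values are written with shortest round-trip ``repr`` so a write/read
    cycle is bit-identical.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["wavenumber_cm-1"] + [str(s) for s in sset.spectrum_ids]))
        fh.write("\n")
        for j in range(sset.grid.n):
            row = [_fmt(sset.grid.values[j])] + [
                _fmt(v) for v in sset.absorbance[:, j]
            ]
            fh.write(sep.join(row))
            fh.write("\n")
    if write_sidecar:
        write_metadata(sset.meta, _sidecar_path(path))
    return path


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "spectrum_id" not in df.columns:
        raise FormatError("metadata sidecar lacks a spectrum_id column")
    df["spectrum_id"] = df["spectrum_id"].astype(str)
    return df


def write_metadata(meta: pd.DataFrame, path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# JCAMP-DX (AFFN only)
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")


def _parse_jcamp_labels(text: str):
    """Split a JCAMP file into (label -> scalar value) and data blocks."""
    labels: dict[str, str] = {}
    data_label = None
    data_lines: list[str] = []
    for line in text.splitlines():
        line = line.split("$$")[0].rstrip()
        if not line.strip():
            continue
        m = _LABEL_RE.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "").replace("-", "").replace("_", "")
            val = m.group(2).strip()
            if key in ("XYDATA", "XYPOINTS"):
                data_label = (key, val)
                data_lines = []
            else:
                labels[key] = val
        elif data_label is not None:
            data_lines.append(line)
    return labels, data_label, data_lines


def read_jcamp(path) -> SpectrumSet:
    """Read a single AFFN-encoded JCAMP-DX spectrum.

    Supports ``##XYDATA=(X++(Y..Y))`` and ``##XYPOINTS=(XY..XY)``. SQZ/DIF
    compressed files are out of scope and raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    labels, data_label, data_lines = _parse_jcamp_labels(path.read_text(encoding="utf-8"))
    if data_label is None:
        raise FormatError("no ##XYDATA or ##XYPOINTS block")
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in labels:
            raise FormatError(f"missing required label ##{req}")
    firstx = float(labels["FIRSTX"])
    lastx = float(labels["LASTX"])
    npoints = int(float(labels["NPOINTS"]))
    yfactor = float(labels.get("YFACTOR", "1"))
    xfactor = float(labels.get("XFACTOR", "1"))
    title = labels.get("TITLE", path.stem) or path.stem

    kind, form = data_label
    num_re = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
    if kind == "XYDATA":
        if any(c in "".join(data_lines) for c in "ABCDEFGHIJKLMNOPQRSabcdefghijklmnopqrs%@"):
            raise FormatError("compressed (SQZ/DIF) JCAMP data is not supported")
        ys: list[float] = []
        for line in data_lines:
            nums = [float(t) for t in num_re.findall(line)]
            if not nums:
                continue
            ys.extend(nums[1:])  # first number on each line is the X check value
        y = np.array(ys)
    else:  # XYPOINTS: X, Y pairs
        nums = [float(t) for ln in data_lines for t in num_re.findall(ln)]
        if len(nums) % 2:
            raise FormatError("odd token count in ##XYPOINTS block")
        y = np.array(nums[1::2])
    if y.size != npoints:
        raise FormatError(f"##NPOINTS={npoints} but decoded {y.size} Y values")
    grid = WavenumberGrid(np.linspace(firstx * xfactor, lastx * xfactor, npoints))
    meta = _default_meta(1)
    meta.loc[0, ["spectrum_id", "sample_id"]] = [title, title]
    return SpectrumSet(grid=grid, absorbance=(y * yfactor)[None, :], meta=meta)


def write_jcamp(sset: SpectrumSet, path, index: int = 0) -> Path:
    """Write one spectrum of the set as AFFN ``##XYDATA=(X++(Y..Y))``."""
    path = Path(path)
    g = sset.grid.values
    y = sset.absorbance[index]
    lines = [
        f"##TITLE={sset.spectrum_ids[index]}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={_fmt(g[0])}",
        f"##LASTX={_fmt(g[-1])}",
        f"##NPOINTS={g.size}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        "##XYDATA=(X++(Y..Y))",
    ]
    for j in range(g.size):
        lines.append(f"{_fmt(g[j])} {_fmt(y[j])}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
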