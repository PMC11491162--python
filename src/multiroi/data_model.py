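"""Domain types and readers for cell tables and outcome tables.

A *cell table* is delimited text with one row per detected cell, carrying a
sample identifier, a region-of-interest (ROI) identifier, x/y coordinates in
microns, and a categorical phenotype.  Optional metadata columns describe the
rectangular observation window of each ROI; when absent, the window defaults
to the bounding box of the ROI's cells.

An *outcome table* carries one row per sample with either a survival pair
(time, event) or a binary label, plus optional numeric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CellTableParseError, ConfigurationError

__all__ = [
    "Window",
    "PointPattern",
    "ROISummary",
    "SampleSummarySet",
    "OutcomeTable",
    "read_cell_table",
    "write_cell_table",
    "read_outcome_table",
    "filter_low_count_rois",
    "log1p_transform",
    "DEFAULT_COLUMNS",
]

#: default cell-table column names; override via ``column_map``
DEFAULT_COLUMNS = {
    "sample": "sample_id",
    "roi": "roi_id",
    "x": "x",
    "y": "y",
    "phenotype": "phenotype",
    "xmin": "xmin",
    "xmax": "xmax",
    "ymin": "ymin",
    "ymax": "ymax",
}

_WINDOW_KEYS = ("xmin", "xmax", "ymin", "ymax")


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window in microns."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"window must have positive extent, got {self}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )


@dataclass
class PointPattern:
    """A marked 2D point set observed in one ROI.

    Coordinates are continuous microns.  Duplicate coordinates are allowed
    (two cell centroids may coincide after segmentation rounding); such pairs
    sit at distance zero.
    """

    x: np.ndarray
    y: np.ndarray
    marks: np.ndarray
    window: Window
    sample_id: str = ""
    roi_id: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.marks = np.asarray(self.marks)
        if not (len(self.x) == len(self.y) == len(self.marks)):
            raise ValueError("x, y, and marks must have equal length")
        inside = self.window.contains(self.x, self.y)
        if not bool(np.all(inside)):
            bad = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"point {bad} at ({self.x[bad]}, {self.y[bad]}) lies outside "
                f"window {self.window} (sample={self.sample_id!r}, roi={self.roi_id!r})"
            )

    def __len__(self) -> int:
        return len(self.x)

    def n_cells(self, mark=None) -> int:
        """Number of cells, optionally restricted to one phenotype."""
        if mark is None:
            return len(self)
        return int(np.sum(self.marks == mark))

    def coords(self, mark=None) -> np.ndarray:
        """(n, 2) coordinate array, optionally restricted to one phenotype."""
        if mark is None:
            return np.column_stack([self.x, self.y])
        sel = self.marks == mark
        return np.column_stack([self.x[sel], self.y[sel]])


@dataclass
class ROISummary:
    """A spatial summary (K or L) evaluated on a radius grid for one ROI."""

    radii: np.ndarray
    value: np.ndarray
    n_cells: int
    area: float
    sample_id: str = ""
    roi_id: str = ""
    statistic: str = "K"
    marks: tuple = ()

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.radii.ndim != 1 or self.value.shape != self.radii.shape:
            raise ValueError("value vector must match the radius grid")
        if len(self.radii) and (
            self.radii[0] < 0 or np.any(np.diff(self.radii) <= 0)
        ):
            raise ValueError("radii must be non-negative and strictly increasing")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.area <= 0:
            raise ValueError("area must be positive")

    @property
    def intensity(self) -> float:
        """Estimated intensity: cells per unit area."""
        return self.n_cells / self.area


@dataclass
class SampleSummarySet:
    """All ROI summaries belonging to one sample; the unit being aggregated."""

    sample_id: str
    summaries: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.summaries) < 1:
            raise ValueError("a sample needs at least one ROI summary")
        grid = self.summaries[0].radii
        for s in self.summaries[1:]:
            if s.radii.shape != grid.shape or not np.array_equal(s.radii, grid):
                raise ValueError(
                    f"summaries of sample {self.sample_id!r} do not share a radius grid"
                )

    def __len__(self) -> int:
        return len(self.summaries)

    @property
    def radii(self) -> np.ndarray:
        return self.summaries[0].radii

    def values_matrix(self) -> np.ndarray:
        """(R_i, n_radii) matrix of summary values."""
        return np.vstack([s.value for s in self.summaries])

    def counts(self) -> np.ndarray:
        return np.array([s.n_cells for s in self.summaries], dtype=float)

    def areas(self) -> np.ndarray:
        return np.array([s.area for s in self.summaries], dtype=float)


class OutcomeTable:
    """Per-sample endpoint (survival or binary) plus optional covariates.

    Parameters
    ----------
    data
        One row per sample.  Must contain ``sample_id`` plus either
        (``time``, ``event``) columns for survival or a ``label`` column for
        a binary endpoint.  Remaining numeric columns are usable covariates.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        if "sample_id" not in data.columns:
            raise ConfigurationError("outcome table needs a 'sample_id' column")
        if data["sample_id"].duplicated().any():
            dup = data.loc[data["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ConfigurationError(f"duplicate sample_id {dup!r} in outcome table")
        if {"time", "event"}.issubset(data.columns):
            self.outcome_type = "survival"
            times = pd.to_numeric(data["time"])
            if (times <= 0).any():
                raise ConfigurationError("survival times must be positive")
            events = data["event"].astype(int)
            if not events.isin([0, 1]).all():
                raise ConfigurationError("event indicators must be 0/1")
        elif "label" in data.columns:
            self.outcome_type = "binary"
            labels = data["label"].astype(int)
            if not labels.isin([0, 1]).all():
                raise ConfigurationError("binary labels must be 0/1")
        else:
            raise ConfigurationError(
                "outcome table needs either (time, event) or a label column"
            )
        data["sample_id"] = data["sample_id"].astype(str)
        self.data = data.set_index("sample_id", drop=False)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    def covariate_columns(self) -> list:
        reserved = {"sample_id", "time", "event", "label"}
        return [c for c in self.data.columns if c not in reserved]

    def aligned(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Rows reordered to ``sample_ids``; missing samples raise."""
        ids = [str(s) for s in sample_ids]
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise ConfigurationError(
                f"samples missing from outcome table: {missing[:5]}"
            )
        return self.data.loc[ids]


def _resolve_columns(column_map: Mapping[str, str] | None) -> dict:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"unknown column_map keys: {sorted(unknown)}; "
                f"expected a subset of {sorted(DEFAULT_COLUMNS)}"
            )
        cols.update(column_map)
    return cols


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _numeric_column(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CellTableParseError(
            f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
            f"at row {row}",
            row=row,
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise CellTableParseError(f"missing value in column {col!r} at row {row}", row=row)
    return vals.to_numpy(dtype=float)


def read_cell_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    window_source: str = "metadata",
) -> list:
    """Read a delimited cell table into one :class:`PointPattern` per (sample, ROI).

    Parameters
    ----------
    path
        CSV (or TSV, by extension) file.
    column_map
        Optional mapping from logical names (``sample``, ``roi``, ``x``, ``y``,
        ``phenotype``, ``xmin``...) to the file's column names.
    window_source
        ``"metadata"`` uses the window columns when all four are present and
        falls back to the bounding box; ``"bounding_box"`` always uses the
        bounding box of the ROI's cells.
    """
    if window_source not in {"metadata", "bounding_box"}:
        raise ConfigurationError(
            f"window_source must be 'metadata' or 'bounding_box', got {window_source!r}"
        )
    cols = _resolve_columns(column_map)
    df = _read_delimited(path)

    required = {k: cols[k] for k in ("sample", "roi", "x", "y", "phenotype")}
    missing = [name for name in required.values() if name not in df.columns]
    if missing:
        raise ConfigurationError(
            f"cell table {path} is missing required column(s): {missing}"
        )

    x = _numeric_column(df, cols["x"])
    y = _numeric_column(df, cols["y"])
    df = df.assign(__x=x, __y=y)

    have_window = window_source == "metadata" and all(
        cols[k] in df.columns for k in _WINDOW_KEYS
    )

    patterns = []
    for (sample, roi), grp in df.groupby(
        [cols["sample"], cols["roi"]], sort=True
    ):
        gx = grp["__x"].to_numpy()
        gy = grp["__y"].to_numpy()
        if have_window:
            window = Window(
                float(grp[cols["xmin"]].iloc[0]),
                float(grp[cols["xmax"]].iloc[0]),
                float(grp[cols["ymin"]].iloc[0]),
                float(grp[cols["ymax"]].iloc[0]),
            )
        else:
            # pad degenerate extents (single cell or collinear cells) so the
            # window keeps a positive area; such ROIs are normally removed by
            # filter_low_count_rois anyway
            x_lo, x_hi = gx.min(), gx.max()
            y_lo, y_hi = gy.min(), gy.max()
            if x_hi == x_lo:
                x_lo, x_hi = x_lo - 0.5, x_hi + 0.5
            if y_hi == y_lo:
                y_lo, y_hi = y_lo - 0.5, y_hi + 0.5
            window = Window(x_lo, x_hi, y_lo, y_hi)
        patterns.append(
            PointPattern(
                x=gx,
                y=gy,
                marks=grp[cols["phenotype"]].to_numpy(),
                window=window,
                sample_id=str(sample),
                roi_id=str(roi),
            )
        )
    return patterns


def write_cell_table(
    patterns: Iterable[PointPattern],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write patterns to a delimited cell table (round-trips with the reader)."""
    cols = _resolve_columns(column_map)
    rows = []
    for p in patterns:
        for xi, yi, mi in zip(p.x, p.y, p.marks):
            rows.append(
                {
                    cols["sample"]: p.sample_id,
                    cols["roi"]: p.roi_id,
                    cols["x"]: xi,
                    cols["y"]: yi,
                    cols["phenotype"]: mi,
                    cols["xmin"]: p.window.x_min,
                    cols["xmax"]: p.window.x_max,
                    cols["ymin"]: p.window.y_min,
                    cols["ymax"]: p.window.y_max,
                }
            )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    # %.17g round-trips doubles exactly
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_outcome_table(path: str | Path) -> OutcomeTable:
    """Read a per-sample outcome CSV into an :class:`OutcomeTable`."""
    return OutcomeTable(_read_delimited(path))


def filter_low_count_rois(
    patterns: Sequence[PointPattern],
    mark,
    min_cells: int = 2,
) -> tuple:
    """Partition patterns into (kept, removed) by per-mark cell count.

    ROIs with fewer than ``min_cells`` cells of the requested phenotype are
    removed.  For a phenotype pair, an ROI must have at least ``min_cells``
    of *each* phenotype to be kept.  The default of 2 drops ROIs on which a
    pairwise summary is undefined or degenerate.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be non-negative")
    marks = mark if isinstance(mark, (tuple, list)) else (mark,)
    kept, removed = [], []
    for p in patterns:
        if all(p.n_cells(m) >= min_cells for m in marks):
            kept.append(p)
        else:
            removed.append(p)
    return kept, removed


def log1p_transform(values) -> np.ndarray:
    """Elementwise log(1 + x) used to normalize right-skewed summary values."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log1p_transform requires non-negative values")
    return np.log1p(arr)
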