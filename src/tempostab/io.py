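"""Domain containers and plain-text I/O.

Parcellated BOLD series travel as delimited text (regions x time by default,
optionally transposed on disk), connectivity/stability matrices as CSV, and
network definitions as JSON/YAML mapping a network name to 1-based atlas
indices. All user-facing region and timepoint indices are 1-based, matching
the AAL atlas convention; arrays are 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CONDITIONS",
    "BoldTimeSeries",
    "SubjectTable",
    "NetworkDefinition",
    "read_timeseries",
    "read_subject_table",
    "read_network_definition",
    "default_networks",
    "read_matrix",
    "write_matrix",
]

CONDITIONS = ("rest", "movie", "smt", "synthetic")

MIN_REGIONS = 2
MIN_TIMEPOINTS = 8


class DimensionError(ValueError):
    """Input has too few regions or timepoints for the pipeline."""


class ParseError(ValueError):
    """Malformed on-disk input."""


@dataclass
class BoldTimeSeries:
    """Parcellated BOLD signal: one row per region, one column per timepoint.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_timepoints)
        Regional mean BOLD signal in arbitrary scanner units.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    region_labels : list of str, optional
        Unique region names; generated as ``ROI001...`` when omitted.
    subject_id : str
    condition : str
        One of ``rest``, ``movie``, ``smt``, ``synthetic``.
    """

    values: np.ndarray
    tr_seconds: float
    region_labels: list[str] | None = None
    subject_id: str = "unknown"
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError(
                f"expected a 2-D regions x time matrix, got shape {self.values.shape}"
            )
        n, t = self.values.shape
        if n < MIN_REGIONS:
            raise DimensionError(f"need at least {MIN_REGIONS} regions, got {n}")
        if t < MIN_TIMEPOINTS:
            raise DimensionError(f"need at least {MIN_TIMEPOINTS} timepoints, got {t}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value at region {bad[0] + 1}, timepoint {bad[1] + 1}"
            )
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.region_labels is None:
            self.region_labels = [f"ROI{i + 1:03d}" for i in range(n)]
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n} regions"
            )
        if len(set(self.region_labels)) != n:
            raise ValueError("region_labels must be unique")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.tr_seconds


@dataclass
class SubjectTable:
    """Cohort manifest: one row per (subject, condition) with a file path.

    ``frame`` columns: subject_id, age_years, condition, path. A subject may
    appear once per condition; ages must lie in the adult lifespan range
    [18, 88] used throughout the cohort analysis.
    """

    frame: pd.DataFrame
    age_range: tuple[float, float] = (18.0, 88.0)

    def __post_init__(self) -> None:
        required = {"subject_id", "age_years", "condition", "path"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        dup = self.frame.duplicated(["subject_id", "condition"])
        if dup.any():
            ids = self.frame.loc[dup, "subject_id"].tolist()
            raise ValueError(f"duplicate (subject, condition) rows: {ids}")
        ages = self.frame.groupby("subject_id")["age_years"].nunique()
        if (ages > 1).any():
            raise ValueError(
                f"inconsistent ages for subjects: {ages[ages > 1].index.tolist()}"
            )
        lo, hi = self.age_range
        bad = self.frame[
            (self.frame.age_years < lo) | (self.frame.age_years > hi)
        ]
        if len(bad):
            raise ValueError(
                f"ages outside [{lo}, {hi}] for subjects "
                f"{sorted(bad.subject_id.unique().tolist())}"
            )

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.frame.subject_id.unique().tolist())

    def ages(self) -> pd.Series:
        return self.frame.groupby("subject_id")["age_years"].first()


KNOWN_NETWORKS = ("DMN", "CEN", "SM", "salience", "visual", "whole_brain")


@dataclass
class NetworkDefinition:
    """A named resting-state network as an ordered set of 1-based atlas indices."""

    name: str
    region_indices: list[int] = field(default_factory=list)
    n_atlas_regions: int | None = None

    def __post_init__(self) -> None:
        idx = [int(i) for i in self.region_indices]
        if len(idx) < 4:
            raise ValueError(
                f"network {self.name!r} has {len(idx)} regions; need >= 4 "
                "(a k=3 subspace needs at least 4 rows)"
            )
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate region indices in network {self.name!r}")
        if min(idx) < 1:
            raise ValueError(
                f"network {self.name!r}: indices are 1-based, got {min(idx)}"
            )
        if self.n_atlas_regions is not None and max(idx) > self.n_atlas_regions:
            raise ValueError(
                f"network {self.name!r}: index {max(idx)} exceeds atlas size "
                f"{self.n_atlas_regions}"
            )
        self.region_indices = idx

    def zero_based(self) -> np.ndarray:
        return np.asarray(self.region_indices, dtype=int) - 1


def read_timeseries(
    path: str | Path,
    layout: str = "regions_by_time",
    tr_seconds: float = 2.0,
    subject_id: str | None = None,
    condition: str = "synthetic",
) -> BoldTimeSeries:
    """Read a delimited numeric matrix and orient it to regions x time.

    The file may carry a single header row of region labels (detected by
    non-numeric cells in the first row). ``layout`` declares the on-disk
    orientation: ``regions_by_time`` (default) or ``time_by_regions``.
    """
    path = Path(path)
    if layout not in ("regions_by_time", "time_by_regions"):
        raise ValueError(f"unknown layout {layout!r}")
    if not path.exists():
        raise FileNotFoundError(f"time-series file not found: {path}")
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    rows: list[list[str]] = []
    for line in text.splitlines():
        if line.strip():
            rows.append([c.strip() for c in line.split(sep)])
    if not rows:
        raise ParseError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise ParseError(f"{path}: ragged row at line {bad + 1}")

    def _numeric_row(cells: Sequence[str]) -> bool:
        try:
            [float(c) for c in cells]
            return True
        except ValueError:
            return False

    labels = None
    if not _numeric_row(rows[0]):
        labels = list(rows[0])
        rows = rows[1:]
        if not rows:
            raise ParseError(f"{path}: header but no data rows")
    data = np.empty((len(rows), len(rows[0])), dtype=float)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 1}, "
                    f"column {j + 1}"
                ) from None
    if layout == "time_by_regions":
        data = data.T
        # header labelled columns = regions in this layout, so labels carry over
    elif labels is not None:
        # header in regions_by_time layout labels timepoints; discard
        labels = None
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ParseError(
            f"{path}: non-finite value at row {bad[0] + 1}, column {bad[1] + 1}"
        )
    return BoldTimeSeries(
        values=data,
        tr_seconds=tr_seconds,
        region_labels=labels,
        subject_id=subject_id or path.stem,
        condition=condition,
    )


def read_subject_table(path: str | Path, **kwargs) -> SubjectTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"subject table not found: {path}")
    return SubjectTable(pd.read_csv(path), **kwargs)


def read_network_definition(
    path: str | Path, n_atlas_regions: int | None = 116
) -> list[NetworkDefinition]:
    """Load network definitions from a JSON or YAML mapping name -> indices."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network definition file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise ParseError(f"{path}: expected a mapping of network name to indices")
    out = []
    for name, idx in mapping.items():
        out.append(
            NetworkDefinition(
                name=str(name),
                region_indices=list(idx),
                n_atlas_regions=n_atlas_regions,
            )
        )
    return out


def default_networks() -> list[NetworkDefinition]:
    """The bundled AAL-116 resting-state network memberships.

    This is a reference reconstruction assembled from the standard AAL
    region ordering (see the comments in ``data/aal116_networks.yaml``);
    edit or replace the file for other conventions.
    """
    from importlib import resources

    with resources.files("tempostab.data").joinpath("aal116_networks.yaml").open() as fh:
        mapping = yaml.safe_load(fh)
    return [
        NetworkDefinition(name=k, region_indices=v, n_atlas_regions=116)
        for k, v in mapping.items()
    ]


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a finite real matrix as CSV at full double precision."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries")
    path = Path(path)
    try:
        np.savetxt(path, np.atleast_2d(matrix), delimiter=",", fmt="%.17g")
    except OSError as err:
        raise OSError(f"failed writing matrix to {path}: {err}") from err


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    except ValueError as err:
        raise ParseError(f"{path}: {err}") from err
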