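"""Shared data model, CSV I/O, validation, and run configuration.

All multivariate time series in this package are stored as real matrices of
shape ``(n_variables, n_timesteps)``: axis 0 indexes channels (people,
sensors, body parts), axis 1 indexes uniformly sampled time.  Every function
that consumes a series accepts either a :class:`MultivariateTimeSeries` or a
bare array in that orientation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("groupsync")


class GroupSyncError(ValueError):
    """Base class for all errors raised by this package."""


class ParameterError(GroupSyncError):
    """A parameter value violates a precondition (radius, segment length...)."""


class ValidationError(GroupSyncError):
    """Input data violate a structural contract (shape, finiteness...)."""


class ParseError(GroupSyncError):
    """A CSV cell could not be interpreted as a number."""


class DegenerateSignalError(GroupSyncError):
    """A channel is constant where a non-degenerate signal is required."""


@dataclass
class MultivariateTimeSeries:
    """A real-valued multichannel recording sampled at a uniform rate.

    Parameters
    ----------
    values
        Matrix of shape ``(n_variables, n_timesteps)``.
    sample_interval
        Seconds between successive samples (default 1.0; only used for
        unit conversion, never for resampling).
    labels
        Optional per-channel identifiers.
    """

    values: np.ndarray
    sample_interval: float = 1.0
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"expected a 2-D (n_variables, n_timesteps) matrix, got ndim={self.values.ndim}"
            )
        n_var, n_t = self.values.shape
        if n_var < 2:
            raise ValidationError(f"a multivariate series needs >= 2 variables, got {n_var}")
        if n_t < 3:
            raise ValidationError(f"a series needs >= 3 time steps, got {n_t}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at variable {bad[0]}, time step {bad[1]}"
            )
        if self.sample_interval <= 0:
            raise ValidationError("sample_interval must be positive")
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != n_var:
                raise ValidationError(
                    f"{len(self.labels)} labels for {n_var} variables"
                )

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]


def as_array(series) -> np.ndarray:
    """Return the (n_variables, n_timesteps) float matrix behind *series*.

    Accepts a :class:`MultivariateTimeSeries` or any array-like already in
    variables-by-time orientation.
    """
    if isinstance(series, MultivariateTimeSeries):
        return series.values
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"expected 2-D (variables, time) data, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite values in input")
    return arr


@dataclass
class SampleCollection:
    """An ordered sample of recordings sharing one variable count.

    Time lengths may differ between members; all variables within one member
    share that member's length by construction.
    """

    series: list[MultivariateTimeSeries]
    n_variables: int

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[MultivariateTimeSeries]:
        return iter(self.series)

    def __getitem__(self, i: int) -> MultivariateTimeSeries:
        return self.series[i]

    @property
    def equal_length(self) -> bool:
        lengths = {s.n_timesteps for s in self.series}
        return len(lengths) == 1

    def stack(self) -> np.ndarray:
        """Stack into a (n_members, n_variables, n_timesteps) array.

        Requires all members to share one time length.
        """
        if not self.equal_length:
            raise ValidationError("members have unequal time lengths; cannot stack")
        return np.stack([s.values for s in self.series])


def validate_collection(series_list: Sequence[MultivariateTimeSeries]) -> SampleCollection:
    """Check that every member shares one variable count and build a collection."""
    if len(series_list) == 0:
        raise ValidationError("empty collection")
    members = [
        s if isinstance(s, MultivariateTimeSeries) else MultivariateTimeSeries(np.asarray(s))
        for s in series_list
    ]
    n_vars = members[0].n_variables
    offending = [i for i, s in enumerate(members) if s.n_variables != n_vars]
    if offending:
        raise ValidationError(
            f"members {offending} have a variable count different from member 0 ({n_vars})"
        )
    return SampleCollection(series=members, n_variables=n_vars)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _locate_bad_cell(frame: pd.DataFrame) -> tuple[int, int, str]:
    for (r, c), cell in np.ndenumerate(frame.values):
        try:
            float(cell)
        except (TypeError, ValueError):
            return r, c, str(cell)
    raise AssertionError("no bad cell found")  # pragma: no cover


def read_time_series(
    path: str | Path,
    layout: str = "rows",
    sample_interval: float = 1.0,
) -> MultivariateTimeSeries:
    """Read a numeric CSV into a variables-by-time matrix.

    ``layout="rows"`` means one variable per row on disk (the package
    default); ``layout="columns"`` means one variable per column.  A leading
    column (rows layout) or leading row (columns layout) of non-numeric cells
    is treated as channel labels.
    """
    if layout not in ("rows", "columns"):
        raise ParameterError(f"layout must be 'rows' or 'columns', got {layout!r}")
    try:
        frame = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"ragged or malformed CSV {path}: {exc}") from exc
    if frame.isna().any().any():
        r = int(frame.isna().any(axis=1).idxmax())
        raise ValidationError(f"ragged CSV {path}: row {r} is shorter than the first row")
    if layout == "columns":
        frame = frame.T.reset_index(drop=True)
        frame.columns = range(frame.shape[1])

    labels = None
    first_col = frame.iloc[:, 0]

    def _numeric(x: str) -> bool:
        try:
            float(x)
            return True
        except (TypeError, ValueError):
            return False

    if not all(_numeric(x) for x in first_col):
        if all(not _numeric(x) for x in first_col):
            labels = [str(x) for x in first_col]
            frame = frame.iloc[:, 1:]
        # mixed numeric/non-numeric first column falls through to the
        # cell-level error below, which names the offending cell
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        r, c, cell = _locate_bad_cell(frame)
        raise ParseError(
            f"non-numeric value {cell!r} at row {r}, column {c} of {path}"
        ) from None
    return MultivariateTimeSeries(values, sample_interval=sample_interval, labels=labels)


def write_time_series(
    series: MultivariateTimeSeries | np.ndarray,
    path: str | Path,
    layout: str = "rows",
) -> None:
    """Write a series as CSV such that :func:`read_time_series` inverts it exactly.

    Floats are rendered with Python's shortest round-trip representation, so
    a write/read cycle reproduces the matrix bit for bit.
    """
    if layout not in ("rows", "columns"):
        raise ParameterError(f"layout must be 'rows' or 'columns', got {layout!r}")
    if isinstance(series, MultivariateTimeSeries):
        values, labels = series.values, series.labels
    else:
        values, labels = as_array(series), None
    frame = pd.DataFrame(values)
    if layout == "rows":
        if labels is not None:
            frame.index = labels
        frame.to_csv(path, header=False, index=labels is not None)
    else:
        frame = frame.T
        if labels is not None:
            frame.columns = labels
        frame.to_csv(path, header=labels is not None, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Bundle of the knobs shared across analyses, loadable from YAML/JSON.

    One explicit seeded generator (``rng()``) drives every stochastic
    operation; no function in this package touches global random state.
    """

    seed: int = 0
    layout: str = "rows"
    radius: float | None = None
    min_line: int = 2
    embedding_dimension: int = 1
    embedding_delay: int = 1
    welch_segment_length: int = 256
    window_length: int | None = None
    step: int | None = None
    segment_length: int | None = None
    uniformity_threshold: float = 0.1

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def configure_logging(verbose: bool = False) -> None:
    """Send structured log lines to stderr; DEBUG level when *verbose*."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
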