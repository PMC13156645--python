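"""Reading, validating and writing areal count datasets and run configuration.

The central container is :class:`SpatialCountDataset`: one row per areal
unit, a nonnegative integer count response, ``p`` covariates in their
original measurement units, and centroid coordinates in decimal degrees.
Coordinates are used as given, with planar Euclidean distances downstream;
no projection is applied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import numbers
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gwnbr")

__all__ = [
    "SpatialCountDataset",
    "RunConfig",
    "ConfigurationError",
    "ValidationError",
    "read_dataset",
    "read_config",
    "write_results",
]


class ConfigurationError(ValueError):
    """Bad run configuration or column mapping."""


class ValidationError(ValueError):
    """Dataset content violates an invariant (negative/fractional counts, NaNs...)."""


# counts given as reals are accepted only if integral to this tolerance
_INTEGER_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class SpatialCountDataset:
    """Areal count data: response, covariates and centroid coordinates.

    Attributes
    ----------
    unit_labels : list of str
        One label per areal unit (e.g. province names).
    response : ndarray of int, shape (n,)
        Nonnegative event counts.
    covariates : ndarray of float, shape (n, p)
        Covariates in original units (no standardization).
    covariate_names : list of str
    coords : ndarray of float, shape (n, 2)
        (longitude, latitude) in decimal degrees.
    """

    unit_labels: tuple[str, ...]
    response: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.response)
        X = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        coords = np.asarray(self.coords, dtype=float)
        n = len(y)
        if X.shape[0] != n or coords.shape != (n, 2):
            raise ValidationError(
                f"inconsistent lengths: response {n}, covariates {X.shape}, coords {coords.shape}"
            )
        if len(self.unit_labels) != n or len(self.covariate_names) != X.shape[1]:
            raise ValidationError("label lengths do not match data dimensions")
        if X.shape[1] < 1:
            raise ValidationError("at least one covariate is required")
        if n < X.shape[1] + 2:
            raise ValidationError(
                f"n={n} too small for p={X.shape[1]} covariates (need n >= p + 2)"
            )
        if not np.all(np.isfinite(X)):
            rows = np.where(~np.isfinite(X).all(axis=1))[0]
            raise ValidationError(f"missing/non-finite covariate values in rows {rows.tolist()}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")
        y_int = _as_counts(y)
        object.__setattr__(self, "response", y_int)
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "unit_labels", tuple(str(u) for u in self.unit_labels))
        object.__setattr__(self, "covariate_names", tuple(str(c) for c in self.covariate_names))

    @property
    def n(self) -> int:
        return len(self.response)

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    def design_matrix(self) -> np.ndarray:
        """n x (p+1) design matrix with a leading column of ones."""
        return np.column_stack([np.ones(self.n), self.covariates])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"unit": self.unit_labels, "y": self.response})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        df["longitude"] = self.coords[:, 0]
        df["latitude"] = self.coords[:, 1]
        return df


def _as_counts(y: np.ndarray) -> np.ndarray:
    """Validate and cast a response vector to nonnegative integers."""
    y = np.asarray(y)
    if y.dtype.kind not in "iuf":
        raise ValidationError(f"response has non-numeric dtype {y.dtype}")
    yf = y.astype(float)
    if not np.all(np.isfinite(yf)):
        rows = np.where(~np.isfinite(yf))[0]
        raise ValidationError(f"missing/non-finite counts in rows {rows.tolist()}")
    rounded = np.rint(yf)
    bad = np.abs(yf - rounded) > _INTEGER_TOL
    if np.any(bad):
        rows = np.where(bad)[0]
        raise ValidationError(
            f"non-integer counts in rows {rows.tolist()} (values {yf[rows].tolist()})"
        )
    if np.any(rounded < 0):
        rows = np.where(rounded < 0)[0]
        raise ValidationError(f"negative counts in rows {rows.tolist()}")
    return rounded.astype(np.int64)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    ``bandwidth`` is a distance for ``mode='fixed'``, a proportion of
    neighbours in (0, 1] for ``mode='adaptive'``, or ``"auto"`` to select it
    by leave-one-out cross-validation.
    """

    kernel: str = "bisquare"
    mode: str = "adaptive"
    bandwidth: float | str = "auto"
    alpha: float = 0.05
    seed: int = 0
    max_iterations: int = 20
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "bisquare"):
            raise ConfigurationError(f"unknown kernel family {self.kernel!r}")
        if self.mode not in ("fixed", "adaptive"):
            raise ConfigurationError(f"unknown kernel mode {self.mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.bandwidth != "auto":
            if not isinstance(self.bandwidth, numbers.Real) or self.bandwidth <= 0:
                raise ConfigurationError(f"bandwidth must be positive or 'auto', got {self.bandwidth!r}")
            if self.mode == "adaptive" and not 0.0 < float(self.bandwidth) <= 1.0:
                raise ConfigurationError(
                    f"adaptive bandwidth is a proportion in (0, 1], got {self.bandwidth}"
                )


_DEFAULT_COLUMN_MAP = {
    "unit": "unit",
    "response": "y",
    "longitude": "longitude",
    "latitude": "latitude",
}


def read_dataset(
    path: str | Path,
    column_map: Mapping[str, str | Sequence[str]] | None = None,
) -> SpatialCountDataset:
    """Read a CSV of areal counts into a validated :class:`SpatialCountDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Explicit mapping with keys ``unit``, ``response``, ``longitude``,
        ``latitude`` and ``covariates`` (a list of column names).  Columns are
        never guessed positionally.  If ``covariates`` is omitted, every
        column not otherwise mapped is treated as a covariate, in file order.

    Row order of the file is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"dataset file not found: {path}")
    cmap = dict(_DEFAULT_COLUMN_MAP)
    covariate_cols: Sequence[str] | None = None
    if column_map:
        for key, value in column_map.items():
            if key == "covariates":
                covariate_cols = list(value)  # type: ignore[arg-type]
            elif key in cmap:
                cmap[key] = str(value)
            else:
                raise ConfigurationError(f"unknown column_map key {key!r}")
    df = pd.read_csv(path)
    if covariate_cols is None:
        reserved = set(cmap.values())
        covariate_cols = [c for c in df.columns if c not in reserved]
    needed = [cmap["response"], cmap["longitude"], cmap["latitude"], *covariate_cols]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing columns in {path.name}: {missing}")
    if cmap["unit"] in df.columns:
        labels = df[cmap["unit"]].astype(str).tolist()
    else:
        labels = [str(i) for i in range(len(df))]
    for col in needed:
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()
            raise ValidationError(f"missing values in column {col!r}, rows {rows}")
    return SpatialCountDataset(
        unit_labels=tuple(labels),
        response=df[cmap["response"]].to_numpy(),
        covariates=df[covariate_cols].to_numpy(dtype=float),
        covariate_names=tuple(covariate_cols),
        coords=df[[cmap["longitude"], cmap["latitude"]]].to_numpy(dtype=float),
    )


def read_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)  # YAML is a superset of JSON
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping | None = None,
) -> dict[str, Path]:
    """Write named result tables as CSV plus a JSON summary.

    Column order is taken from each DataFrame as given (deterministic).
    Floats are written with ``repr`` round-trip precision so re-reading
    reproduces the values exactly.
    """
    if not tables:
        raise ValueError("no result tables to write")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - OS dependent
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        dest = out_dir / f"{name}.csv"
        table.to_csv(dest, index=False, float_format=None)
        paths[name] = dest
        logger.info("wrote %s (%d rows)", dest, len(table))
    dest = out_dir / "summary.json"
    with open(dest, "w", encoding="utf-8") as fh:
        json.dump(summary if summary is not None else {}, fh, indent=2, default=_json_default)
        fh.write("\n")
    paths["summary"] = dest
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
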