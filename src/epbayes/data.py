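"""Lifetime datasets: the in-memory sample container, CSV/TSV readers
and writers, and the three small reliability datasets used throughout
the documentation and tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LifetimeSample",
    "DataError",
    "FIXTURES",
    "load_dataset",
    "write_dataset",
    "fixture_checksum",
]


class DataError(ValueError):
    """Raised for malformed or out-of-domain input data."""


@dataclass(frozen=True)
class LifetimeSample:
    """Event times with censoring statuses and optional covariates.

    ``status`` follows the survival convention 1 = event observed,
    0 = right-censored.  All times must be strictly positive and at
    least one observation must be an event.
    """

    times: np.ndarray
    status: np.ndarray = None  # type: ignore[assignment]
    covariates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise DataError("times must be a non-empty 1-d vector")
        if np.any(~np.isfinite(times)) or np.any(times <= 0):
            bad = int(np.argmax(~(np.isfinite(times) & (times > 0))))
            raise DataError(f"non-positive or non-finite time at row {bad}: {times[bad]!r}")
        status = self.status
        if status is None:
            status = np.ones_like(times, dtype=int)
        status = np.asarray(status, dtype=int)
        if status.shape != times.shape:
            raise DataError("status must have the same length as times")
        if not np.all(np.isin(status, (0, 1))):
            raise DataError("status values must be 0 (censored) or 1 (event)")
        if not np.any(status == 1):
            raise DataError("at least one event (status 1) is required")
        cov = self.covariates
        if cov is not None:
            cov = np.asarray(cov, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            if cov.shape[0] != times.size:
                raise DataError("covariates must have one row per observation")
            if np.any(~np.isfinite(cov)):
                raise DataError("covariates must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "covariates", cov)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def n_censored(self) -> int:
        return self.n - self.n_events

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else int(self.covariates.shape[1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "status": self.status})
        if self.covariates is not None:
            for j in range(self.n_covariates):
                df[f"x{j + 1}"] = self.covariates[:, j]
        return df


# --- bundled datasets -------------------------------------------------------

# 15 lifetimes simulated from EP(gamma=1, alpha=30), recorded to 2 dp
# (half-up rounding; the 13th value 23.125 -> 23.13).
TABLE1 = (
    8.07, 11.46, 18.47, 36.61, 6.09, 35.70, 40.79, 21.99,
    20.67, 1.85, 6.23, 5.33, 23.13, 11.86, 27.11,
)

# 18 failure times of an electronic device (complete sample).
DEVICE = (
    5.0, 11.0, 21.0, 31.0, 46.0, 75.0, 98.0, 122.0, 145.0,
    165.0, 195.0, 224.0, 245.0, 293.0, 321.0, 330.0, 350.0, 420.0,
)

# 34 transistor lifetimes (weeks) from an accelerated life test; the
# final three 52s are right-censoring times.
TRANSISTOR_TIMES = (
    3.0, 4.0, 5.0, 6.0, 6.0, 7.0, 8.0, 8.0, 9.0, 9.0, 9.0, 10.0, 10.0,
    11.0, 11.0, 11.0, 13.0, 13.0, 13.0, 13.0, 13.0, 17.0, 17.0, 19.0,
    19.0, 25.0, 29.0, 33.0, 42.0, 42.0, 52.0, 52.0, 52.0, 52.0,
)
TRANSISTOR_STATUS = (1,) * 31 + (0, 0, 0)

FIXTURES = {
    "table1": (TABLE1, None),
    "device": (DEVICE, None),
    "transistor": (TRANSISTOR_TIMES, TRANSISTOR_STATUS),
}

# SHA-256 of the canonical fixture rendering; guards against accidental edits.
_FIXTURE_SHA256 = "b850c43235ee8ce9c563354b4ea69b6d1a613f4f0840affcef44d48fee54bf7b"


def fixture_checksum() -> str:
    parts = []
    for name in sorted(FIXTURES):
        times, status = FIXTURES[name]
        status = status if status is not None else (1,) * len(times)
        parts.append(name + ":" + ",".join(f"{t:.3f}/{s:d}" for t, s in zip(times, status)))
    return hashlib.sha256("|".join(parts).encode()).hexdigest()


def _load_fixture(name: str) -> LifetimeSample:
    if fixture_checksum() != _FIXTURE_SHA256:
        raise DataError("bundled datasets have been modified")
    times, status = FIXTURES[name]
    return LifetimeSample(np.array(times), None if status is None else np.array(status))


def load_dataset(
    source: Union[str, Path],
    time_column: Optional[str] = None,
    status_column: Optional[str] = None,
    covariate_columns: Sequence[str] = (),
    delimiter: Optional[str] = None,
) -> LifetimeSample:
    """Load a lifetime dataset from a delimited text file or by the name
    of a bundled dataset (``table1``, ``device``, ``transistor``).

    ``time_column`` defaults to the first column; with no
    ``status_column`` every observation is treated as an event.
    """
    if isinstance(source, str) and source in FIXTURES:
        return _load_fixture(source)
    path = Path(source)
    if not path.exists():
        raise DataError(f"no such file or bundled dataset: {source!r}")
    if delimiter is None:
        import csv

        with open(path, newline="") as fh:
            head = fh.readline()
        try:
            delimiter = csv.Sniffer().sniff(head, delimiters=",\t; ").delimiter
        except csv.Error:
            delimiter = ","
    try:
        # round_trip parsing keeps write -> load bit-exact
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"could not parse {path}: {exc}") from exc
    tcol = time_column or df.columns[0]
    for col in [tcol, *([status_column] if status_column else []), *covariate_columns]:
        if col not in df.columns:
            raise DataError(f"column {col!r} not found in {path} (has {list(df.columns)})")
    times = pd.to_numeric(df[tcol], errors="coerce").to_numpy()
    if np.any(np.isnan(times)):
        raise DataError(f"non-numeric time at row {int(np.argmax(np.isnan(times)))}")
    status = None
    if status_column:
        status = pd.to_numeric(df[status_column], errors="coerce").to_numpy()
        if np.any(np.isnan(status)):
            raise DataError(f"non-numeric status at row {int(np.argmax(np.isnan(status)))}")
    cov = df[list(covariate_columns)].to_numpy(dtype=float) if covariate_columns else None
    return LifetimeSample(times, status, cov)


def write_dataset(sample: LifetimeSample, path: Union[str, Path]) -> None:
    """Write a sample as CSV (columns time, status, x1..xJ); floats are
    written with 17 significant digits so a reload is bit-exact."""
    sample.to_frame().to_csv(path, index=False, float_format="%.17g")
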