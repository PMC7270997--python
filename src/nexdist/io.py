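"""Data ingestion and synthetic fixtures.

Samples are plain-text files (one value per line, ``#`` comments) or CSV
files with a named column.  The fixture generator draws right-skewed,
heavy-tailed NE-W samples whose true parameters are the NE-W point
estimates reported for the three application domains (cancer remission
times, machine failure times, vehicle insurance losses); the real data sets
themselves are not publicly printed, so these are synthetic stand-ins with
the same fitted shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .family import new_weibull

__all__ = ["DataSeries", "read_series", "write_series", "generate_fixture", "FIXTURE_PARAMS"]

# (theta, a, gamma) of the NE-W fits reported for each application domain
FIXTURE_PARAMS: dict[str, tuple[float, float, float]] = {
    "remission": (2.156, 1.985, 0.107),
    "failure": (0.079, 0.943, 2.065),
    "loss": (0.632, 0.975, 0.031),
}


@dataclass(frozen=True)
class DataSeries:
    values: np.ndarray
    source: str

    @property
    def n(self) -> int:
        return int(self.values.size)


def read_series(path, column: str | None = None) -> DataSeries:
    """Read a univariate sample from plain text or CSV.

    Plain text: one value per line; blank lines and ``#`` comments skipped.
    CSV (by ``.csv`` suffix): ``column`` selects the series and is required
    when the file has more than one column.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if column is None:
            if df.shape[1] != 1:
                raise ValueError(
                    f"{path}: CSV has {df.shape[1]} columns; pass column= "
                    f"(available: {list(df.columns)})"
                )
            column = df.columns[0]
        if column not in df.columns:
            raise ValueError(
                f"{path}: no column {column!r} (available: {list(df.columns)})"
            )
        values = df[column].to_numpy(dtype=float)
        return DataSeries(values, f"{path}::{column}")

    values = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        token = raw.split("#", 1)[0].strip()
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError:
            raise ValueError(f"{path}: unparseable value {token!r} on line {lineno}") from None
    return DataSeries(np.asarray(values, dtype=float), str(path))


def write_series(series, path) -> None:
    """Write values one per line at 12 significant digits."""
    values = series.values if isinstance(series, DataSeries) else np.asarray(series)
    Path(path).write_text("".join(f"{v:.12g}\n" for v in values))


def generate_fixture(kind: str, n: int, seed: int = 0) -> DataSeries:
    """Synthetic NE-W sample emulating one of the three application domains.

    ``kind`` is one of ``remission``, ``failure``, ``loss``; the true
    parameters per kind are in :data:`FIXTURE_PARAMS`.  Deterministic per
    ``seed``.
    """
    try:
        theta, a, gamma = FIXTURE_PARAMS[kind]
    except KeyError:
        raise KeyError(
            f"unknown fixture kind {kind!r}; available: {sorted(FIXTURE_PARAMS)}"
        ) from None
    n = int(n)
    if n < 1:
        raise ValueError("fixture size must be >= 1")
    values = new_weibull(theta, a, gamma).rvs(n, seed=seed)
    return DataSeries(values, f"synthetic:{kind}(theta={theta}, a={a}, gamma={gamma}, seed={seed})")
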