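"""Ordinal scales, series, empirical CDFs and file I/O.

An ordinal variable takes values on an ordered qualitative range
``s_0 < s_1 < ... < s_m``.  All measures in this package are functionals of
the marginal CDF ``f_i = P(X <= s_i)`` (the final component f_m = 1 is
always omitted) and, for serial dependence at lag h, of the lagged
bivariate CDF ``f_ij(h) = P(X_t <= s_i, X_{t-h} <= s_j)``.  This module
provides the containers and their empirical (plug-in) estimators.

Ordering is user-declared: labels are ranked by their position in the
configured scale, never lexicographically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrdinalScale",
    "OrdinalSeries",
    "MarginalCDF",
    "LaggedBivariateCDF",
    "ecdf",
    "lagged_ecdf",
    "read_scale",
    "read_series",
    "write_cdf",
    "write_bivariate_cdf",
]


@dataclass(frozen=True)
class OrdinalScale:
    """An ordered range of m + 1 distinct category labels."""

    labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("an ordinal scale needs at least two categories")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate category labels in scale: {labels}")

    @property
    def m(self) -> int:
        return len(self.labels) - 1

    @classmethod
    def integer(cls, m: int) -> "OrdinalScale":
        """The default integer-coded scale 0 < 1 < ... < m."""
        return cls(tuple(str(i) for i in range(m + 1)))

    def codes_for(self, values: Sequence) -> np.ndarray:
        """Map labels to 0-based rank counts; unknown labels are an error."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        codes = np.empty(len(values), dtype=np.int64)
        for t, v in enumerate(values):
            key = str(v)
            if key not in index:
                raise ValueError(
                    f"label {v!r} at position {t} is not on the scale "
                    f"{list(self.labels)}"
                )
            codes[t] = index[key]
        return codes

    def reversed(self) -> "OrdinalScale":
        return OrdinalScale(tuple(reversed(self.labels)))


@dataclass(frozen=True)
class OrdinalSeries:
    """An ordinal time series stored as 0-based rank counts I_t."""

    codes: np.ndarray
    scale: OrdinalScale

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size == 0:
            raise ValueError("series must be a non-empty 1-d sequence")
        if codes.min() < 0 or codes.max() > self.scale.m:
            raise ValueError(
                f"rank counts must lie in 0..{self.scale.m}; got range "
                f"[{codes.min()}, {codes.max()}]"
            )

    @property
    def n(self) -> int:
        return self.codes.size

    @property
    def m(self) -> int:
        return self.scale.m

    def labels(self) -> list[str]:
        return [self.scale.labels[i] for i in self.codes]


@dataclass(frozen=True)
class MarginalCDF:
    """The vector (f_0, ..., f_{m-1}); f_m = 1 is implicit."""

    f: np.ndarray
    scale: OrdinalScale | None = None

    def __post_init__(self):
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "f", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("CDF vector must be 1-d and non-empty")
        if f.min() < -1e-12 or f.max() > 1 + 1e-12:
            raise ValueError("CDF components must lie in [0, 1]")
        if np.any(np.diff(f) < -1e-12):
            raise ValueError("CDF components must be non-decreasing")

    @property
    def m(self) -> int:
        return self.f.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.f, dtype=dtype)

    @property
    def pmf(self) -> np.ndarray:
        """Probabilities of the m + 1 categories."""
        full = np.concatenate([self.f, [1.0]])
        return np.diff(full, prepend=0.0)

    def is_one_point(self, tol: float = 1e-12) -> bool:
        return bool(np.all((self.f < tol) | (self.f > 1 - tol)))

    def is_two_point(self, tol: float = 1e-12) -> bool:
        """The extreme polarized CDF (1/2, ..., 1/2) of maximal dispersion."""
        return bool(np.all(np.abs(self.f - 0.5) < tol))

    def reversed(self) -> "MarginalCDF":
        """CDF after reversing the scale order (s_i -> s_{m-i})."""
        scale = self.scale.reversed() if self.scale is not None else None
        return MarginalCDF(1.0 - self.f[::-1], scale)


@dataclass(frozen=True)
class LaggedBivariateCDF:
    """f_ij(h) = P(X_t <= s_i, X_{t-h} <= s_j) as an m x m matrix."""

    h: int
    fij: np.ndarray
    marginal: MarginalCDF

    def __post_init__(self):
        fij = np.asarray(self.fij, dtype=float)
        object.__setattr__(self, "fij", fij)
        m = self.marginal.m
        if self.h < 1:
            raise ValueError("lag must be a positive integer")
        if fij.shape != (m, m):
            raise ValueError(f"bivariate CDF must be {m}x{m}; got {fij.shape}")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.fij)

    def check(self, tol: float = 1e-12) -> None:
        """Verify monotonicity and the Frechet bounds against the marginal."""
        f = self.marginal.f
        upper = np.minimum.outer(f, f)
        lower = np.maximum(0.0, np.add.outer(f, f) - 1.0)
        if np.any(self.fij > upper + tol) or np.any(self.fij < lower - tol):
            raise ValueError("bivariate CDF violates the Frechet bounds")
        if np.any(np.diff(self.fij, axis=0) < -tol) or np.any(
            np.diff(self.fij, axis=1) < -tol
        ):
            raise ValueError("bivariate CDF must be componentwise monotone")


def ecdf(series: OrdinalSeries) -> MarginalCDF:
    """Cumulative relative frequencies f_hat of an ordinal series."""
    m = series.m
    counts = np.bincount(series.codes, minlength=m + 1)
    f = np.cumsum(counts[:m]) / series.n
    return MarginalCDF(f, series.scale)


def lagged_ecdf(series: OrdinalSeries, h: int) -> LaggedBivariateCDF:
    """Empirical lagged bivariate CDF at lag h >= 1.

    Averages the pair indicators 1{I_t <= i, I_{t-h} <= j} over the n - h
    available pairs; the attached marginal is the full-sample one, so the
    coupling identities hold only up to O(h / n) edge effects.
    """
    h = int(h)
    n, m = series.n, series.m
    if not 1 <= h <= n - 1:
        raise ValueError(f"lag h must satisfy 1 <= h <= n-1 = {n - 1}")
    cur, lag = series.codes[h:], series.codes[:-h]
    # joint counts of (I_t, I_{t-h}), cumulated in both directions
    joint = np.zeros((m + 1, m + 1))
    np.add.at(joint, (cur, lag), 1.0)
    cum = joint.cumsum(axis=0).cumsum(axis=1) / (n - h)
    return LaggedBivariateCDF(h=h, fij=cum[:m, :m], marginal=ecdf(series))


# ---------------------------------------------------------------------------
# I/O


def read_scale(path: str | Path) -> OrdinalScale:
    """Read an ordered category list from a YAML or JSON config.

    The config is either a bare list of labels (ordered low to high) or a
    mapping with a ``categories`` key holding that list.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        obj = json.loads(text)
    else:
        import yaml

        obj = yaml.safe_load(text)
    if isinstance(obj, dict):
        if "categories" not in obj:
            raise ValueError(f"{path}: scale config needs a 'categories' list")
        obj = obj["categories"]
    if not isinstance(obj, list):
        raise ValueError(f"{path}: scale config must be a list of labels")
    return OrdinalScale(tuple(str(x) for x in obj))


def read_series(
    path: str | Path,
    scale: OrdinalScale,
    *,
    column: str | int = 0,
) -> OrdinalSeries:
    """Read an ordinal series from CSV/plain text, one observation per row.

    ``column`` selects by name (CSV with header) or position.  Values must
    all be labels of ``scale``; integer-coded files work with the matching
    :meth:`OrdinalScale.integer` scale.
    """
    header = "infer" if isinstance(column, str) else None
    df = pd.read_csv(path, header=header, dtype=str, skipinitialspace=True)
    col = df[column] if isinstance(column, str) else df.iloc[:, column]
    values = col.dropna().str.strip().tolist()
    return OrdinalSeries(scale.codes_for(values), scale)


def write_cdf(cdf: MarginalCDF, path: str | Path) -> None:
    labels = (
        list(cdf.scale.labels[: cdf.m])
        if cdf.scale is not None
        else [str(i) for i in range(cdf.m)]
    )
    pd.DataFrame({"category": labels, "cdf": cdf.f}).to_csv(path, index=False)


def write_bivariate_cdf(biv: LaggedBivariateCDF, path: str | Path) -> None:
    m = biv.marginal.m
    scale = biv.marginal.scale
    labels = list(scale.labels[:m]) if scale is not None else [str(i) for i in range(m)]
    pd.DataFrame(biv.fij, index=labels, columns=labels).to_csv(path)
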