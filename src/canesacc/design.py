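"""Rotatable central composite designs and coded/real factor conversion.

A two-factor rotatable CCD has 2^k factorial points at coded +/-1, 2k axial
points at coded +/-alpha with alpha = (2^k)^(1/4), and replicated center
points at coded 0, giving five levels (-alpha, -1, 0, +1, +alpha) per
factor.  The coded basis keeps factor effects proportional regardless of
the physical units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_away

__all__ = [
    "FactorScale",
    "CCDDesign",
    "rotatability_alpha",
    "build_ccd",
    "load_design_table",
    "write_design_table",
]


def rotatability_alpha(k: int) -> float:
    """Coded axial distance giving a rotatable CCD for ``k`` factors.

    Returns (2^k)^(1/4): 1.414... for k=2, 2.0 for k=4.  Rotatability makes
    prediction variance constant on spheres around the design center.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"factor count k must be a positive integer, got {k!r}")
    return float((2.0**k) ** 0.25)


@dataclass(frozen=True)
class FactorScale:
    """Mapping between one factor's coded levels and real units.

    ``center_real`` sits at coded 0 and the axial extremes at coded
    -alpha/+alpha, so one coded unit spans
    ``(axial_high_real - center_real) / alpha`` real units.
    """

    name: str
    unit: str
    center_real: float
    axial_low_real: float
    axial_high_real: float
    alpha: float = 1.41

    def __post_init__(self) -> None:
        if not (self.axial_low_real < self.center_real < self.axial_high_real):
            raise ValueError(
                f"{self.name}: require axial_low < center < axial_high, got "
                f"{self.axial_low_real}, {self.center_real}, {self.axial_high_real}"
            )
        if self.alpha <= 0:
            raise ValueError(f"{self.name}: alpha must be positive")
        mid = (self.axial_low_real + self.axial_high_real) / 2.0
        if abs(mid - self.center_real) > 1e-6 * max(1.0, abs(self.center_real)):
            raise ValueError(
                f"{self.name}: center {self.center_real} is not the midpoint of the "
                f"axial levels ({mid})"
            )

    @property
    def step_real(self) -> float:
        """Real units per coded unit."""
        return (self.axial_high_real - self.center_real) / self.alpha

    def decode(self, coded: float) -> float:
        """Coded level -> real units (extrapolation beyond +/-alpha allowed)."""
        return self.center_real + coded * self.step_real

    def encode(self, real: float) -> float:
        """Real units -> coded level (inverse of :meth:`decode`)."""
        return (real - self.center_real) / self.step_real

    def decode_printed(self, coded: float, ndigits: int = 1) -> float:
        """Decoded level rounded half-away-from-zero, as tables print it."""
        return round_half_away(self.decode(coded), ndigits)


@dataclass
class CCDDesign:
    """A central composite design: factor scales plus coded run levels.

    ``runs`` is a DataFrame indexed by ``run_id`` with one ``<factor>_coded``
    column per factor.
    """

    factors: list[FactorScale]
    runs: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        cols = self.coded_columns
        missing = [c for c in cols if c not in self.runs.columns]
        if missing:
            raise ValueError(f"design table missing coded columns: {missing}")
        if self.runs.index.has_duplicates:
            dups = self.runs.index[self.runs.index.duplicated()].tolist()
            raise ValueError(f"duplicate run_id values: {dups}")
        coded = self.coded_matrix
        for scale, col in zip(self.factors, coded.T):
            if np.any(np.abs(col) > scale.alpha + 1e-9):
                raise ValueError(
                    f"{scale.name}: coded levels outside [-alpha, +alpha]"
                )
        if not np.any(np.all(np.abs(coded) < 1e-9, axis=1)):
            raise ValueError("design has no center (all-zero) run")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def coded_columns(self) -> list[str]:
        return [f"{f.name}_coded" for f in self.factors]

    @property
    def coded_matrix(self) -> np.ndarray:
        return self.runs[self.coded_columns].to_numpy(dtype=float)

    @property
    def run_ids(self) -> list:
        return self.runs.index.tolist()

    @property
    def n_center(self) -> int:
        return int(np.sum(np.all(np.abs(self.coded_matrix) < 1e-9, axis=1)))

    def decode_point(self, coded_point) -> dict[str, float]:
        """Decode one coded point to real units, keyed by factor name."""
        return {
            f.name: f.decode(c) for f, c in zip(self.factors, np.asarray(coded_point))
        }

    def standard_points(self) -> np.ndarray:
        """The textbook CCD point set for this k and alpha (one center row)."""
        k = self.k
        alphas = np.array([f.alpha for f in self.factors])
        factorial = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
        axial = np.zeros((2 * k, k))
        for i in range(k):
            axial[2 * i, i] = -alphas[i]
            axial[2 * i + 1, i] = alphas[i]
        return np.vstack([factorial, axial, np.zeros((1, k))])

    def validate_standard(self, atol: float = 1e-6) -> list[str]:
        """Report runs that are not textbook CCD points (no correction made)."""
        std = self.standard_points()
        warnings = []
        for run_id, row in zip(self.run_ids, self.coded_matrix):
            dist = np.abs(std - row).max(axis=1)
            if dist.min() > atol:
                nearest = std[dist.argmin()]
                warnings.append(
                    f"run {run_id}: coded point {tuple(row)} is not a standard CCD "
                    f"point (nearest: {tuple(nearest)})"
                )
        return warnings

    def as_standard(self) -> "CCDDesign":
        """Copy with every run snapped to the nearest textbook CCD point.

        Axial coordinates of factorial-type runs are snapped to +/-1: a run
        recorded at an axial extreme that otherwise matches a factorial point
        is treated as that factorial point, which is how standard RSM software
        builds the regression matrix for an 11-run two-factor CCD.
        """
        std = self.standard_points()
        snapped = np.empty_like(self.coded_matrix)
        for i, row in enumerate(self.coded_matrix):
            dist = np.abs(std - row).max(axis=1)
            snapped[i] = std[dist.argmin()]
        runs = self.runs.copy()
        runs[self.coded_columns] = snapped
        return CCDDesign(self.factors, runs)


def build_ccd(
    factors: list[FactorScale], n_center: int, alpha: float | None = None
) -> CCDDesign:
    """Construct the textbook rotatable CCD: 2^k factorial + 2k axial +
    ``n_center`` center runs, numbered 1..N in that order.

    ``alpha`` overrides the factors' own axial distance for the axial runs
    (all factor scales must then agree with it for decoding to be exact).
    """
    k = len(factors)
    if k < 1:
        raise ValueError("need at least one factor")
    if n_center < 1:
        raise ValueError("need at least one center run")
    if alpha is None:
        alpha = factors[0].alpha
    factorial = list(itertools.product([-1.0, 1.0], repeat=k))
    axial = []
    for i in range(k):
        for sign in (-1.0, 1.0):
            pt = [0.0] * k
            pt[i] = sign * alpha
            axial.append(tuple(pt))
    center = [tuple([0.0] * k)] * n_center
    points = factorial + axial + center
    runs = pd.DataFrame(
        points,
        columns=[f"{f.name}_coded" for f in factors],
        index=pd.RangeIndex(1, len(points) + 1, name="run_id"),
    )
    return CCDDesign(factors, runs)


def load_design_table(path, factors: list[FactorScale]) -> CCDDesign:
    """Read a design table (CSV: ``run_id`` + ``<factor>_coded`` columns).

    The design is loaded exactly as stored, never regenerated; use
    :meth:`CCDDesign.validate_standard` to see how it differs from the
    textbook layout.
    """
    df = pd.read_csv(path)
    if "run_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'run_id'")
    missing = [f"{f.name}_coded" for f in factors if f"{f.name}_coded" not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing coded-level columns {missing}")
    for col in [f"{f.name}_coded" for f in factors]:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric values in column {col}, rows "
                f"{bad.index.tolist()}"
            )
        df[col] = pd.to_numeric(df[col])
    if df["run_id"].duplicated().any():
        dups = df.loc[df["run_id"].duplicated(), "run_id"].tolist()
        raise ValueError(f"{path}: duplicate run_id values {dups}")
    return CCDDesign(factors, df.set_index("run_id"))


def write_design_table(design: CCDDesign, path) -> None:
    """Write a design table readable by :func:`load_design_table`."""
    out = design.runs.copy()
    for f in design.factors:
        out[f"{f.name}_real"] = [f.decode(c) for c in out[f"{f.name}_coded"]]
    out.to_csv(path, index=True, index_label="run_id")
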