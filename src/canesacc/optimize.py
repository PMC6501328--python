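"""Canonical analysis and constrained optimization of fitted surfaces.

The fitted quadratic Y = b0 + g'x + x'Bx (B the symmetric quadratic-form
matrix) has stationary point x_s = -B^-1 g / 2; its eigenvalues classify
the surface (all negative: maximum; all positive: minimum; mixed: saddle).
Because the published optima sit at coded corners, maximization is done
exactly over a per-factor box by case analysis rather than over the
rotatable sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import round_half_away
from .rsm import QuadraticFit, predict

__all__ = [
    "CanonicalResult",
    "Optimum",
    "ValidationResult",
    "canonical_analysis",
    "optimize_in_box",
    "validate_prediction",
    "percent_error",
    "improvement_percent",
]


@dataclass
class CanonicalResult:
    stationary_point: np.ndarray | None  # coded; None when B is singular
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns
    classification: str  # maximum | minimum | saddle | degenerate
    predicted_at_stationary: float | None
    ridge_direction: np.ndarray | None = None  # eigvec of a ~zero eigenvalue


@dataclass
class Optimum:
    coded: np.ndarray
    real: dict[str, float]
    predicted: float
    at_boundary: list[bool]  # per factor


@dataclass
class ValidationResult:
    coded_point: np.ndarray
    predicted: float
    experimental: float
    percent_error: float

    @property
    def percent_error_printed(self) -> float:
        return round_half_away(self.percent_error, 1)


def canonical_analysis(fit: QuadraticFit, tol: float = 1e-8) -> CanonicalResult:
    """Locate and classify the stationary point of the fitted surface."""
    b = fit.quadratic_form
    g = fit.gradient_coef
    evals, evecs = np.linalg.eigh(b)
    scale = max(np.abs(evals).max(), 1.0)
    degenerate = np.any(np.abs(evals) < tol * scale) or np.abs(evals).max() < tol

    if degenerate:
        ridge = evecs[:, np.argmin(np.abs(evals))]
        return CanonicalResult(None, evals, evecs, "degenerate", None, ridge)

    x_s = -0.5 * np.linalg.solve(b, g)
    y_s = predict(fit, x_s)
    if np.all(evals < 0):
        cls = "maximum"
    elif np.all(evals > 0):
        cls = "minimum"
    else:
        cls = "saddle"
    return CanonicalResult(x_s, evals, evecs, cls, y_s)


def _edge_candidates(fit: QuadraticFit, lo: np.ndarray, hi: np.ndarray):
    """Stationary points of the univariate quadratics on each box edge."""
    b = fit.coefficients
    pts = []
    # edges with X1 fixed: Y(x2) is quadratic with leading coef b22
    for x1 in (lo[0], hi[0]):
        if b["b22"] != 0:
            x2 = -(b["b2"] + b["b12"] * x1) / (2.0 * b["b22"])
            if lo[1] - 1e-12 <= x2 <= hi[1] + 1e-12:
                pts.append((x1, float(np.clip(x2, lo[1], hi[1]))))
    # edges with X2 fixed
    for x2 in (lo[1], hi[1]):
        if b["b11"] != 0:
            x1 = -(b["b1"] + b["b12"] * x2) / (2.0 * b["b11"])
            if lo[0] - 1e-12 <= x1 <= hi[0] + 1e-12:
                pts.append((float(np.clip(x1, lo[0], hi[0])), x2))
    return pts


def optimize_in_box(fit: QuadraticFit, box=None, atol: float = 1e-9) -> Optimum:
    """Exact maximization of the fitted quadratic over a coded box.

    The maximizer of a bivariate quadratic over a rectangle is either the
    interior stationary point (when the surface is a maximum and the point
    is inside), an edge vertex of one of the four univariate restrictions,
    or a corner; all candidates are enumerated and the best kept.
    """
    alphas = np.array([f.alpha for f in fit.design.factors])
    if box is None:
        lo, hi = -alphas, alphas
    else:
        box = np.asarray(box, dtype=float)
        lo, hi = box[:, 0], box[:, 1]
    if not np.all(np.isfinite(lo) & np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("box bounds must be finite with lo < hi per factor")

    candidates: list[tuple[float, float]] = [
        (x1, x2) for x1 in (lo[0], hi[0]) for x2 in (lo[1], hi[1])
    ]
    candidates += _edge_candidates(fit, lo, hi)
    canon = canonical_analysis(fit)
    if canon.stationary_point is not None:
        xs = canon.stationary_point
        if np.all(xs >= lo - 1e-12) and np.all(xs <= hi + 1e-12):
            candidates.append((float(np.clip(xs[0], lo[0], hi[0])),
                               float(np.clip(xs[1], lo[1], hi[1]))))

    values = [predict(fit, np.array(c)) for c in candidates]
    best = int(np.argmax(values))
    coded = np.array(candidates[best])
    # prefer the exact interior stationary point when it attains the max
    if canon.classification == "maximum" and canon.stationary_point is not None:
        xs = canon.stationary_point
        if np.all(xs >= lo) and np.all(xs <= hi) and predict(fit, xs) >= values[best] - atol:
            coded = xs
    real = fit.design.decode_point(coded)
    boundary = [
        bool(abs(c - l) < 1e-9 or abs(c - h) < 1e-9)
        for c, l, h in zip(coded, lo, hi)
    ]
    return Optimum(coded=coded, real=real, predicted=predict(fit, coded),
                   at_boundary=boundary)


def percent_error(experimental: float, predicted: float) -> float:
    """Validation percent error, relative to the *predicted* value:
    100 * |experimental - predicted| / predicted."""
    if predicted <= 0:
        raise ValueError("predicted response is non-positive; percent error undefined")
    return 100.0 * abs(experimental - predicted) / predicted


def validate_prediction(
    fit: QuadraticFit, coded_point, experimental_mean: float
) -> ValidationResult:
    """Percent error of the model prediction at a validation point."""
    if experimental_mean <= 0:
        raise ValueError("experimental mean must be positive")
    coded_point = np.asarray(coded_point, dtype=float)
    pred = predict(fit, coded_point)
    err = percent_error(experimental_mean, pred)
    return ValidationResult(coded_point, pred, experimental_mean, err)


def improvement_percent(value_line: float, value_reference: float) -> float:
    """Relative improvement of a line over a reference, in percent.

    Report with round-half-away-from-zero to the nearest integer.
    """
    if value_reference <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (value_line / value_reference - 1.0)
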