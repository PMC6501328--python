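"""Second-order response-surface model on coded CCD factors.

The model is the full six-term bivariate quadratic

    Y = b0 + b1*X1 + b2*X2 + b11*X1^2 + b22*X2^2 + b12*X1*X2

fitted by ordinary least squares on coded levels.  With balanced
replication, fitting run means and fitting all replicates give identical
coefficients; both entry points are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CCDDesign

__all__ = ["ResponseTable", "QuadraticFit", "fit_quadratic", "predict"]

COEF_NAMES = ("b0", "b1", "b2", "b11", "b22", "b12")


class ResponseTable:
    """Replicate- or summary-level responses keyed by (run, genotype, timepoint).

    Long format: columns ``run_id, genotype, timepoint, rep, value``.
    Summary format: columns ``run_id, genotype, timepoint, mean, sd, n``.
    """

    LONG_COLS = ["run_id", "genotype", "timepoint", "rep", "value"]
    SUMMARY_COLS = ["run_id", "genotype", "timepoint", "mean", "sd", "n"]

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if {"rep", "value"}.issubset(df.columns):
            self.kind = "long"
            if (df["value"] <= 0).any():
                raise ValueError("response values must be positive")
        elif {"mean", "sd", "n"}.issubset(df.columns):
            self.kind = "summary"
            if (df["n"] < 1).any() or (df["sd"] < 0).any() or (df["mean"] <= 0).any():
                raise ValueError("summary rows require n >= 1, sd >= 0, mean > 0")
        else:
            raise ValueError(
                "response table needs either (rep, value) or (mean, sd, n) columns"
            )
        self.df = df

    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].unique())

    def timepoints(self) -> list[str]:
        return sorted(self.df["timepoint"].unique())

    def select(self, genotype: str, timepoint: str) -> pd.DataFrame:
        sel = self.df[
            (self.df["genotype"] == genotype) & (self.df["timepoint"] == timepoint)
        ]
        if sel.empty:
            raise KeyError(f"no responses for genotype={genotype!r}, timepoint={timepoint!r}")
        return sel

    def run_means(self, genotype: str, timepoint: str) -> pd.Series:
        """Per-run mean response, indexed by run_id."""
        sel = self.select(genotype, timepoint)
        if self.kind == "long":
            return sel.groupby("run_id")["value"].mean()
        return sel.set_index("run_id")["mean"]

    def replicate_frame(self, genotype: str, timepoint: str) -> pd.DataFrame:
        """Run-level replicate values (long data only)."""
        if self.kind != "long":
            raise ValueError("replicate-level data not available in a summary table")
        return self.select(genotype, timepoint)

    def check_against_design(self, design: CCDDesign) -> None:
        unknown = set(self.df["run_id"]) - set(design.run_ids)
        if unknown:
            raise ValueError(f"response rows reference unknown run_ids: {sorted(unknown)}")


@dataclass
class QuadraticFit:
    """OLS solution of the six-term quadratic, in the coded basis."""

    coefficients: dict[str, float]
    design: CCDDesign
    x: np.ndarray = field(repr=False)  # n x 2 coded points used in the fit
    y: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    r_squared: float = 0.0
    df_resid: int = 0

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in COEF_NAMES])

    @property
    def quadratic_form(self) -> np.ndarray:
        """Symmetric matrix B with x'Bx giving the pure quadratic part."""
        b11, b22, b12 = (self.coefficients[c] for c in ("b11", "b22", "b12"))
        return np.array([[b11, b12 / 2.0], [b12 / 2.0, b22]])

    @property
    def gradient_coef(self) -> np.ndarray:
        return np.array([self.coefficients["b1"], self.coefficients["b2"]])

    def summary(self) -> dict:
        return {
            "coefficients": dict(self.coefficients),
            "r_squared": self.r_squared,
            "df_resid": self.df_resid,
            "n_obs": int(len(self.y)),
        }


def _design_matrix(x: np.ndarray) -> np.ndarray:
    x1, x2 = x[:, 0], x[:, 1]
    return np.column_stack([np.ones_like(x1), x1, x2, x1**2, x2**2, x1 * x2])


def fit_quadratic(
    design: CCDDesign,
    responses: ResponseTable,
    genotype: str,
    timepoint: str,
    use_replicates: bool = True,
) -> QuadraticFit:
    """Fit the full quadratic for one (genotype, timepoint) series.

    Replicate-level data are used when available and ``use_replicates`` is
    true; otherwise run means are fitted (identical coefficients under
    balanced replication).
    """
    if design.k != 2:
        raise ValueError("the quadratic surface model is defined for k=2 factors")
    responses.check_against_design(design)
    if responses.kind == "long" and use_replicates:
        frame = responses.replicate_frame(genotype, timepoint)
        run_ids = frame["run_id"].to_numpy()
        y = frame["value"].to_numpy(dtype=float)
    else:
        means = responses.run_means(genotype, timepoint)
        run_ids = means.index.to_numpy()
        y = means.to_numpy(dtype=float)
    coded = design.runs[design.coded_columns]
    x = coded.loc[run_ids].to_numpy(dtype=float)

    distinct = np.unique(x, axis=0)
    if len(distinct) < 6:
        raise ValueError(
            f"need >= 6 distinct design points for a 6-term model, have {len(distinct)}"
        )
    xmat = _design_matrix(x)
    rank = np.linalg.matrix_rank(xmat)
    if rank < 6:
        # name the collinear columns for the error message
        names = ["1", "X1", "X2", "X1^2", "X2^2", "X1X2"]
        _, r = np.linalg.qr(xmat)
        bad = [names[i] for i in range(6) if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
    fitted = xmat @ beta
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return QuadraticFit(
        coefficients=dict(zip(COEF_NAMES, beta.tolist())),
        design=design,
        x=x,
        y=y,
        fitted=fitted,
        residuals=resid,
        r_squared=r2,
        df_resid=len(y) - 6,
    )


def predict(fit: QuadraticFit, point, warn_extrapolation: bool = False):
    """Evaluate the fitted quadratic at coded point(s).

    ``point`` is one (x1, x2) pair or an (n, 2) array; returns a float or an
    array accordingly.  With ``warn_extrapolation`` a second return value
    flags points outside the coded box spanned by +/-alpha.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    yhat = _design_matrix(pts) @ fit.beta
    scalar = np.asarray(point).ndim == 1
    result = float(yhat[0]) if scalar else yhat
    if warn_extrapolation:
        alphas = np.array([f.alpha for f in fit.design.factors])
        outside = np.any(np.abs(pts) > alphas + 1e-9, axis=1)
        return result, (bool(outside[0]) if scalar else outside)
    return result
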