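"""Model-adequacy ANOVA and Tukey HSD multiple comparisons.

The response-surface ANOVA partitions total (corrected) variation into
regression, lack of fit, and pure error.  Pure error comes from genuinely
replicated design points — replicated center runs when only run means are
available, full within-run replication otherwise — and the lack-of-fit F
test (MS_lof / MS_pe) judges whether the quadratic is adequate.

Tukey HSD compares group means with the studentized-range distribution and
summarizes the pairwise decisions as a compact letter display: groups
sharing a letter do not differ significantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rsm import QuadraticFit

__all__ = ["AnovaTable", "TukeyResult", "anova_rsm", "tukey_hsd"]


@dataclass
class AnovaTable:
    """SS partition with F tests for regression and lack of fit."""

    rows: dict[str, tuple[float, int, float | None]]  # source -> (SS, df, MS)
    f_regression: float
    p_regression: float
    f_lack_of_fit: float | None
    p_lack_of_fit: float | None
    conf_level: float

    @property
    def regression_significant(self) -> bool:
        return self.p_regression < (1.0 - self.conf_level)

    @property
    def lack_of_fit_testable(self) -> bool:
        return self.f_lack_of_fit is not None and np.isfinite(self.f_lack_of_fit)

    @property
    def lack_of_fit_significant(self) -> bool | None:
        if not self.lack_of_fit_testable:
            return None
        return self.p_lack_of_fit < (1.0 - self.conf_level)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"source": src, "SS": ss, "df": df, "MS": ms}
            for src, (ss, df, ms) in self.rows.items()
        ]
        out = pd.DataFrame(recs).set_index("source")
        out.loc["regression", "F"] = self.f_regression
        out.loc["regression", "p"] = self.p_regression
        if self.f_lack_of_fit is not None:
            out.loc["lack_of_fit", "F"] = self.f_lack_of_fit
            out.loc["lack_of_fit", "p"] = self.p_lack_of_fit
        return out


def anova_rsm(fit: QuadraticFit, conf_level: float = 0.90) -> AnovaTable:
    """ANOVA for a fitted quadratic surface.

    Pure error pools squared deviations within groups of observations that
    share the same coded design point.  When the fit used run means, only
    the replicated center runs contribute (df = n_center - 1); when it used
    replicate-level data, all within-point replication contributes.
    """
    y, fitted, x = fit.y, fit.fitted, fit.x
    n = len(y)
    ybar = y.mean()
    ss_total = float(np.sum((y - ybar) ** 2))
    ss_reg = float(np.sum((fitted - ybar) ** 2))
    ss_resid = float(np.sum((y - fitted) ** 2))
    df_reg, df_resid = 5, n - 6

    # pure error: within-group SS over identical design points
    _, inverse = np.unique(x, axis=0, return_inverse=True)
    ss_pe, df_pe = 0.0, 0
    for g in np.unique(inverse):
        yg = y[inverse == g]
        if len(yg) > 1:
            ss_pe += float(np.sum((yg - yg.mean()) ** 2))
            df_pe += len(yg) - 1
    ss_lof = max(ss_resid - ss_pe, 0.0)
    df_lof = df_resid - df_pe

    ms_reg = ss_reg / df_reg
    ms_resid = ss_resid / df_resid if df_resid > 0 else None
    f_reg = ms_reg / ms_resid if ms_resid and ms_resid > 0 else np.inf
    p_reg = float(stats.f.sf(f_reg, df_reg, df_resid)) if df_resid > 0 else 0.0

    rows = {
        "regression": (ss_reg, df_reg, ms_reg),
        "residual": (ss_resid, df_resid, ms_resid),
    }
    if df_pe > 0 and df_lof > 0:
        ms_lof = ss_lof / df_lof
        ms_pe = ss_pe / df_pe
        if ms_pe > 0:
            f_lof = ms_lof / ms_pe
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:  # exact fit of an exact surface; tolerate rounding residue
            exact = ss_lof <= 1e-12 * max(ss_total, 1.0)
            f_lof = 0.0 if exact else np.inf
            p_lof = 1.0 if exact else 0.0
        rows["lack_of_fit"] = (ss_lof, df_lof, ms_lof)
        rows["pure_error"] = (ss_pe, df_pe, ms_pe)
    else:
        f_lof = p_lof = None
        rows["lack_of_fit"] = (ss_lof, df_lof, None)
        rows["pure_error"] = (ss_pe, df_pe, None)
    rows["total"] = (ss_total, n - 1, None)
    return AnovaTable(rows, float(f_reg), p_reg, f_lof, p_lof, conf_level)


@dataclass
class TukeyResult:
    """All-pairs Tukey (Tukey–Kramer for unequal n) with letter display."""

    groups: list[str]
    means: np.ndarray
    pooled_ms: float
    df_error: int
    alpha: float
    q_critical: float
    significant: pd.DataFrame = field(repr=False)  # bool matrix, groups x groups
    p_values: pd.DataFrame = field(repr=False)
    letters: dict[str, str] = field(default_factory=dict)

    def hsd(self, n: int) -> float:
        """Honest significant difference for balanced group size ``n``."""
        return self.q_critical * np.sqrt(self.pooled_ms / n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "letters": [self.letters[g] for g in self.groups]},
            index=pd.Index(self.groups, name="group"),
        )


def _compact_letters(
    groups: list[str], means: np.ndarray, significant: pd.DataFrame
) -> dict[str, str]:
    """Insert-and-absorb compact letter display, letters in mean-descending order."""
    order = sorted(range(len(groups)), key=lambda i: -means[i])
    sets: list[set[int]] = [set(range(len(groups)))]
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            if not significant.iloc[a, b]:
                continue
            new_sets: list[set[int]] = []
            for s in sets:
                if a in s and b in s:
                    new_sets.extend([s - {a}, s - {b}])
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            sets = [
                s
                for s in new_sets
                if s and not any(s < t for t in new_sets)
            ]
            # dedupe
            uniq = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = uniq
    # order letter sets by the best (largest) mean they contain
    sets.sort(key=lambda s: min(order.index(i) for i in s))
    letters = {g: "" for g in groups}
    for li, s in enumerate(sets):
        ch = chr(ord("a") + li)
        for i in sorted(s, key=lambda i: order.index(i)):
            letters[groups[i]] += ch
    return letters


def tukey_hsd(
    means,
    sds,
    ns,
    groups: list[str] | None = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey HSD from per-group summary statistics.

    Pooled within-group mean square is the replication-weighted average of
    the group variances; the critical value is the studentized-range
    quantile q(alpha; g, df_error).  Unequal group sizes use Tukey–Kramer
    pairwise standard errors.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    g = len(means)
    if g < 2:
        raise ValueError("need at least two groups")
    if np.any(ns < 2):
        raise ValueError("need n >= 2 per group for a pooled error estimate")
    if groups is None:
        groups = [f"g{i + 1}" for i in range(g)]

    df_error = int(np.sum(ns - 1))
    pooled_ms = float(np.sum((ns - 1) * sds**2) / np.sum(ns - 1))
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, g, df_error))

    sig = np.zeros((g, g), dtype=bool)
    pvals = np.ones((g, g))
    for a in range(g):
        for b in range(a + 1, g):
            se = np.sqrt(pooled_ms / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            diff = abs(means[a] - means[b])
            if se == 0:
                q_stat = 0.0 if diff == 0 else np.inf
            else:
                q_stat = diff / se
            p = float(stats.studentized_range.sf(q_stat, g, df_error))
            sig[a, b] = sig[b, a] = q_stat > q_crit
            pvals[a, b] = pvals[b, a] = p
    sig_df = pd.DataFrame(sig, index=groups, columns=groups)
    p_df = pd.DataFrame(pvals, index=groups, columns=groups)
    letters = _compact_letters(list(groups), means, sig_df)
    return TukeyResult(
        groups=list(groups),
        means=means,
        pooled_ms=pooled_ms,
        df_error=df_error,
        alpha=alpha,
        q_critical=q_crit,
        significant=sig_df,
        p_values=p_df,
        letters=letters,
    )
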