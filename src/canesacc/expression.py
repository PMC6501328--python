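"""Relative gene expression by the 2^-ddCt method with multiple references.

dCt = Ct_target - mean(Ct_references) per sample (arithmetic mean of
reference Cts, i.e. geometric mean of reference abundances); ddCt subtracts
the calibrator group's mean dCt; fold change = 2^-ddCt.  Technical
replicates are averaged per (sample, gene) before dCt; biological
replicates propagate to a group SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtTable", "DdctResult", "ddct", "silencing_percent"]


class CtTable:
    """qPCR Ct records: columns ``sample, group, gene, role, ct`` (+ optional ``rep``).

    ``role`` is 'target' or 'reference'; every sample needs at least one
    reference record.
    """

    REQUIRED = ["sample", "group", "gene", "role", "ct"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        bad_roles = set(df["role"]) - {"target", "reference"}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        if not np.all(np.isfinite(df["ct"])):
            raise ValueError("Ct values must be finite")
        self.df = df.copy()
        out_of_range = df[(df["ct"] <= 5) | (df["ct"] >= 40)]
        if len(out_of_range):
            warnings.warn(
                f"{len(out_of_range)} Ct values outside the typical (5, 40) range",
                stacklevel=2,
            )

    def tech_averaged(self) -> pd.DataFrame:
        """Mean Ct per (sample, group, gene, role), collapsing technical reps."""
        return (
            self.df.groupby(["sample", "group", "gene", "role"], as_index=False)["ct"]
            .mean()
        )


@dataclass
class DdctResult:
    target_gene: str
    calibrator_group: str
    per_sample: pd.DataFrame  # sample, group, dct, ddct, fold
    per_group: pd.DataFrame  # group, mean fold, sem, n

    def fold(self, group: str) -> float:
        return float(self.per_group.loc[group, "fold_mean"])


def ddct(table: CtTable, target_gene: str, calibrator_group: str) -> DdctResult:
    """Fold change of ``target_gene`` per sample/group relative to the calibrator."""
    df = table.tech_averaged()
    if target_gene not in set(df.loc[df["role"] == "target", "gene"]):
        raise ValueError(f"target gene {target_gene!r} not present in the table")
    if calibrator_group not in set(df["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} not present")

    rows = []
    for (sample, group), sub in df.groupby(["sample", "group"]):
        refs = sub[sub["role"] == "reference"]
        tgt = sub[(sub["role"] == "target") & (sub["gene"] == target_gene)]
        if refs.empty or tgt.empty:
            warnings.warn(
                f"sample {sample!r} skipped: missing "
                f"{'reference' if refs.empty else 'target'} Ct",
                stacklevel=2,
            )
            continue
        dct = float(tgt["ct"].iloc[0]) - float(refs["ct"].mean())
        rows.append({"sample": sample, "group": group, "dct": dct})
    per_sample = pd.DataFrame(rows)
    if per_sample.empty or calibrator_group not in set(per_sample["group"]):
        raise ValueError(f"no usable samples in calibrator group {calibrator_group!r}")

    cal_mean_dct = per_sample.loc[
        per_sample["group"] == calibrator_group, "dct"
    ].mean()
    per_sample["ddct"] = per_sample["dct"] - cal_mean_dct
    per_sample["fold"] = 2.0 ** (-per_sample["ddct"])

    grp = per_sample.groupby("group")["fold"]
    per_group = pd.DataFrame(
        {
            "fold_mean": grp.mean(),
            "fold_sem": grp.sem(ddof=1).fillna(0.0),
            "n": grp.size(),
        }
    )
    return DdctResult(target_gene, calibrator_group, per_sample, per_group)


def silencing_percent(fold: float) -> float:
    """Percent suppression implied by a fold change: 100 * (1 - fold)."""
    if fold < 0:
        raise ValueError("fold change must be non-negative")
    return 100.0 * (1.0 - fold)
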