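"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is deterministic given its seed and emits the same in-memory
containers (and on-disk formats, via :mod:`canesacc.io`) that the analysis
functions consume, so recovery of the planted truth can be asserted
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CCDDesign
from .offtarget import longest_shared_stretch
from .rsm import COEF_NAMES, ResponseTable, _design_matrix

__all__ = [
    "SurfaceSimSpec",
    "simulate_ccd_responses",
    "simulate_offtarget_set",
    "simulate_ct_table",
    "table1_like_coefficients",
]


def table1_like_coefficients() -> dict[str, float]:
    """True coefficients of a surface shaped like the packaged NT 48-h data.

    The box-constrained argmax sits on the low-ethanol face near coded time
    +1.2, mimicking the published geometry.
    """
    return dict(zip(COEF_NAMES, (22.9, -7.8, 4.5, -1.5, -2.6, -0.25)))


@dataclass
class SurfaceSimSpec:
    """Replicated CCD responses from a known quadratic surface.

    Defaults mirror the packaged experiment: 11-run two-factor CCD, four
    replicates per run, replicate noise SD around 1 g/L (the magnitude of
    the printed replicate SDs).
    """

    coefficients: dict[str, float] = field(default_factory=table1_like_coefficients)
    noise_sd: float = 1.0
    n_replicates: int = 4
    seed: int = 0
    genotype: str = "SIM"
    timepoint: str = "48h"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        missing = set(COEF_NAMES) - set(self.coefficients)
        if missing:
            raise ValueError(f"missing coefficients: {sorted(missing)}")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in COEF_NAMES])


def surface_value(coefficients: dict[str, float], point) -> float:
    """Evaluate a quadratic surface given by named coefficients."""
    beta = np.array([coefficients[c] for c in COEF_NAMES])
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    vals = _design_matrix(pts) @ beta
    return float(vals[0]) if np.asarray(point).ndim == 1 else vals


def simulate_ccd_responses(spec: SurfaceSimSpec, design: CCDDesign) -> ResponseTable:
    """Gaussian replicate noise around the true surface at each design run."""
    rng = np.random.default_rng(spec.seed)
    coded = design.coded_matrix
    means = _design_matrix(coded) @ spec.beta
    rows = []
    for run_id, mu in zip(design.run_ids, means):
        for rep in range(1, spec.n_replicates + 1):
            rows.append(
                {
                    "run_id": run_id,
                    "genotype": spec.genotype,
                    "timepoint": spec.timepoint,
                    "rep": rep,
                    "value": mu + rng.normal(0.0, spec.noise_sd),
                }
            )
    df = pd.DataFrame(rows)
    if (df["value"] <= 0).any():
        # keep values positive as real glucose readings are; shift is noted
        df["value"] = df["value"].clip(lower=1e-6)
    return ResponseTable(df)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _max_clean_segment(length: int, snp_offsets: list[int]) -> int:
    """Longest identity run inside a planted copy broken at the SNP offsets."""
    cuts = sorted(set(snp_offsets))
    edges = [-1] + cuts + [length]
    return max(b - a - 1 for a, b in zip(edges[:-1], edges[1:]))


def simulate_offtarget_set(
    query_length: int = 413,
    planted_lengths: list[int] = (24, 16, 15, 14, 13, 10),
    snp_counts: list[int] | None = None,
    subject_length: int = 1500,
    seed: int = 0,
    max_tries: int = 200,
):
    """Subjects each carrying one planted copy of a query substring.

    ``snp_counts[i]`` SNPs are placed inside subject i's planted copy,
    breaking its identity run.  Rejection sampling guarantees no subject
    shares an accidental stretch longer than its planted (post-SNP) truth.

    Returns ``(query, subjects, truth)`` where ``subjects`` is a list of
    (id, sequence) and ``truth`` a DataFrame with the expected longest
    stretch per subject.
    """
    planted_lengths = list(planted_lengths)
    if snp_counts is None:
        snp_counts = [0] * len(planted_lengths)
    if len(snp_counts) != len(planted_lengths):
        raise ValueError("snp_counts must align with planted_lengths")
    if max(planted_lengths) > min(query_length, subject_length):
        raise ValueError("planted stretch longer than query or subject")

    rng = np.random.default_rng(seed)
    query = _random_seq(rng, query_length)
    subjects, truth_rows = [], []
    for i, (plen, n_snp) in enumerate(zip(planted_lengths, snp_counts)):
        sid = f"SYN_BAHD{i + 2:02d}"  # synthetic candidate family members
        if n_snp >= plen:
            raise ValueError("more SNPs than planted positions")
        for attempt in range(max_tries):
            qstart = int(rng.integers(0, query_length - plen + 1))
            insert = list(query[qstart : qstart + plen])
            offsets = (
                sorted(rng.choice(plen, size=n_snp, replace=False).tolist())
                if n_snp
                else []
            )
            for off in offsets:
                insert[off] = rng.choice(
                    [b for b in "ACGT" if b != insert[off]]
                )
            expected = _max_clean_segment(plen, offsets)
            background = _random_seq(rng, subject_length - plen)
            pos = int(rng.integers(0, len(background) + 1))
            subject = background[:pos] + "".join(insert) + background[pos:]
            actual = longest_shared_stretch(query, subject).length
            if actual == expected:
                subjects.append((sid, subject))
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "planted_length": plen,
                        "n_snps": n_snp,
                        "expected_longest_stretch": expected,
                    }
                )
                break
        else:
            raise RuntimeError(
                f"could not plant a clean {plen}-mer in {max_tries} tries"
            )
    truth = pd.DataFrame(truth_rows)
    return query, subjects, truth


def simulate_ct_table(
    fold_changes: dict[str, float],
    calibrator_group: str,
    n_samples: int = 3,
    reference_genes: tuple[str, ...] = ("GAPDH", "EF1"),
    target_gene: str = "BAHD01",
    base_target_ct: float = 25.0,
    reference_cts: tuple[float, ...] = (18.0, 20.0),
    sample_drift_sd: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Ct table whose 2^-ddCt analysis recovers the given fold changes.

    Each group's target Ct is shifted by -log2(fold) relative to the
    calibrator; a per-sample global Ct drift (loading differences) is added
    to every gene of a sample and cancels in dCt; measurement noise with SD
    ``noise_sd`` is added per well.
    """
    if calibrator_group not in fold_changes:
        fold_changes = {**fold_changes, calibrator_group: 1.0}
    if any(f <= 0 for f in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in fold_changes.items():
        shift = -np.log2(fold)
        for s in range(1, n_samples + 1):
            sample = f"{group}_s{s}"
            drift = rng.normal(0.0, sample_drift_sd)
            for gene, ct0 in zip(reference_genes, reference_cts):
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "role": "reference",
                        "ct": ct0 + drift + rng.normal(0.0, noise_sd),
                    }
                )
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": target_gene,
                    "role": "target",
                    "ct": base_target_ct + shift + drift + rng.normal(0.0, noise_sd),
                }
            )
    from .expression import CtTable

    return CtTable(pd.DataFrame(rows))
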