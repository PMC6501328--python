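"""Readers/writers for the package's delimited formats and packaged data.

Packaged fixtures carry the organosolv CCD glucose-release experiment used
throughout the documentation: an 11-run two-factor design (ethanol % v/v,
residence time min), replicate-summarized glucose responses for six
sugarcane genotypes at two hydrolysis timepoints, and the independent
validation measurements at 30% ethanol / 240 min.  Values are stored
exactly as published (2 decimals), never re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import CCDDesign, FactorScale, load_design_table
from .expression import CtTable
from .rsm import ResponseTable

__all__ = [
    "PipelineConfig",
    "load_config",
    "load_fixtures",
    "packaged_factor_scales",
    "read_response_table",
    "write_response_table",
    "read_ct_table",
    "write_ct_table",
    "read_fasta",
    "write_fasta",
]


@dataclass
class PipelineConfig:
    """Run-wide settings: factor scales, confidence levels, region, k-mer, seed."""

    factors: list[FactorScale]
    model_conf_level: float = 0.90
    tukey_conf_level: float = 0.95
    region: str = "box"  # box | sphere
    kmer_length: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        for lvl in (self.model_conf_level, self.tukey_conf_level):
            if not (0.0 < lvl < 1.0):
                raise ValueError("confidence levels must lie in (0, 1)")
        if self.region not in ("box", "sphere"):
            raise ValueError("region must be 'box' or 'sphere'")


def _factor_from_mapping(m: dict) -> FactorScale:
    return FactorScale(
        name=m["name"],
        unit=m.get("unit", ""),
        center_real=float(m["center"]),
        axial_low_real=float(m["axial_low"]),
        axial_high_real=float(m["axial_high"]),
        alpha=float(m.get("alpha", 1.41)),
    )


def load_config(path) -> PipelineConfig:
    """Load a YAML config (factor definitions plus optional settings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    factors = [_factor_from_mapping(m) for m in raw["factors"]]
    kwargs = {
        k: raw[k]
        for k in ("model_conf_level", "tukey_conf_level", "region", "kmer_length", "seed")
        if k in raw
    }
    return PipelineConfig(factors=factors, **kwargs)


def packaged_factor_scales() -> list[FactorScale]:
    """Factor scales of the packaged experiment (alpha printed as 1.41).

    Ethanol: 30-100% v/v centered at 65; residence time: 0-240 min centered
    at 120.  The axial distance is fixed at the two-decimal 1.41 because
    that value, not sqrt(2), reproduces the published real levels (40.2%
    ethanol and 34.9 min at coded -1).
    """
    data = resources.files("canesacc.data").joinpath("factors.yaml")
    raw = yaml.safe_load(data.read_text())
    return [_factor_from_mapping(m) for m in raw["factors"]]


@dataclass
class Fixtures:
    design: CCDDesign  # as printed, including the nonstandard run 2
    responses: ResponseTable  # mean/sd/n summaries, n=4
    validation: pd.DataFrame = field(repr=False)  # experimental + published columns


def load_fixtures() -> Fixtures:
    """The packaged design, response, and validation tables."""
    factors = packaged_factor_scales()
    data = resources.files("canesacc.data")
    with resources.as_file(data.joinpath("ccd_design.csv")) as p:
        design = load_design_table(p, factors)
    responses = ResponseTable(pd.read_csv(data.joinpath("glucose_responses.csv")))
    validation = pd.read_csv(data.joinpath("validation.csv"))
    if len(design.runs) != 11:
        raise RuntimeError("packaged design corrupted: expected 11 runs")
    counts = responses.df.groupby(["genotype", "timepoint"]).size()
    if not (counts == 11).all() or len(counts) != 12:
        raise RuntimeError("packaged responses corrupted: expected 6x2 series of 11 runs")
    if len(validation) != 12:
        raise RuntimeError("packaged validation table corrupted: expected 12 records")
    return Fixtures(design=design, responses=responses, validation=validation)


def read_response_table(path) -> ResponseTable:
    return ResponseTable(pd.read_csv(path))


def write_response_table(table: ResponseTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_ct_table(path) -> CtTable:
    return CtTable(pd.read_csv(path))


def write_ct_table(table: CtTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    """FASTA records as (id, uppercase sequence); duplicate ids are an error."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate FASTA ids {dups}")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")
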