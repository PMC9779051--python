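"""Readers/writers for FASTA, BED6, TSV tables and GMT gene sets, plus the
run configuration.

All genomic coordinates are 0-based half-open BED conventions; a
BED → internal → BED roundtrip is the identity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, FormatError


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Contig name → upper-cased sequence; duplicate names or empty records
    are format errors."""
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"contig {rec.id!r} has an empty sequence")
        genome[rec.id] = seq
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_tss_bed(path) -> pd.DataFrame:
    """6-column stranded TSS BED → table(chrom, tss, strand, gene_id, ...).

    The TSS is the interval start on the + strand and ``end − 1`` on the −
    strand.  Strand is required ('.' is a format error): the promoter
    window is strand-asymmetric.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse BED file {path}: {exc}") from exc
    if df.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 BED columns, found {df.shape[1]}")
    df.columns = _BED6_COLS
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer coordinates") from exc
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(
            f"{path}: strand must be '+' or '-' for every TSS record "
            f"(found {sorted(df.loc[bad, 'strand'].unique())})"
        )
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    df = df.rename(columns={"name": "gene_id"})
    return df[["chrom", "tss", "strand", "gene_id", "start", "end", "score"]]


def write_tss_bed(annotation: pd.DataFrame, path) -> None:
    """Write a TSS annotation (chrom, tss, strand, gene_id) as BED6.

    The TSS occupies a 1-bp interval; + strand records place it at
    ``start``, − strand records at ``end − 1`` — matching
    :func:`read_tss_bed`'s convention so the roundtrip is identity.
    """
    out = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["tss"],
            "end": annotation["tss"] + 1,
            "name": annotation["gene_id"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_peaks_bed(peaks, path) -> None:
    """Peaks/DEPs as BED6 with score = −log10 p and direction as strand
    surrogate in the name field."""
    rows = []
    for i, p in enumerate(peaks):
        name = getattr(p, "direction", "peak")
        rows.append((p.chrom, p.start, p.end, f"{name}_{i}", round(p.score, 4), "."))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_probe_table(path) -> pd.DataFrame:
    """Probe TSV: probe_id, chrom, start, end + one column per array."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: probe table needs columns {sorted(required)}")
    if df.shape[1] <= 4:
        raise FormatError(f"{path}: probe table has no array columns")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_expression(path) -> pd.DataFrame:
    """Gene × sample log2 expression TSV, first column gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None or len(df.columns) == 0:
        raise FormatError(f"{path}: expected gene_id index plus sample columns")
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: expression matrix contains missing values")
    return df


def read_gmt(path) -> Dict[str, List[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT lines need >= 3 fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate gene set {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths, group assignments and thresholds of one pipeline run.

    Threshold defaults are the published operating point of the method:
    1500-bp scan window, ≥2 probes and −log10 p ≥ 2 per peak, 500-bp merge
    spacing, median enrichment ≥ 0.3, CV ≤ 0.8, DMG gates p < 0.01 and
    |M difference| > 0.4, DEG gates pfp ≤ 0.05 and fold change 1.5.
    """

    genome_fasta: Optional[str] = None
    tss_bed: Optional[str] = None
    probe_table: Optional[str] = None
    expression_tsv: Optional[str] = None
    geneset_gmt: Optional[str] = None
    groups: Dict[str, List[str]] = field(default_factory=dict)
    methylome_comparison: List[str] = field(default_factory=lambda: ["CN", "LP"])
    expression_comparison: List[str] = field(default_factory=lambda: ["CN", "LP"])
    rebound_comparison: List[str] = field(default_factory=lambda: ["CN-R", "LP-R"])
    window: int = 1500
    min_probes: int = 2
    min_score: float = 2.0
    merge_spacing: int = 500
    median_threshold: float = 0.3
    cv_threshold: float = 0.8
    dmg_p: float = 0.01
    dmg_mdiff: float = 0.4
    fdr: float = 0.05
    fc: float = 1.5
    n_perm: int = 1000
    window_test: str = "ks"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def manifest(self) -> Dict:
        from . import __version__

        d = dataclasses.asdict(self)
        d["medipchip_version"] = __version__
        return d

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")
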