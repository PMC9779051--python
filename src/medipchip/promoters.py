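"""Stranded promoter extraction and CpG-density classification.

Promoters are the −700/+200 bp windows around annotated transcription start
sites (TSS).  Each promoter is assigned one of three CpG-density classes by
scanning every 500-bp sub-window at 1-bp steps:

* **HCP** (high-CpG-density): some 500-bp window has GC content ≥ 55% *and*
  CpG observed/expected ratio ≥ 0.6;
* **LCP** (low-CpG-density): no 500-bp window reaches CpG O/E ≥ 0.4;
* **ICP** (intermediate): everything else.

The CpG O/E ratio for a window of unambiguous length *N* is
``(#CpG × N) / (#C × #G)``, the observed CpG dinucleotide count relative to
its expectation under mononucleotide independence.  Ambiguity codes (N etc.)
are excluded from all counts, including the length; windows that are more
than half ambiguous are skipped.

Coordinates are 0-based half-open throughout; the TSS is the 0-based
position of the first transcribed base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import CoordinateError

PROMOTER_UPSTREAM = 700
PROMOTER_DOWNSTREAM = 200
CLASS_WINDOW = 500
HCP_GC = 0.55
HCP_OE = 0.60
LCP_OE = 0.40

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRecord:
    """A stranded promoter window with its CpG-density summary statistics."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic, 0-based half-open
    end: int
    sequence: str
    clipped: bool = False
    gc: float = field(default=np.nan)
    cpg_oe: float = field(default=np.nan)
    promoter_class: Optional[str] = None


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / #unambiguous-bases of a DNA string."""
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    s = seq.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    n_valid = n_c + n_g + s.count("A") + s.count("T")
    if n_valid == 0:
        return 0.0
    return (n_g + n_c) / n_valid


def cpg_oe(seq: str) -> float:
    """CpG observed/expected ratio ``(#CpG × N) / (#C × #G)``.

    *N* counts unambiguous bases only.  Defined as 0 when the sequence has
    no C or no G (the expectation is then zero and so is the observation).
    """
    if not seq:
        raise ValueError("cpg_oe of an empty sequence is undefined")
    s = seq.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_valid = n_c + n_g + s.count("A") + s.count("T")
    n_cpg = s.count("CG")
    return n_cpg * n_valid / (n_c * n_g)


def extract_promoter(
    genome: Mapping[str, str],
    chrom: str,
    tss: int,
    strand: str,
    gene_id: str,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PromoterRecord:
    """Extract the −upstream/+downstream promoter window around a TSS.

    On the + strand the genomic interval is ``[tss-upstream, tss+downstream)``;
    on the − strand it is the mirror ``[tss-downstream, tss+upstream)`` and
    the returned sequence is reverse-complemented so that it always reads
    5'→3' on the gene's own strand.  Windows running off the contig are
    clipped and flagged.
    """
    if chrom not in genome:
        raise CoordinateError(f"unknown contig {chrom!r}")
    contig = genome[chrom]
    if not 0 <= tss < len(contig):
        raise CoordinateError(
            f"TSS {tss} outside contig {chrom!r} (length {len(contig)})"
        )
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    elif strand == "-":
        lo, hi = tss - downstream, tss + upstream
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    start, end = max(lo, 0), min(hi, len(contig))
    clipped = (start != lo) or (end != hi)
    seq = contig[start:end].upper()
    if strand == "-":
        seq = reverse_complement(seq)
    rec = PromoterRecord(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        sequence=seq,
        clipped=clipped,
    )
    rec.gc = gc_content(seq)
    rec.cpg_oe = cpg_oe(seq)
    return rec


def _window_stats(seq: str, window: int):
    """Per-window (gc, oe, evaluable) arrays for all ``window``-bp windows."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_acgt = is_c | is_g | (arr == ord("A")) | (arr == ord("T"))
    is_cg = np.zeros(arr.size, dtype=bool)
    if arr.size > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]

    def winsum(x, width):
        c = np.concatenate(([0], np.cumsum(x)))
        return c[width:] - c[: x.size - width + 1]

    n = arr.size
    n_win = n - window + 1
    nc = winsum(is_c, window).astype(float)
    ng = winsum(is_g, window).astype(float)
    nvalid = winsum(is_acgt, window).astype(float)
    # a CpG belongs to the window iff both bases are inside it
    ncg = winsum(is_cg[: n - 1], window - 1).astype(float)[:n_win]
    evaluable = nvalid > window / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(nvalid > 0, (nc + ng) / nvalid, 0.0)
        oe = np.where((nc > 0) & (ng > 0), ncg * nvalid / (nc * ng), 0.0)
    return gc, oe, evaluable


def classify_sequence(seq: str, window: int = CLASS_WINDOW) -> str:
    """Classify a promoter sequence as HCP / ICP / LCP.

    Sequences shorter than ``window`` are evaluated on their full length.
    A pure string function: total, and independent of which strand's
    promoter convention produced the sequence.
    """
    if not seq:
        raise ValueError("cannot classify an empty sequence")
    if len(seq) < window:
        gc, oe = gc_content(seq), cpg_oe(seq)
        if gc >= HCP_GC and oe >= HCP_OE:
            return "HCP"
        return "LCP" if oe < LCP_OE else "ICP"
    gc, oe, ok = _window_stats(seq, window)
    if not ok.any():
        # every window majority-ambiguous: fall back to whole-sequence stats
        gc_full, oe_full = gc_content(seq), cpg_oe(seq)
        if gc_full >= HCP_GC and oe_full >= HCP_OE:
            return "HCP"
        return "LCP" if oe_full < LCP_OE else "ICP"
    gc, oe = gc[ok], oe[ok]
    if bool(np.any((gc >= HCP_GC) & (oe >= HCP_OE))):
        return "HCP"
    if not bool(np.any(oe >= LCP_OE)):
        return "LCP"
    return "ICP"


def classify_promoter(rec: PromoterRecord, window: int = CLASS_WINDOW) -> str:
    """Assign and return the promoter class of a :class:`PromoterRecord`."""
    rec.promoter_class = classify_sequence(rec.sequence, window=window)
    return rec.promoter_class


def annotate_promoters(
    genome: Mapping[str, str],
    tss_table: pd.DataFrame,
) -> pd.DataFrame:
    """Extract and classify every promoter of a TSS annotation.

    ``tss_table`` needs columns chrom, tss, strand, gene_id (as produced by
    :func:`medipchip.io.read_tss_bed`).  Returns a table with one row per
    gene: gene_id, chrom, start, end, strand, gc, cpg_oe, promoter_class,
    clipped.
    """
    rows = []
    for t in tss_table.itertuples(index=False):
        rec = extract_promoter(genome, t.chrom, int(t.tss), t.strand, t.gene_id)
        classify_promoter(rec)
        rows.append(
            (rec.gene_id, rec.chrom, rec.start, rec.end, rec.strand,
             rec.gc, rec.cpg_oe, rec.promoter_class, rec.clipped)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand",
                 "gc", "cpg_oe", "promoter_class", "clipped"],
    )
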