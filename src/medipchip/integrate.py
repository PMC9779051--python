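"""Methylome–transcriptome integration and gene-set enrichment.

Promoter methylation is expected to repress transcription, so the synergy
join keeps only discordant gene states: transcriptionally *down* with a
*hyper*methylated promoter, or *up* with a *hypo*methylated one.
Persistence intersects two DEG calls (post-restriction and post-rebound)
and keeps genes altered in the same direction in both.  Gene-set enrichment
is a self-contained one-sided hypergeometric test with Benjamini–Hochberg
correction over the collection, reported on the log2(q) scale with the
conventional significance gate log2(q) < −2.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import IntegrityError

SYNERGY_PAIRS = (("down", "hyper"), ("up", "hypo"))
DEFAULT_LOG2_Q_GATE = -2.0


def _require_unique(df: pd.DataFrame, name: str):
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"duplicate gene_id in {name}: {sorted(df.loc[dup, 'gene_id'])[:5]}"
        )


def synergy_table(
    degs: pd.DataFrame, dmgs: pd.DataFrame
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Join DEG and DMG tables into discordant synergy records.

    ``degs`` needs gene_id + direction (up/down); ``dmgs`` needs gene_id,
    direction (hyper/hypo), promoter_class and peak_dm_value.  Returns the
    synergy table (gene_id, transcription_status, methylation_status,
    promoter_class, peak_dm_value) and the per-category counts
    ``{"down+hyper": ..., "up+hypo": ...}``.
    """
    _require_unique(degs, "DEG table")
    _require_unique(dmgs, "DMG table")
    joined = degs.merge(
        dmgs, on="gene_id", suffixes=("_expr", "_meth"), how="inner"
    )
    rows = []
    for t in joined.itertuples(index=False):
        pair = (t.direction_expr, t.direction_meth)
        if pair in SYNERGY_PAIRS:
            rows.append(
                (t.gene_id, t.direction_expr, t.direction_meth,
                 t.promoter_class, t.peak_dm_value)
            )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "transcription_status", "methylation_status",
                 "promoter_class", "peak_dm_value"],
    ).sort_values("gene_id").reset_index(drop=True)
    counts = {
        f"{e}+{m}": int(
            ((table["transcription_status"] == e)
             & (table["methylation_status"] == m)).sum()
        )
        for e, m in SYNERGY_PAIRS
    }
    return table, counts


def persistence(
    degs_main: pd.DataFrame, degs_rebound: pd.DataFrame
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Genes differentially expressed in the same direction in both calls.

    Both tables need gene_id + direction and must come from calls at the
    same thresholds.  Returns (records, counts-per-direction); symmetric in
    its arguments and idempotent.
    """
    _require_unique(degs_main, "main DEG table")
    _require_unique(degs_rebound, "rebound DEG table")
    joined = degs_main[["gene_id", "direction"]].merge(
        degs_rebound[["gene_id", "direction"]],
        on="gene_id", suffixes=("_main", "_rebound"),
    )
    keep = joined["direction_main"] == joined["direction_rebound"]
    table = (
        joined.loc[keep, ["gene_id", "direction_main"]]
        .rename(columns={"direction_main": "direction"})
        .sort_values("gene_id")
        .reset_index(drop=True)
    )
    counts = {
        d: int((table["direction"] == d).sum()) for d in ("up", "down")
    }
    return table, counts


def geneset_enrichment(
    hits: Iterable[str],
    universe: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    log2_q_gate: float = DEFAULT_LOG2_Q_GATE,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``hits`` in each gene set.

    Every set is first intersected with the universe.  P(overlap ≥ k) comes
    from the hypergeometric tail; q-values are Benjamini–Hochberg across the
    collection and reported as log2(q) with ``significant`` flagging
    log2(q) < ``log2_q_gate``.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits or not universe:
        raise ValueError("hits and universe must be non-empty")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    m = len(universe)
    n = len(hits)
    rows = []
    for name, genes in collections.items():
        in_univ = set(genes) & universe
        k_set = len(in_univ)
        overlap = len(in_univ & hits)
        # P(X >= overlap), X ~ Hypergeom(M=m, n=k_set, N=n)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_set, n))
        rows.append((name, k_set, overlap, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pval"])
    if len(df):
        df["qval"] = multipletests(df["pval"].to_numpy(), method="fdr_bh")[1]
        with np.errstate(divide="ignore"):
            df["log2_q"] = np.log2(df["qval"])
        df["significant"] = df["log2_q"] < log2_q_gate
    return df.sort_values("pval").reset_index(drop=True)
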