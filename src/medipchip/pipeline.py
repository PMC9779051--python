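"""End-to-end orchestration: file-driven runs and in-memory fixture studies.

:func:`run_pipeline` executes the full inference chain from files named in a
:class:`~medipchip.io.RunConfig` and writes every stage's table plus a run
manifest.  The two ``run_*_study`` helpers regenerate the published-table
fixture datasets in memory and push them through the same stage functions;
they are what the acceptance checks and the worked README example run.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import integrate, io, medip, rankprod, simulate
from .errors import ConfigError
from .promoters import annotate_promoters

logger = logging.getLogger("medipchip")


def _derive_seed(seed: int, stream: int) -> int:
    return int((int(seed) * 1009 + stream * 9973) % (2**31 - 1))


# ---------------------------------------------------------------------------
# in-memory stage drivers (shared by file pipeline and fixture studies)
# ---------------------------------------------------------------------------

def methylome_stage(
    probe_df: pd.DataFrame,
    groups: Dict[str, List[str]],
    comparison: List[str],
    promoters: pd.DataFrame,
    cfg: io.RunConfig,
) -> Dict:
    """Normalize → M′ → DEPs → filters → DMGs for one two-group comparison."""
    control, treatment = comparison
    for g in comparison:
        if g not in groups or not groups[g]:
            raise ConfigError(f"no arrays assigned to group {g!r}")
    # replicate arrays are normalized within their condition: quantile
    # normalization across conditions would flatten genuine group-level
    # enrichment differences, the very signal M' measures
    normed = medip.normalize(probe_df, groups[control])
    normed = medip.normalize(normed, groups[treatment])
    e_vals = normed[groups[treatment]].to_numpy(dtype=float)
    c_vals = normed[groups[control]].to_numpy(dtype=float)
    m_prime = medip.compute_m_prime(e_vals, c_vals)
    deps = medip.find_differential_peaks(
        normed, m_prime,
        window=cfg.window, min_probes=cfg.min_probes,
        min_score=cfg.min_score, merge_spacing=cfg.merge_spacing,
        test=cfg.window_test,
    )
    retained = medip.filter_deps(
        deps, e_vals, c_vals,
        median_threshold=cfg.median_threshold, cv_threshold=cfg.cv_threshold,
    )
    dmgs = medip.call_dmgs(
        retained, promoters, p_threshold=cfg.dmg_p, m_diff=cfg.dmg_mdiff
    )
    return {
        "normalized": normed, "m_prime": m_prime, "deps": deps,
        "retained_deps": retained, "dmgs": dmgs,
    }


def expression_stage(
    matrix: pd.DataFrame,
    groups: Dict[str, List[str]],
    comparison: List[str],
    cfg: io.RunConfig,
    seed_stream: int = 1,
) -> pd.DataFrame:
    control, treatment = comparison
    for g in comparison:
        if g not in groups or not groups[g]:
            raise ConfigError(f"no samples assigned to group {g!r}")
    return rankprod.call_degs(
        matrix, groups[control], groups[treatment],
        fdr=cfg.fdr, fc=cfg.fc, n_perm=cfg.n_perm,
        seed=_derive_seed(cfg.seed, seed_stream),
    )


# ---------------------------------------------------------------------------
# fixture studies
# ---------------------------------------------------------------------------

def run_synergy_study(
    seed: int,
    n_null: int = 200,
    n_perm: int = 200,
    window_test: str = "ks",
) -> Dict:
    """Full-pipeline run on the synergy-table fixture.

    Plants the 27 published discordant genes (13 expression-down with
    promoter hypermethylation, 14 up with hypomethylation; effect sizes 1.0
    log2 units, probe noise 0.2, expression noise 0.1, 3 arrays/group)
    among ``n_null`` unaffected genes, then runs the methylome chain, the
    rank-product DEG caller (CN vs LP) and the synergy join.  Returns the
    stage outputs plus the synergy category counts.
    """
    effects = simulate.build_table_fixture("table6")
    classes = simulate.table6_promoter_classes()
    table_genes = [e.gene_id for e in effects]
    n_total = len(table_genes) + n_null
    # differentially methylated genes scatter across a real genome: spread
    # the planted promoters evenly among the null genes rather than packing
    # them into adjacent slots
    planted_slots = set(
        np.linspace(0, n_total - 1, len(table_genes)).round().astype(int)
    )
    gene_ids: List[str] = []
    archetypes: List[str] = []
    it_table = iter(table_genes)
    null_i = 0
    for slot in range(n_total):
        if slot in planted_slots:
            g = next(it_table)
            gene_ids.append(g)
            archetypes.append(simulate.ARCHETYPE_FOR_CLASS[classes[g]])
        else:
            gene_ids.append(f"null{null_i:04d}")
            archetypes.append(simulate.ARCHETYPES[null_i % 3])
            null_i += 1

    cfg = simulate.SimConfig(
        seed=_derive_seed(seed, 11), n_genes=len(gene_ids),
        noise_sd=0.2, expr_noise_sd=0.1,
        planted_dm_effect=1.0, planted_expr_effect=1.0,
    )
    genome, ann = simulate.make_genome(cfg, archetypes=archetypes, gene_ids=gene_ids)
    promoters = annotate_promoters(genome, ann)

    medip_tables = simulate.simulate_medip(cfg, effects, ann)
    probe_df, groups = medip.combine_groups(medip_tables)
    run_cfg = io.RunConfig(seed=seed, n_perm=n_perm, window_test=window_test)
    meth = methylome_stage(probe_df, groups, ["CN", "LP"], promoters, run_cfg)

    expr, expr_groups = simulate.simulate_expression(cfg, effects, gene_ids)
    degs = expression_stage(expr, expr_groups, ["CN", "LP"], run_cfg, seed_stream=21)

    table, counts = integrate.synergy_table(degs, meth["dmgs"])
    return {
        "config": cfg, "effects": effects, "promoters": promoters,
        "probe_df": probe_df, "groups": groups, **meth,
        "expression": expr, "degs": degs,
        "synergy": table, "counts": counts,
    }


def run_persistence_study(
    seed: int,
    n_null: int = 200,
    n_perm: int = 200,
) -> Dict:
    """Both-comparison run on the persistent-gene fixture.

    Plants the 17 published persistently altered genes (6 up / 11 down,
    2-fold effects, expression noise 0.1, 3 arrays/group) among ``n_null``
    unaffected genes across all four feeding groups, calls DEGs for
    CN-vs-LP and CN-R-vs-LP-R at pfp ≤ 0.05 with the 1.5 fold-change gate,
    and intersects the calls sign-concordantly.
    """
    effects = simulate.build_table_fixture("table4")
    gene_ids = [e.gene_id for e in effects] + [f"null{i:04d}" for i in range(n_null)]
    cfg = simulate.SimConfig(
        seed=_derive_seed(seed, 31), n_genes=len(gene_ids),
        expr_noise_sd=0.1, planted_expr_effect=1.0,
    )
    expr, groups = simulate.simulate_expression(cfg, effects, gene_ids)
    run_cfg = io.RunConfig(seed=seed, n_perm=n_perm)
    degs_main = expression_stage(expr, groups, ["CN", "LP"], run_cfg, seed_stream=41)
    degs_rebound = expression_stage(
        expr, groups, ["CN-R", "LP-R"], run_cfg, seed_stream=42
    )
    table, counts = integrate.persistence(degs_main, degs_rebound)
    return {
        "config": cfg, "effects": effects, "expression": expr,
        "degs_main": degs_main, "degs_rebound": degs_rebound,
        "persistence": table, "counts": counts,
    }


# ---------------------------------------------------------------------------
# file-driven pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: io.RunConfig, outdir, methylome_only: bool = False) -> Dict[str, Path]:
    """Execute every configured stage from files and write result tables.

    Returns the mapping of output names to written paths.  Deterministic
    given the config (including seed); the manifest records every effective
    threshold so a rerun from the manifest reproduces the outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    t0 = time.time()

    promoters = None
    if cfg.genome_fasta and cfg.tss_bed:
        genome = io.read_fasta(cfg.genome_fasta)
        tss = io.read_tss_bed(cfg.tss_bed)
        promoters = annotate_promoters(genome, tss)
        path = outdir / "promoters.tsv"
        io.write_tsv(promoters, path)
        written["promoters"] = path
        for cls in ("HCP", "ICP", "LCP"):
            sub = promoters[promoters["promoter_class"] == cls]
            bed = sub.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]]
            p = outdir / f"promoters_{cls}.bed"
            bed.to_csv(p, sep="\t", header=False, index=False)
            written[f"promoters_{cls}"] = p
        logger.info("promoters: %d classified (%.1fs)", len(promoters), time.time() - t0)

    dmgs = None
    if cfg.probe_table:
        if promoters is None:
            raise ConfigError("the methylome stage needs genome_fasta and tss_bed")
        probe_df = io.read_probe_table(cfg.probe_table)
        meth = methylome_stage(
            probe_df, cfg.groups, cfg.methylome_comparison, promoters, cfg
        )
        dmgs = meth["dmgs"]
        io.write_peaks_bed(meth["deps"], outdir / "deps.bed")
        written["deps"] = outdir / "deps.bed"
        io.write_tsv(dmgs, outdir / "dmgs.tsv")
        written["dmgs"] = outdir / "dmgs.tsv"
        logger.info("methylome: %d DEPs, %d retained, %d DMGs",
                    len(meth["deps"]), len(meth["retained_deps"]), len(dmgs))

    degs_main = degs_rebound = None
    if cfg.expression_tsv and not methylome_only:
        matrix = io.read_expression(cfg.expression_tsv)
        degs_main = expression_stage(matrix, cfg.groups, cfg.expression_comparison, cfg, 1)
        io.write_tsv(degs_main, outdir / "degs_main.tsv")
        written["degs_main"] = outdir / "degs_main.tsv"
        rebound_ready = all(
            g in cfg.groups and cfg.groups[g] for g in cfg.rebound_comparison
        )
        if rebound_ready:
            degs_rebound = expression_stage(matrix, cfg.groups, cfg.rebound_comparison, cfg, 2)
            io.write_tsv(degs_rebound, outdir / "degs_rebound.tsv")
            written["degs_rebound"] = outdir / "degs_rebound.tsv"
        logger.info("expression: %d main DEGs%s", len(degs_main),
                    f", {len(degs_rebound)} rebound DEGs" if degs_rebound is not None else "")

        if dmgs is not None:
            table, counts = integrate.synergy_table(degs_main, dmgs)
            io.write_tsv(table, outdir / "synergy.tsv")
            written["synergy"] = outdir / "synergy.tsv"
            logger.info("synergy: %s", counts)
        if degs_rebound is not None:
            table, counts = integrate.persistence(degs_main, degs_rebound)
            io.write_tsv(table, outdir / "persistence.tsv")
            written["persistence"] = outdir / "persistence.tsv"
            logger.info("persistence: %s", counts)
        if cfg.geneset_gmt:
            collections = io.read_gmt(cfg.geneset_gmt)
            hits = set(degs_main["gene_id"])
            if hits:
                enr = integrate.geneset_enrichment(hits, set(matrix.index), collections)
                io.write_tsv(enr, outdir / "enrichment.tsv")
                written["enrichment"] = outdir / "enrichment.tsv"

    cfg.write_manifest(outdir / "manifest.json")
    written["manifest"] = outdir / "manifest.json"
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return written
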