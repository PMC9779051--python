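"""Synthetic genomes, tiled MeDIP probe signals, and 4-group expression data.

The generator plants known effects so that every downstream stage — promoter
classification, differential-enrichment peak calling, rank-product DEG
calling, and methylome/transcriptome integration — can be validated against
ground truth without external array data.

What the simulation emulates
----------------------------
* a single-contig genome whose gene promoters are drawn from three base
  composition archetypes (CpG-rich / intermediate / CpG-poor) designed to
  fall into the HCP / ICP / LCP promoter classes;
* probes tiling the genome at a fixed spacing, each array reporting a
  log2(MeDIP/Input) ratio: Gaussian background noise, plus a baseline
  methylation enrichment over planted differentially-methylated promoters
  (present in both groups) and a ±effect in the treatment group only;
* gene-level log2 expression for the four feeding groups (control CN,
  low-protein LP, and their rebound counterparts CN-R / LP-R), with planted
  up/down effects in LP — and in LP-R too when the effect is persistent.

Two rat-study gene lists ship as ready-made effect fixtures: the set of 17
genes whose expression change persists through rebound feeding (6 up / 11
down) and the set of 27 genes with discordant expression/methylation changes
(13 down+hypermethylated / 14 up+hypomethylated, each with a published
promoter class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, SizingError
from .promoters import PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM, reverse_complement

# Promoters are placed on a fixed grid of per-gene slots.  3000 bp keeps
# adjacent promoters >= 1600 bp apart, beyond the 1500-bp scan window, so a
# peak seeded in one promoter can never reach its neighbour.
GENE_SLOT = 3000
PROMOTER_LEN = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM

ARCHETYPES = ("cpg_rich", "intermediate", "cpg_poor")
ARCHETYPE_FOR_CLASS = {"HCP": "cpg_rich", "ICP": "intermediate", "LCP": "cpg_poor"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    ``noise_sd`` is the per-probe, per-array log2(MeDIP/Input) noise;
    ``expr_noise_sd`` the per-gene, per-array log2-expression noise.
    ``dm_baseline`` is the baseline MeDIP enrichment (log2 units) over every
    planted differentially-methylated promoter in *both* groups — a DMR is a
    region that is genuinely methylated somewhere, so hypomethylation is a
    loss from this baseline rather than "negative methylation".
    """

    seed: int = 0
    n_genes: int = 60
    chrom_length: Optional[int] = None  # derived from n_genes when None
    probe_spacing: int = 100
    probe_length: int = 50
    n_arrays_per_group: int = 3
    noise_sd: float = 0.2
    expr_noise_sd: float = 0.1
    planted_dm_effect: float = 1.0
    planted_expr_effect: float = 1.0
    dm_baseline: float = 1.0
    group_labels: Tuple[str, str, str, str] = ("CN", "LP", "CN-R", "LP-R")

    def __post_init__(self):
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if self.noise_sd <= 0 or self.expr_noise_sd <= 0:
            raise ConfigError("noise standard deviations must be > 0")
        if self.probe_spacing <= 0 or self.probe_spacing > 750:
            raise ConfigError(
                "probe_spacing must be in (0, 750] so every 1500-bp window "
                "holds at least two probes"
            )
        if self.n_arrays_per_group < 1:
            raise ConfigError("n_arrays_per_group must be >= 1")
        if len(self.group_labels) != 4 or len(set(self.group_labels)) != 4:
            raise ConfigError("group_labels must be 4 distinct names")
        if self.resolved_chrom_length() < self.min_chrom_length():
            raise SizingError(
                f"chrom_length {self.resolved_chrom_length()} too small for "
                f"{self.n_genes} non-overlapping promoters "
                f"(need >= {self.min_chrom_length()})"
            )

    def min_chrom_length(self) -> int:
        return self.n_genes * GENE_SLOT + 2 * GENE_SLOT

    def resolved_chrom_length(self) -> int:
        return self.chrom_length if self.chrom_length is not None else self.min_chrom_length()


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effect of one gene.

    ``persistent`` effects are present in both the CN-vs-LP and the
    CN-R-vs-LP-R comparison; non-persistent effects only in the first.
    """

    gene_id: str
    dm_direction: str = "none"  # hyper | hypo | none
    expr_direction: str = "none"  # up | down | none
    persistent: bool = False

    def __post_init__(self):
        if self.dm_direction not in ("hyper", "hypo", "none"):
            raise ConfigError(f"bad dm_direction {self.dm_direction!r}")
        if self.expr_direction not in ("up", "down", "none"):
            raise ConfigError(f"bad expr_direction {self.expr_direction!r}")
        if self.persistent and self.expr_direction == "none":
            raise ConfigError("a persistent effect needs an expression direction")


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    # one deterministic sub-stream per (generator, group, array)
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _markov_seq(rng: np.random.Generator, n: int, gc: float, cpg_factor: float) -> str:
    """First-order Markov DNA with GC fraction ``gc`` and a multiplicative
    bias ``cpg_factor`` on P(G | previous base C).

    ``cpg_factor`` < 1 depletes CpG dinucleotides (O/E ≈ cpg_factor for
    mild bias), > 1 enriches them; 1.0 gives an i.i.d. sequence with
    O/E ≈ 1.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    p_after_c = p.copy()
    p_after_c[2] = min(p[2] * cpg_factor, 0.9)
    p_after_c /= p_after_c.sum()
    bases = np.array(list("ACGT"))
    out = np.empty(n, dtype="<U1")
    u = rng.random(n)
    cum = np.cumsum(p)
    cum_c = np.cumsum(p_after_c)
    prev_is_c = False
    for i in range(n):
        c = cum_c if prev_is_c else cum
        j = int(np.searchsorted(c, u[i], side="right"))
        j = min(j, 3)
        out[i] = bases[j]
        prev_is_c = j == 1
    return "".join(out)


_ARCHETYPE_PARAMS = {
    "cpg_rich": (0.60, 1.6),
    "intermediate": (0.45, 1.0),
    "cpg_poor": (0.35, 0.10),
}


def promoter_interval(tss: int, strand: str) -> Tuple[int, int]:
    """Genomic interval of the −700/+200 promoter window (0-based half-open)."""
    if strand == "+":
        return tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    return tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM


def make_genome(
    cfg: SimConfig,
    archetypes: Optional[Sequence[str]] = None,
    gene_ids: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Synthesize a one-contig genome with ``cfg.n_genes`` promoters.

    ``archetypes`` fixes the composition archetype per gene (default: cycle
    through the three archetypes).  Returns ``(genome, annotation)`` where
    the annotation has one row per gene: chrom, tss, strand, gene_id and the
    ground-truth ``archetype``; promoter genomic intervals follow from
    :func:`promoter_interval`.
    """
    length = cfg.resolved_chrom_length()
    chrom = "chrS1"
    if archetypes is None:
        archetypes = [ARCHETYPES[i % 3] for i in range(cfg.n_genes)]
    if len(archetypes) != cfg.n_genes:
        raise ConfigError("one archetype per gene required")
    for a in archetypes:
        if a not in _ARCHETYPE_PARAMS:
            raise ConfigError(f"unknown archetype {a!r}")
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    if len(gene_ids) != cfg.n_genes or len(set(gene_ids)) != cfg.n_genes:
        raise ConfigError("gene_ids must be unique, one per gene")

    rng = _rng(cfg, 0)
    # background: CpG-depleted 40% GC, the bulk genomic norm
    seq = list(_markov_seq(rng, length, 0.40, 0.25))
    rows = []
    for i in range(cfg.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        tss = GENE_SLOT + i * GENE_SLOT + (PROMOTER_UPSTREAM if strand == "+" else PROMOTER_DOWNSTREAM)
        lo, hi = promoter_interval(tss, strand)
        if lo < 0 or hi > length:
            raise SizingError("promoter does not fit on the contig")
        gc, fac = _ARCHETYPE_PARAMS[archetypes[i]]
        prom = _markov_seq(rng, hi - lo, gc, fac)
        if strand == "-":
            # classification reads the gene strand: store its revcomp genomically
            prom = reverse_complement(prom)
        seq[lo:hi] = prom
        rows.append((chrom, tss, strand, gene_ids[i], archetypes[i]))
    ann = pd.DataFrame(rows, columns=["chrom", "tss", "strand", "gene_id", "archetype"])
    return {chrom: "".join(seq)}, ann


# ---------------------------------------------------------------------------
# MeDIP probe signals
# ---------------------------------------------------------------------------

def simulate_medip(
    cfg: SimConfig,
    effects: Iterable[PlantedEffect],
    annotation: pd.DataFrame,
) -> Dict[str, pd.DataFrame]:
    """Tiled per-array log2(MeDIP/Input) tables for the CN and LP groups.

    Probes tile every contig at ``cfg.probe_spacing`` (starts on the spacing
    grid).  Each value is Gaussian noise around 0; probes overlapping a
    planted differentially-methylated promoter additionally carry
    ``cfg.dm_baseline`` in both groups, plus ``±cfg.planted_dm_effect`` in
    the treatment (LP) group only — + for hyper, − for hypo.

    Returns ``{group_label: DataFrame(probe_id, chrom, start, end,
    <group>_1..<group>_n)}`` for the first two group labels.
    """
    effects = list(effects)
    known = set(annotation["gene_id"])
    for e in effects:
        if e.gene_id not in known:
            raise KeyError(f"planted effect references unknown gene {e.gene_id!r}")
    by_gene = {e.gene_id: e for e in effects}

    length = cfg.resolved_chrom_length()
    chrom = annotation["chrom"].iloc[0] if len(annotation) else "chrS1"
    starts = np.arange(0, max(length - cfg.probe_length, 0) + 1, cfg.probe_spacing)
    ends = starts + cfg.probe_length
    n_probes = starts.size

    base = np.zeros(n_probes)     # shared baseline (both groups)
    delta = np.zeros(n_probes)    # treatment-only effect
    for t in annotation.itertuples(index=False):
        eff = by_gene.get(t.gene_id)
        if eff is None or eff.dm_direction == "none":
            continue
        lo, hi = promoter_interval(int(t.tss), t.strand)
        mask = (starts < hi) & (ends > lo)
        base[mask] += cfg.dm_baseline
        delta[mask] += cfg.planted_dm_effect if eff.dm_direction == "hyper" else -cfg.planted_dm_effect

    control, treatment = cfg.group_labels[0], cfg.group_labels[1]
    out = {}
    for gi, group in enumerate((control, treatment)):
        cols = {}
        for a in range(cfg.n_arrays_per_group):
            rng = _rng(cfg, 1, gi, a)
            vals = rng.normal(0.0, cfg.noise_sd, n_probes) + base
            if group == treatment:
                vals = vals + delta
            cols[f"{group}_{a + 1}"] = vals
        df = pd.DataFrame(
            {
                "probe_id": [f"P{i:06d}" for i in range(n_probes)],
                "chrom": chrom,
                "start": starts,
                "end": ends,
                **cols,
            }
        )
        out[group] = df
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SimConfig,
    effects: Iterable[PlantedEffect],
    gene_ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Gene × sample log2 expression for all four feeding groups.

    Gene baselines are drawn once (Uniform(4, 12) log2 units, typical of
    microarray intensity after summarization) and shared across groups;
    planted up/down genes are shifted by ``±cfg.planted_expr_effect`` in LP,
    and in LP-R as well when the effect is persistent.

    Returns ``(matrix, groups)``: the matrix is indexed by gene_id with one
    column per array, ``groups`` maps each group label to its column names.
    """
    effects = list(effects)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    gene_ids = list(gene_ids)
    known = set(gene_ids)
    for e in effects:
        if e.gene_id not in known:
            raise KeyError(f"planted effect references unknown gene {e.gene_id!r}")
    by_gene = {e.gene_id: e for e in effects}
    n = len(gene_ids)

    rng = _rng(cfg, 2)
    baseline = rng.uniform(4.0, 12.0, n)
    shift = np.zeros(n)
    for i, g in enumerate(gene_ids):
        eff = by_gene.get(g)
        if eff is not None and eff.expr_direction != "none":
            shift[i] = cfg.planted_expr_effect if eff.expr_direction == "up" else -cfg.planted_expr_effect
    persistent = np.array(
        [by_gene.get(g) is not None and by_gene[g].persistent for g in gene_ids]
    )

    cn, lp, cnr, lpr = cfg.group_labels
    data = {}
    groups: Dict[str, List[str]] = {g: [] for g in cfg.group_labels}
    for gi, group in enumerate(cfg.group_labels):
        for a in range(cfg.n_arrays_per_group):
            rng = _rng(cfg, 3, gi, a)
            vals = baseline + rng.normal(0.0, cfg.expr_noise_sd, n)
            if group == lp:
                vals = vals + shift
            elif group == lpr:
                vals = vals + np.where(persistent, shift, 0.0)
            col = f"{group}_{a + 1}"
            data[col] = vals
            groups[group].append(col)
    mat = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return mat, groups


# ---------------------------------------------------------------------------
# published-table effect fixtures
# ---------------------------------------------------------------------------

# 17 genes whose expression change persists through rebound feeding.
TABLE_PERSISTENT_UP = (
    "Cyr61",
    "LOC102553868",
    "LOC102554740/LOC103693750",
    "Nmrk2",
    "Palld",
    "Ubap1l",
)
TABLE_PERSISTENT_DOWN = (
    "Cdkn1a",
    "Cebpd",
    "Crem",
    "LOC103689947/Selenbp1",
    "Maf",
    "Nr4a1",
    "Nr4a2",
    "Pde4b",
    "Retsat",
    "Slc25a25",
    "Tmem100",
)

# 27 genes with discordant expression/methylation changes; promoter class as
# published.  13 transcriptionally down + promoter-hypermethylated, then 14
# up + hypomethylated.
TABLE_SYNERGY = (
    # gene_id, promoter_class, expr_direction, dm_direction
    ("Aff4", "HCP", "down", "hyper"),
    ("Cd24", "HCP", "down", "hyper"),
    ("Ctsl", "HCP", "down", "hyper"),
    ("Maf", "HCP", "down", "hyper"),
    ("Zfp91", "HCP", "down", "hyper"),
    ("Zfyve9", "HCP", "down", "hyper"),
    ("Zranb2", "HCP", "down", "hyper"),
    ("Pdk4", "ICP", "down", "hyper"),
    ("Prkag3", "ICP", "down", "hyper"),
    ("Prkar2a", "ICP", "down", "hyper"),
    ("Psmd7", "ICP", "down", "hyper"),
    ("Usp7", "ICP", "down", "hyper"),
    ("Gsta1", "LCP", "down", "hyper"),
    ("Coa3", "HCP", "up", "hypo"),
    ("Kcnc1", "HCP", "up", "hypo"),
    ("Kitlg", "HCP", "up", "hypo"),
    ("Plk2", "HCP", "up", "hypo"),
    ("Stx4", "HCP", "up", "hypo"),
    ("Cxcr4", "ICP", "up", "hypo"),
    ("Jph2", "ICP", "up", "hypo"),
    ("Rgs4", "ICP", "up", "hypo"),
    ("Rps6ka2", "ICP", "up", "hypo"),
    ("Fsd2", "LCP", "up", "hypo"),
    ("Gpihbp1", "LCP", "up", "hypo"),
    ("Steap4", "LCP", "up", "hypo"),
    ("Tie1", "LCP", "up", "hypo"),
    ("Tmem176b", "LCP", "up", "hypo"),
)


def build_table_fixture(table_id: str) -> List[PlantedEffect]:
    """Planted-effect lists mirroring the two published gene tables.

    ``table4``: the 17 persistently altered genes (6 up / 11 down), all
    ``persistent=True``, no methylation effect.  ``table6``: the 27 genes
    with discordant expression/methylation status (13 down+hyper, 14
    up+hypo), not persistent.
    """
    if table_id == "table4":
        ups = [PlantedEffect(g, "none", "up", True) for g in TABLE_PERSISTENT_UP]
        downs = [PlantedEffect(g, "none", "down", True) for g in TABLE_PERSISTENT_DOWN]
        return ups + downs
    if table_id == "table6":
        return [
            PlantedEffect(g, dm, expr, False)
            for g, _cls, expr, dm in TABLE_SYNERGY
        ]
    raise ConfigError(f"unknown table_id {table_id!r} (expected 'table4' or 'table6')")


def table6_promoter_classes() -> Dict[str, str]:
    """Published promoter class (HCP/ICP/LCP) per synergy-table gene."""
    return {g: cls for g, cls, _e, _d in TABLE_SYNERGY}
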