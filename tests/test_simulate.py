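"""Synthetic-data generator: determinism, planted effects, table fixtures."""

import numpy as np
import pandas as pd
import pytest

from medipchip.errors import ConfigError, SizingError
from medipchip.promoters import classify_sequence, extract_promoter
from medipchip.simulate import (
    ARCHETYPE_FOR_CLASS,
    PlantedEffect,
    SimConfig,
    build_table_fixture,
    make_genome,
    promoter_interval,
    simulate_expression,
    simulate_medip,
    table6_promoter_classes,
)

EXPECTED_CLASS = {v: k for k, v in ARCHETYPE_FOR_CLASS.items()}


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(noise_sd=0.0)
        with pytest.raises(ConfigError):
            SimConfig(probe_spacing=800)  # 1500-bp window must hold >= 2 probes
        with pytest.raises(ConfigError):
            SimConfig(n_arrays_per_group=0)
        with pytest.raises(SizingError):
            SimConfig(n_genes=50, chrom_length=10_000)

    def test_effect_validation(self):
        with pytest.raises(ConfigError):
            PlantedEffect("g", dm_direction="sideways")
        with pytest.raises(ConfigError):
            PlantedEffect("g", persistent=True)  # needs an expression direction


class TestGenome:
    def test_fixed_seed_reproduces_bytes(self):
        g1, a1 = make_genome(SimConfig(seed=1, n_genes=6))
        g2, a2 = make_genome(SimConfig(seed=1, n_genes=6))
        assert g1 == g2
        assert a1.equals(a2)
        g3, _ = make_genome(SimConfig(seed=2, n_genes=6))
        assert g3 != g1

    def test_zero_genes_gives_empty_annotation_valid_fasta(self):
        genome, ann = make_genome(SimConfig(n_genes=0))
        assert len(ann) == 0
        (seq,) = genome.values()
        assert set(seq) <= set("ACGT") and len(seq) > 0

    def test_archetypes_recovered_by_classifier(self):
        arch = ["cpg_rich"] * 10 + ["intermediate"] * 10 + ["cpg_poor"] * 10
        genome, ann = make_genome(SimConfig(seed=3, n_genes=30), archetypes=arch)
        hits = {a: 0 for a in set(arch)}
        for t in ann.itertuples(index=False):
            rec = extract_promoter(genome, t.chrom, int(t.tss), t.strand, t.gene_id)
            if classify_sequence(rec.sequence) == EXPECTED_CLASS[t.archetype]:
                hits[t.archetype] += 1
        assert all(v >= 9 for v in hits.values()), hits


@pytest.fixture(scope="module")
def setup():
    cfg = SimConfig(seed=5, n_genes=12, noise_sd=0.2, planted_dm_effect=1.0)
    genome, ann = make_genome(cfg)
    effects = [
        PlantedEffect(ann.gene_id[0], dm_direction="hyper"),
        PlantedEffect(ann.gene_id[3], dm_direction="hypo"),
    ]
    return cfg, ann, simulate_medip(cfg, effects, ann)


class TestMedip:
    def test_probe_grid(self, setup):
        cfg, _, tables = setup
        for df in tables.values():
            assert (df["start"] % cfg.probe_spacing == 0).all()
            assert (df["end"] - df["start"] == cfg.probe_length).all()

    def test_planted_hyper_m_prime_near_effect(self, setup):
        cfg, ann, tables = setup
        lo, hi = promoter_interval(int(ann.tss[0]), ann.strand[0])
        cn, lp = tables["CN"], tables["LP"]
        mask = (cn["start"] < hi) & (cn["end"] > lo)
        e = lp.loc[mask, [c for c in lp if c.startswith("LP_")]].to_numpy()
        c = cn.loc[mask, [c for c in cn if c.startswith("CN_")]].to_numpy()
        m_prime = e.mean(axis=1) - c.mean(axis=1)
        assert m_prime.mean() == pytest.approx(cfg.planted_dm_effect, abs=0.2)

    def test_hypo_mirrors_hyper(self, setup):
        cfg, ann, tables = setup
        lo, hi = promoter_interval(int(ann.tss[3]), ann.strand[3])
        cn, lp = tables["CN"], tables["LP"]
        mask = (cn["start"] < hi) & (cn["end"] > lo)
        e = lp.loc[mask, [c for c in lp if c.startswith("LP_")]].to_numpy()
        c = cn.loc[mask, [c for c in cn if c.startswith("CN_")]].to_numpy()
        assert (e.mean(axis=1) - c.mean(axis=1)).mean() == pytest.approx(
            -cfg.planted_dm_effect, abs=0.2
        )

    def test_null_effect_leaves_groups_equal(self):
        cfg = SimConfig(seed=6, n_genes=8, planted_dm_effect=0.0, noise_sd=0.2)
        genome, ann = make_genome(cfg)
        tables = simulate_medip(cfg, [PlantedEffect(g, dm_direction="hyper")
                                      for g in ann.gene_id], ann)
        cn, lp = tables["CN"], tables["LP"]
        bound = 3 * cfg.noise_sd / np.sqrt(cfg.n_arrays_per_group)
        for t in ann.itertuples(index=False):
            lo, hi = promoter_interval(int(t.tss), t.strand)
            mask = (cn["start"] < hi) & (cn["end"] > lo)
            diff = (
                lp.loc[mask, [c for c in lp if c.startswith("LP_")]].mean().mean()
                - cn.loc[mask, [c for c in cn if c.startswith("CN_")]].mean().mean()
            )
            assert abs(diff) < bound

    def test_unknown_gene_rejected(self, setup):
        cfg, ann, _ = setup
        with pytest.raises(KeyError):
            simulate_medip(cfg, [PlantedEffect("nosuch", dm_direction="hyper")], ann)


class TestExpression:
    def test_planted_fold_changes_realized(self):
        cfg = SimConfig(seed=7, n_genes=50, expr_noise_sd=0.1,
                        planted_expr_effect=1.0)
        effects = [PlantedEffect("g0000", expr_direction="up"),
                   PlantedEffect("g0001", expr_direction="down")]
        mat, groups = simulate_expression(cfg, effects)
        fc = np.exp2(mat[groups["LP"]].mean(axis=1) - mat[groups["CN"]].mean(axis=1))
        assert fc["g0000"] >= 1.8
        assert fc["g0001"] <= 1 / 1.8

    def test_persistence_controls_rebound_shift(self):
        cfg = SimConfig(seed=8, n_genes=10, expr_noise_sd=0.05)
        effects = [
            PlantedEffect("g0000", expr_direction="up", persistent=True),
            PlantedEffect("g0001", expr_direction="up", persistent=False),
        ]
        mat, groups = simulate_expression(cfg, effects)
        reb_fc = mat[groups["LP-R"]].mean(axis=1) - mat[groups["CN-R"]].mean(axis=1)
        assert reb_fc["g0000"] > 0.7  # shifted in the rebound comparison too
        assert abs(reb_fc["g0001"]) < 0.3  # restricted-phase effect only

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=9, n_genes=20)
        m1, _ = simulate_expression(cfg, [])
        m2, _ = simulate_expression(cfg, [])
        assert m1.equals(m2)


class TestTableFixtures:
    def test_synergy_fixture_shape(self):
        effects = build_table_fixture("table6")
        assert len(effects) == 27
        assert all(e.dm_direction != "none" for e in effects)
        down_hyper = [e for e in effects
                      if (e.expr_direction, e.dm_direction) == ("down", "hyper")]
        up_hypo = [e for e in effects
                   if (e.expr_direction, e.dm_direction) == ("up", "hypo")]
        assert (len(down_hyper), len(up_hypo)) == (13, 14)
        classes = table6_promoter_classes()
        assert classes["Aff4"] == "HCP" and classes["Tmem176b"] == "LCP"

    def test_persistent_fixture_shape(self):
        effects = build_table_fixture("table4")
        assert len(effects) == 17
        assert all(e.persistent for e in effects)
        by_gene = {e.gene_id: e for e in effects}
        assert by_gene["Cyr61"].expr_direction == "up"
        dirs = [e.expr_direction for e in effects]
        assert (dirs.count("up"), dirs.count("down")) == (6, 11)

    def test_unknown_table_rejected(self):
        with pytest.raises(ConfigError):
            build_table_fixture("table9")
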