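"""Normalization, sliding-window peak calling, M′, DEP filters, DMG calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from oracles import interval_union_oracle

from medipchip.medip import (
    DifferentialPeak,
    Peak,
    call_dmgs,
    compute_m_prime,
    filter_deps,
    find_differential_peaks,
    find_peaks,
    linear_smooth,
    median_center,
    merge_peaks,
    normalize,
    quantile_normalize,
)


def probe_track(values, chrom="chr1", spacing=100, length=50):
    n = len(values)
    starts = np.arange(n) * spacing
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + length,
         "value": np.asarray(values, dtype=float)}
    )


class TestNormalize:
    def test_median_centering(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert median_center(df)["a"].tolist() == [-1.0, 0.0, 1.0]

    def test_quantile_normalization_identity_on_identical_arrays(self):
        df = pd.DataFrame({"a": [0.3, -1.2, 2.0], "b": [0.3, -1.2, 2.0]})
        out = quantile_normalize(df)
        assert np.allclose(out, df)

    def test_quantile_normalization_equalizes_sorted_values(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(1, 2, 50)})
        out = quantile_normalize(df)
        assert np.allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_smoothing_averages_neighbors(self):
        df = pd.DataFrame({"v": [0.0, 3.0, 0.0, 0.0]})
        chroms = pd.Series(["c"] * 4)
        out = linear_smooth(df, chroms)
        assert out["v"].tolist() == [1.5, 1.0, 1.0, 0.0]

    def test_normalize_pipeline_shape_preserved(self, rng):
        df = probe_track(rng.normal(size=30)).drop(columns="value")
        df["probe_id"] = [f"p{i}" for i in range(30)]
        df["a1"] = rng.normal(size=30)
        df["a2"] = rng.normal(0.5, 1.5, 30)
        out = normalize(df, ["a1", "a2"])
        assert list(out.columns) == list(df.columns)
        assert not out[["a1", "a2"]].isna().to_numpy().any()
        # quantile step equalized the arrays before the final smoothing
        centered = median_center(df[["a1", "a2"]])
        qn = quantile_normalize(centered)
        assert np.allclose(np.sort(qn["a1"]), np.sort(qn["a2"]))


class TestFindPeaks:
    def test_null_track_has_no_peaks(self):
        assert find_peaks(probe_track(np.zeros(100))) == []

    def test_planted_block_yields_one_covering_peak(self):
        rng = np.random.default_rng(20240918)
        values = rng.normal(0, 0.2, 500)
        values[200:210] = 1.5
        peaks = find_peaks(probe_track(values))
        assert len(peaks) == 1
        assert peaks[0].probe_idx == list(range(200, 210))
        assert peaks[0].score >= 2

    def test_agrees_with_scipy_window_enumeration(self, rng):
        # independent oracle: score each centered window with scipy's
        # one-sided two-sample KS, then form runs the same way
        values = rng.normal(0, 0.2, 300)
        values[100:110] = 1.5
        df = probe_track(values)
        centers = (df["start"] + df["end"]) / 2.0
        above = []
        for i in range(len(df)):
            in_win = (centers >= centers[i] - 750) & (centers < centers[i] + 750)
            # alternative='less': in-window CDF below the background CDF,
            # i.e. in-window values stochastically larger
            res = stats.ks_2samp(
                values[in_win.to_numpy()], values[~in_win.to_numpy()],
                alternative="less", method="asymp",
            )
            above.append(-np.log10(max(res.pvalue, 1e-300)) >= 2)
        oracle_run = np.flatnonzero(above)
        peaks = find_peaks(df, boundary_frac=0.0)
        assert len(peaks) == 1
        assert peaks[0].probe_idx == oracle_run.tolist()

    def test_single_hot_probe_below_min_probes(self, rng):
        values = rng.normal(0, 0.2, 300)
        values[150] = 3.0
        # refinement trims the run to the lone hot probe, below min_probes
        assert find_peaks(probe_track(values)) == []

    def test_unsorted_probes_rejected(self):
        df = probe_track(np.zeros(10))
        df.loc[3, "start"] = 10_000
        with pytest.raises(ValueError):
            find_peaks(df)

    def test_wilcoxon_variant_finds_planted_block(self, rng):
        values = rng.normal(0, 0.2, 200)
        values[80:90] = 1.5
        peaks = find_peaks(probe_track(values), test="wilcoxon")
        assert len(peaks) == 1
        assert set(range(80, 90)) <= set(peaks[0].probe_idx)


class TestMergePeaks:
    def make(self, pairs):
        return [Peak("c", s, e, [i], float(i)) for i, (s, e) in enumerate(pairs)]

    def test_gap_below_spacing_merges(self):
        merged = merge_peaks(self.make([(0, 100), (500, 600)]), spacing=500)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 600)
        assert merged[0].probe_idx == [0, 1]

    def test_gap_at_or_above_spacing_kept_separate(self):
        assert len(merge_peaks(self.make([(0, 100), (700, 800)]), spacing=500)) == 2
        assert len(merge_peaks(self.make([(0, 100), (600, 700)]), spacing=500)) == 2

    def test_single_peak_unchanged(self):
        (p,) = merge_peaks(self.make([(10, 200)]), spacing=500)
        assert (p.start, p.end) == (10, 200)

    def test_merged_score_is_maximum(self):
        peaks = self.make([(0, 100), (200, 300)])
        peaks[0].score, peaks[1].score = 3.0, 7.0
        (m,) = merge_peaks(peaks, spacing=500)
        assert m.score == 7.0

    @given(
        st.lists(
            st.tuples(st.integers(0, 3000), st.integers(1, 400)),
            min_size=0, max_size=12,
        ),
        st.integers(1, 600),
    )
    def test_matches_interval_union_oracle(self, raw, spacing):
        intervals = sorted((s, s + ln) for s, ln in raw)
        merged = merge_peaks(self.make(intervals), spacing=spacing)
        assert [(p.start, p.end) for p in merged] == interval_union_oracle(
            intervals, spacing
        )


class TestMPrime:
    def test_printed_formula(self):
        e = np.array([[1.0, 1.2]])
        c = np.array([[0.2, 0.2]])
        assert compute_m_prime(e, c)[0] == pytest.approx(0.9)

    def test_zero_under_equal_groups_and_antisymmetric(self, rng):
        x = rng.normal(size=(20, 3))
        y = rng.normal(size=(20, 3))
        assert np.allclose(compute_m_prime(x, x), 0.0)
        assert np.allclose(compute_m_prime(x, y), -compute_m_prime(y, x))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_m_prime(np.empty((0, 2)), np.ones((3, 2)))


class TestDifferentialPeaks:
    def test_null_track_gives_no_deps(self):
        df = probe_track(np.zeros(100))
        assert find_differential_peaks(df, np.zeros(100)) == []

    def test_planted_blocks_give_directional_deps(self, rng):
        m = rng.normal(0, 0.15, 400)
        m[100:110] += 1.0
        m[300:310] -= 1.0
        deps = find_differential_peaks(probe_track(m), m)
        dirs = {d.direction for d in deps}
        assert dirs == {"hyper", "hypo"}
        hyper = next(d for d in deps if d.direction == "hyper")
        hypo = next(d for d in deps if d.direction == "hypo")
        assert set(range(100, 110)) <= set(hyper.probe_idx)
        assert set(range(300, 310)) <= set(hypo.probe_idx)
        assert hyper.peak_dm_value > 0.4 and hypo.peak_dm_value < -0.4

    def test_negated_track_mirrors_directions(self, rng):
        m = rng.normal(0, 0.15, 300)
        m[100:110] += 1.0
        df = probe_track(m)
        deps = find_differential_peaks(df, m)
        mirrored = find_differential_peaks(df, -m)
        key = lambda d: (d.start, d.end, tuple(d.probe_idx))
        assert sorted(key(d) for d in deps if d.direction == "hyper") == sorted(
            key(d) for d in mirrored if d.direction == "hypo"
        )


def make_dep(n_probes=6, direction="hyper", dm=0.6, score=3.0):
    return DifferentialPeak(
        chrom="chr1", start=0, end=n_probes * 100,
        probe_idx=list(range(n_probes)), score=score, direction=direction,
        m_prime_values=np.full(n_probes, dm), peak_dm_value=dm,
    )


class TestFilters:
    def test_enriched_low_cv_peak_passes(self):
        dep = make_dep(dm=0.6)
        e = np.full((6, 3), 0.5) + np.array([0.0, 0.01, -0.01]) * 1.0
        c = np.zeros((6, 3))
        (kept,) = filter_deps([dep], e, c)
        assert kept.passes_median_filter and kept.passes_cv_filter

    def test_unenriched_groups_fail_median_filter(self):
        dep = make_dep(dm=0.2)
        e = np.full((6, 3), 0.1)
        c = np.full((6, 3), 0.1)
        assert filter_deps([dep], e, c) == []
        assert dep.passes_median_filter is False

    def test_sign_discordant_median_m_fails(self):
        dep = make_dep(direction="hypo", dm=0.5)  # hypo but positive M′
        e = np.full((6, 3), 0.6)
        c = np.zeros((6, 3))
        assert filter_deps([dep], e, c) == []

    def test_noisy_probes_fail_cv_filter(self, rng):
        dep = make_dep(n_probes=4)
        e = np.full((4, 3), 0.5)
        # 3 of 4 probes wildly variable in the control group
        c = np.zeros((4, 3))
        c[:3, :] = [[-3.0, 4.0, 0.2]] * 3
        assert filter_deps([dep], e, c) == []
        assert dep.passes_cv_filter is False
        assert dep.passes_median_filter is True

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            filter_deps([make_dep()], np.empty((6, 0)), np.zeros((6, 1)))


class TestCallDmgs:
    promoters = pd.DataFrame(
        {"gene_id": ["g1"], "chrom": ["chr1"], "start": [1000], "end": [1900],
         "promoter_class": ["HCP"]}
    )

    def dep(self, start, end, dm=0.6, score=3.0, direction="hyper"):
        d = make_dep(direction=direction, dm=dm, score=score)
        d.start, d.end = start, end
        d.passes_median_filter = d.passes_cv_filter = True
        return d

    def test_overlapping_strong_dep_calls_gene(self):
        out = call_dmgs([self.dep(1500, 2500)], self.promoters)
        assert out["gene_id"].tolist() == ["g1"]
        assert out["direction"].tolist() == ["hyper"]
        assert out["promoter_class"].tolist() == ["HCP"]

    def test_intergenic_dep_calls_nothing(self):
        assert call_dmgs([self.dep(5000, 6000)], self.promoters).empty

    def test_small_dm_value_excluded(self):
        assert call_dmgs([self.dep(1500, 2500, dm=0.3)], self.promoters).empty

    def test_weak_p_excluded(self):
        assert call_dmgs([self.dep(1500, 2500, score=1.5)], self.promoters).empty

    def test_unretained_dep_excluded(self):
        d = self.dep(1500, 2500)
        d.passes_cv_filter = False
        assert call_dmgs([d], self.promoters).empty

    def test_empty_promoter_set_rejected(self):
        with pytest.raises(ValueError):
            call_dmgs([self.dep(0, 100)], self.promoters.iloc[:0])
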