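"""MeDIP-chip differential-enrichment core.

The chain mirrors the classic NimbleGen tiling-array workflow:

1. **normalize** — per-array median centering, cross-array quantile
   normalization (ties resolved to the mean of the pooled quantiles), and a
   3-probe centered moving average along each chromosome.
2. **find_peaks** — a 1500-bp sliding window anchored at every probe start;
   each window's values are compared against all out-of-window values with a
   one-sided two-sample Kolmogorov–Smirnov test (Wilcoxon rank-sum
   available as an alternative), and windows with ≥2 probes and
   −log10 p ≥ 2 are unioned into peaks.
3. **compute_m_prime** — the per-probe differential statistic
   ``M′ = mean(log2 MeDIP_E/Input_E) − mean(log2 MeDIP_C/Input_C)``.
4. **find_differential_peaks** — the peak finder rerun on the M′ track and
   its negation, giving hyper- and hypomethylated differential enrichment
   peaks (DEPs), merged within 500 bp.
5. **filter_deps** — a DEP survives iff (a) at least one group has an
   in-peak median log2(MeDIP/Input) ≥ 0.3 and the in-peak median M′ agrees
   in sign with the peak direction, and (b) at least half of its probes have
   a coefficient of variation ≤ 0.8 in both groups (CV taken on
   linear-scale ratios, where it is well defined).
6. **call_dmgs** — a gene is differentially methylated iff a retained DEP
   overlaps its promoter by ≥1 bp with peak p < 0.01 and |peak DM| > 0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import AlignmentError

LN10 = math.log(10.0)

DEFAULT_WINDOW = 1500
DEFAULT_MIN_PROBES = 2
DEFAULT_MIN_SCORE = 2.0
DEFAULT_MERGE_SPACING = 500
DEFAULT_MEDIAN_THRESHOLD = 0.3
DEFAULT_CV_THRESHOLD = 0.8
DEFAULT_DMG_P = 0.01
DEFAULT_DMG_MDIFF = 0.4


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    probe_idx: List[int]
    score: float  # −log10 p of the best member window


@dataclass
class DifferentialPeak:
    chrom: str
    start: int
    end: int
    probe_idx: List[int]
    score: float
    direction: str  # hyper | hypo
    m_prime_values: np.ndarray = field(default=None)
    peak_dm_value: float = float("nan")  # median in-peak M′, log2 scale
    passes_median_filter: Optional[bool] = None
    passes_cv_filter: Optional[bool] = None

    @property
    def retained(self) -> bool:
        return bool(self.passes_median_filter) and bool(self.passes_cv_filter)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def median_center(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each array's median log-ratio."""
    return values - values.median(axis=0)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every array onto the mean quantile profile.

    Ties within an array receive the mean of the pooled quantile values they
    span (rank method 'average', linear interpolation into the mean sorted
    profile).
    """
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(n, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def linear_smooth(values: pd.DataFrame, chroms: pd.Series, window: int = 3) -> pd.DataFrame:
    """Centered moving average along each chromosome (edges use the
    neighbors that exist).  Probes must already be coordinate-sorted."""
    out = values.copy()
    for _, idx in chroms.groupby(chroms, sort=False).groups.items():
        block = values.loc[idx]
        out.loc[idx] = (
            block.rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
    return out


def normalize(
    probe_df: pd.DataFrame,
    array_cols: Sequence[str],
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Median-center, quantile-normalize and smooth a probe table.

    ``probe_df`` carries probe metadata (probe_id, chrom, start, end) plus
    one column per array; all arrays must share the probe set (one table ⇒
    shared by construction, but NaNs mark mismatched designs).
    Returns a copy with the array columns replaced by normalized values.
    """
    if len(array_cols) < 1:
        raise ValueError("need at least one array column")
    vals = probe_df[list(array_cols)]
    if vals.isna().to_numpy().any():
        raise AlignmentError("probe sets differ across arrays (missing values)")
    vals = median_center(vals)
    if len(array_cols) > 1:
        vals = quantile_normalize(vals)
    vals = linear_smooth(vals, probe_df["chrom"], window=smooth_window)
    out = probe_df.copy()
    out[list(array_cols)] = vals
    return out


def combine_groups(tables: Dict[str, pd.DataFrame]) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Merge per-group probe tables on probe coordinates into one table.

    Raises :class:`AlignmentError` when the groups do not share a probe
    design.  Returns the merged table and a group → array-column map.
    """
    keys = ["probe_id", "chrom", "start", "end"]
    merged = None
    groups: Dict[str, List[str]] = {}
    for name, df in tables.items():
        cols = [c for c in df.columns if c not in keys]
        groups[name] = cols
        part = df[keys + cols]
        if merged is None:
            merged = part.copy()
        else:
            if len(part) != len(merged) or not (
                part[keys].reset_index(drop=True) == merged[keys].reset_index(drop=True)
            ).all().all():
                raise AlignmentError("probe sets differ between groups")
            merged = pd.concat([merged, part[cols].reset_index(drop=True)], axis=1)
    return merged, groups


# ---------------------------------------------------------------------------
# sliding-window peak finding
# ---------------------------------------------------------------------------

def _window_bounds(centers: np.ndarray, window: int) -> Tuple[np.ndarray, np.ndarray]:
    """Index range [lo, hi) of probes inside the window centered on each probe."""
    half = window / 2.0
    lo = np.searchsorted(centers, centers - half, side="left")
    hi = np.searchsorted(centers, centers + half, side="right")
    return lo, hi


def _ks_probe_scores(
    centers: np.ndarray,
    values: np.ndarray,
    all_sorted: np.ndarray,
    window: int,
) -> np.ndarray:
    """−log10 p per probe from the window centered on it (one chromosome).

    The one-sided two-sample KS statistic D⁺ = sup_x [F_out(x) − F_in(x)]
    measures how far the in-window values sit above the out-of-window
    background; the asymptotic upper-tail p-value uses Hodges'
    approximation ``exp(−2z² − 2z(m + 2n)/(3√(mn(m+n))))`` with
    ``z = √(mn/(m+n))·D⁺`` and m ≥ n — the same formula scipy's
    one-sided two-sample KS test applies.
    """
    n_total = all_sorted.size
    n = centers.size
    scores = np.zeros(n)
    lo_arr, hi_arr = _window_bounds(centers, window)
    for i in range(n):
        lo, hi = lo_arr[i], hi_arr[i]
        m_in = hi - lo
        m_out = n_total - m_in
        if m_out < 1:
            continue
        w = np.sort(values[lo:hi])
        c_all = np.searchsorted(all_sorted, w, side="left")
        j = np.arange(m_in)
        f_out = (c_all - j) / m_out
        d_plus = float(np.max(f_out - j / m_in))
        if d_plus <= 0:
            continue
        big, small = max(m_in, m_out), min(m_in, m_out)
        en = m_in * m_out / n_total
        z = math.sqrt(en) * d_plus
        expt = 2.0 * z * z + 2.0 * z * (big + 2 * small) / math.sqrt(
            m_in * m_out * n_total
        ) / 3.0
        scores[i] = expt / LN10
    return scores


def find_peaks(
    probe_df: pd.DataFrame,
    value_col: str = "value",
    window: int = DEFAULT_WINDOW,
    min_probes: int = DEFAULT_MIN_PROBES,
    min_score: float = DEFAULT_MIN_SCORE,
    test: str = "ks",
    boundary_frac: float = 0.5,
) -> List[Peak]:
    """Sliding-window enrichment peaks on a single-value probe track.

    Every probe is scored with the ``window``-bp window centered on it: the
    window's values are tested against all out-of-window values on the
    track (one-sided KS by default, Wilcoxon rank-sum as an option).
    Maximal runs of consecutive probes with −log10 p ≥ ``min_score``
    holding ≥ ``min_probes`` probes become peaks; the peak score is the
    best member score.  Probes must be sorted by (chrom, start).

    Because a centered window reaches ``window/2`` past the signal, a raw
    run extends several probes beyond the enriched region; each run is
    therefore refined to its core, dropping edge probes below
    ``boundary_frac`` × the summit value (half-maximum boundaries;
    ``boundary_frac=0`` disables refinement).
    """
    if test not in ("ks", "wilcoxon"):
        raise ValueError(f"unknown window test {test!r}")
    starts = probe_df["start"].to_numpy()
    ends = probe_df["end"].to_numpy()
    values = probe_df[value_col].to_numpy(dtype=float)
    for _, g in probe_df.groupby("chrom", sort=False):
        if not np.all(np.diff(g["start"].to_numpy()) >= 0):
            raise ValueError("probes must be sorted by start within chromosome")

    all_sorted = np.sort(values)
    n_total = values.size
    peaks: List[Peak] = []
    offset = 0
    for chrom, g in probe_df.groupby("chrom", sort=False):
        c_n = len(g)
        c_starts = starts[offset : offset + c_n]
        c_ends = ends[offset : offset + c_n]
        centers = (c_starts + c_ends) / 2.0
        c_values = values[offset : offset + c_n]
        if test == "ks":
            scores = _ks_probe_scores(centers, c_values, all_sorted, window)
        else:
            scores = np.zeros(c_n)
            lo_arr, hi_arr = _window_bounds(centers, window)
            for i in range(c_n):
                lo, hi = lo_arr[i], hi_arr[i]
                if n_total - (hi - lo) < 1:
                    continue
                out_mask = np.ones(n_total, dtype=bool)
                out_mask[offset + lo : offset + hi] = False
                p = stats.mannwhitneyu(
                    c_values[lo:hi], values[out_mask], alternative="greater"
                ).pvalue
                scores[i] = -math.log10(max(p, 1e-300))
        # maximal runs of consecutive above-cutoff probes
        above = scores >= min_score
        i = 0
        while i < c_n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < c_n and above[j + 1]:
                j += 1
            lo, hi = i, j
            if boundary_frac > 0:
                summit = float(c_values[lo : hi + 1].max())
                if summit > 0:
                    cut = boundary_frac * summit
                    while lo < hi and c_values[lo] < cut:
                        lo += 1
                    while hi > lo and c_values[hi] < cut:
                        hi -= 1
            if hi - lo + 1 >= min_probes:
                idx = list(range(offset + lo, offset + hi + 1))
                peaks.append(
                    Peak(chrom, int(c_starts[lo]), int(c_ends[hi]), idx,
                         float(scores[i : j + 1].max()))
                )
            i = j + 1
        offset += c_n
    return peaks


def merge_peaks(peaks: Sequence[Peak], spacing: int = DEFAULT_MERGE_SPACING) -> List[Peak]:
    """Union peaks on the same chromosome whose gap is < ``spacing`` bp.

    The merged score is the maximum of the member scores; probe lists are
    unioned.  Input order may be arbitrary; output is coordinate-sorted.
    """
    out: List[Peak] = []
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
        last = out[-1] if out else None
        if last is not None and p.chrom == last.chrom and p.start - last.end < spacing:
            last.end = max(last.end, p.end)
            last.score = max(last.score, p.score)
            last.probe_idx = sorted(set(last.probe_idx) | set(p.probe_idx))
        else:
            out.append(Peak(p.chrom, p.start, p.end, list(p.probe_idx), p.score))
    return out


# ---------------------------------------------------------------------------
# differential statistic and DEPs
# ---------------------------------------------------------------------------

def compute_m_prime(group_e, group_c) -> np.ndarray:
    """Per-probe ``M′ = mean(E arrays) − mean(C arrays)`` of log2 ratios.

    Accepts 2-D (probes × arrays) arrays/DataFrames, or 1-D per-probe
    vectors of group averages.
    """
    e = np.asarray(group_e, dtype=float)
    c = np.asarray(group_c, dtype=float)
    if e.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    e_mean = e.mean(axis=1) if e.ndim == 2 else e
    c_mean = c.mean(axis=1) if c.ndim == 2 else c
    return e_mean - c_mean


def find_differential_peaks(
    probe_df: pd.DataFrame,
    m_prime: np.ndarray,
    window: int = DEFAULT_WINDOW,
    min_probes: int = DEFAULT_MIN_PROBES,
    min_score: float = DEFAULT_MIN_SCORE,
    merge_spacing: int = DEFAULT_MERGE_SPACING,
    test: str = "ks",
) -> List[DifferentialPeak]:
    """Hyper- and hypomethylation DEPs from the per-probe M′ track.

    The peak finder runs on M′ (hyper) and on −M′ (hypo); each direction is
    merged separately within ``merge_spacing`` bp.  The peak DM value is the
    median of the in-peak M′ values (log2 scale).
    """
    m_prime = np.asarray(m_prime, dtype=float)
    track = probe_df[["chrom", "start", "end"]].copy()
    deps: List[DifferentialPeak] = []
    for direction, sign in (("hyper", 1.0), ("hypo", -1.0)):
        track["value"] = sign * m_prime
        raw = find_peaks(
            track, "value", window=window, min_probes=min_probes,
            min_score=min_score, test=test,
        )
        for p in merge_peaks(raw, spacing=merge_spacing):
            mvals = m_prime[p.probe_idx]
            deps.append(
                DifferentialPeak(
                    chrom=p.chrom, start=p.start, end=p.end,
                    probe_idx=list(p.probe_idx), score=p.score,
                    direction=direction, m_prime_values=mvals,
                    peak_dm_value=float(np.median(mvals)),
                )
            )
    deps.sort(key=lambda d: (d.chrom, d.start, d.end, d.direction))
    return deps


def _probe_cv(linear: np.ndarray) -> np.ndarray:
    """Per-probe coefficient of variation across arrays (linear scale)."""
    if linear.shape[1] < 2:
        # a single array shows no replicate variability
        return np.zeros(linear.shape[0])
    return linear.std(axis=1, ddof=1) / linear.mean(axis=1)


def filter_deps(
    deps: Sequence[DifferentialPeak],
    group_e: np.ndarray,
    group_c: np.ndarray,
    median_threshold: float = DEFAULT_MEDIAN_THRESHOLD,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> List[DifferentialPeak]:
    """Apply the median-enrichment and CV reproducibility filters in place.

    ``group_e`` / ``group_c`` are full (probes × arrays) matrices of
    normalized log2(MeDIP/Input), indexed consistently with the probe table
    the DEPs were called on.  Returns the retained DEPs; every DEP's flags
    are set either way.
    """
    group_e = np.atleast_2d(np.asarray(group_e, dtype=float))
    group_c = np.atleast_2d(np.asarray(group_c, dtype=float))
    if group_e.shape[1] < 1 or group_c.shape[1] < 1:
        raise ValueError("each group needs at least one array")
    retained: List[DifferentialPeak] = []
    for dep in deps:
        idx = np.asarray(dep.probe_idx, dtype=int)
        e_block = group_e[idx, :]
        c_block = group_c[idx, :]
        med_e = float(np.median(e_block))
        med_c = float(np.median(c_block))
        m_med = float(np.median(dep.m_prime_values))
        sign_ok = m_med > 0 if dep.direction == "hyper" else m_med < 0
        dep.passes_median_filter = (max(med_e, med_c) >= median_threshold) and sign_ok
        cv_e = _probe_cv(np.exp2(e_block))
        cv_c = _probe_cv(np.exp2(c_block))
        ok = (cv_e <= cv_threshold) & (cv_c <= cv_threshold)
        dep.passes_cv_filter = bool(ok.sum() * 2 >= idx.size)
        if dep.retained:
            retained.append(dep)
    return retained


# ---------------------------------------------------------------------------
# DMG calling
# ---------------------------------------------------------------------------

def call_dmgs(
    deps: Sequence[DifferentialPeak],
    promoters: pd.DataFrame,
    p_threshold: float = DEFAULT_DMG_P,
    m_diff: float = DEFAULT_DMG_MDIFF,
    require_retained: bool = True,
) -> pd.DataFrame:
    """Differentially methylated genes: promoters overlapped by strong DEPs.

    A gene is a DMG iff a (retained) DEP overlaps its promoter interval by
    ≥1 bp with peak p < ``p_threshold`` (score > −log10 p) and
    |peak DM value| > ``m_diff``.  When several DEPs hit one promoter the
    one with the largest |DM| wins.  ``promoters`` needs columns gene_id,
    chrom, start, end, promoter_class.
    """
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    min_score = -math.log10(p_threshold)
    trees: Dict[str, IntervalTree] = {}
    for row in promoters.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, (row.gene_id, row.promoter_class)
        )
    best: Dict[str, tuple] = {}
    for dep in deps:
        if require_retained and not dep.retained:
            continue
        if not (dep.score > min_score and abs(dep.peak_dm_value) > m_diff):
            continue
        tree = trees.get(dep.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(dep.start, dep.end):
            gene_id, cls = iv.data
            prev = best.get(gene_id)
            if prev is None or abs(dep.peak_dm_value) > abs(prev[2]):
                best[gene_id] = (dep.direction, cls, dep.peak_dm_value, dep.score)
    rows = [
        (g, d, cls, dm, score) for g, (d, cls, dm, score) in sorted(best.items())
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "direction", "promoter_class",
                       "peak_dm_value", "score"],
    )
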