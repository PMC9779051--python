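"""Independent brute-force oracles shared across the suite.

Each oracle recomputes a quantity from its definition with none of the
implementation's machinery: plain string scans for promoter classes,
explicit enumeration of label permutations for the rank-product pfp, and a
coverage array for peak merging.
"""

import itertools

import numpy as np
from scipy.stats import rankdata

from medipchip.rankprod import fold_change_vectors


def brute_force_class(seq: str, window: int = 500) -> str:
    """Enumerate every 500-bp window with plain string operations."""

    def win_gc(s):
        valid = sum(s.count(b) for b in "ACGT")
        return (s.count("G") + s.count("C")) / valid if valid else 0.0

    def win_oe(s):
        c, g = s.count("C"), s.count("G")
        if c == 0 or g == 0:
            return 0.0
        valid = sum(s.count(b) for b in "ACGT")
        return s.count("CG") * valid / (c * g)

    if len(seq) < window:
        windows = [seq]
    else:
        windows = [seq[i : i + window] for i in range(len(seq) - window + 1)]
        # majority-ambiguous windows are skipped; whole sequence if none left
        windows = [w for w in windows
                   if sum(w.count(b) for b in "ACGT") > window / 2] or [seq]
    if any(win_gc(w) >= 0.55 and win_oe(w) >= 0.6 for w in windows):
        return "HCP"
    if not any(win_oe(w) >= 0.4 for w in windows):
        return "LCP"
    return "ICP"


def pfp_oracle(mat, group_a, group_b, direction):
    """Exhaustive pfp by direct definition: enumerate every per-vector label
    permutation, recompute the rank product, and count null values at or
    below each observed one."""
    fc = fold_change_vectors(mat, group_a, group_b)
    sign = -1 if direction == "up" else 1
    ranks = np.column_stack(
        [rankdata(sign * fc[:, v]) for v in range(fc.shape[1])]
    )
    rp_obs = np.exp(np.mean(np.log(ranks), axis=1))
    g, nv = ranks.shape
    perms = list(itertools.permutations(range(g)))
    total = np.zeros(g)
    n_assign = 0
    for combo in itertools.product(perms, repeat=nv):
        perm_rp = np.exp(
            np.mean(
                np.log(np.column_stack([ranks[list(combo[v]), v]
                                        for v in range(nv)])),
                axis=1,
            )
        )
        n_assign += 1
        for i in range(g):
            total[i] += np.sum(perm_rp <= rp_obs[i])
    expected = total / n_assign
    return expected / rankdata(rp_obs)


def interval_union_oracle(intervals, spacing):
    """Coverage-array oracle for peak merging: paint [start, end+spacing)
    and read off connected components; gaps strictly below ``spacing``
    disappear, a gap of exactly ``spacing`` survives."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals) + spacing + 1
    cov = np.zeros(hi, dtype=bool)
    for s, e in intervals:
        cov[s : e + spacing] = True
    merged, start = [], None
    for i, c in enumerate(cov):
        if c and start is None:
            start = i
        elif not c and start is not None:
            merged.append((start, i - spacing))
            start = None
    return merged
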