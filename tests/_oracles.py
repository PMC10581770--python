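"""Independent, naively written recomputations used as test oracles.

Everything here is deliberately implemented with plain Python loops and
math, independent of the package's vectorized code paths.
"""

import math

import numpy as np


def log10_or(value, nondetect=0.0):
    if value < 0:
        raise ValueError("negative intensity")
    return math.log10(value) if value > 0 else nondetect


def background_flags(matrix_rows, blank_cols, sample_cols, multiplier=2.0, nondetect=0.0):
    """matrix_rows: dict feature_id -> dict sample_id -> intensity."""
    flagged = set()
    for fid, row in matrix_rows.items():
        logs = [log10_or(row[c], nondetect) for c in sample_cols]
        mean_log = sum(logs) / len(logs)
        blank_max = max(log10_or(row[c], nondetect) for c in blank_cols)
        if mean_log <= multiplier * blank_max:
            flagged.add(fid)
    return flagged


def background_subnetworks(flags, subnetwork_of, fraction=0.5):
    counts = {}
    for fid, sub in subnetwork_of.items():
        total, hit = counts.get(sub, (0, 0))
        counts[sub] = (total + 1, hit + (1 if fid in flags else 0))
    return {s for s, (total, hit) in counts.items() if hit / total > fraction}


def transient_flags(matrix_rows, sample_cols, max_samples=2, threshold=5e4):
    flagged = set()
    for fid, row in matrix_rows.items():
        present = sum(1 for c in sample_cols if row[c] > 0)
        peak = max(row[c] for c in sample_cols)
        if present <= max_samples and peak < threshold:
            flagged.add(fid)
    return flagged


def rare_subnetworks(matrix_rows, sample_cols, subnetwork_of):
    nonzero = [
        row[c] for row in matrix_rows.values() for c in sample_cols if row[c] > 0
    ]
    reference = sum(nonzero) / len(nonzero)
    sub_max = {}
    for fid, row in matrix_rows.items():
        sub = subnetwork_of[fid]
        peak = max(row[c] for c in sample_cols)
        sub_max[sub] = max(sub_max.get(sub, 0.0), peak)
    return {s for s, peak in sub_max.items() if peak < reference}


def filter_cascade(matrix_rows, blank_cols, sample_cols, subnetwork_of):
    """Full three-stage cascade; returns the surviving feature ids."""
    flags = background_flags(matrix_rows, blank_cols, sample_cols)
    bad_subs = background_subnetworks(flags, subnetwork_of)
    survivors = {
        fid: row
        for fid, row in matrix_rows.items()
        if fid not in flags and subnetwork_of[fid] not in bad_subs
    }
    t_flags = transient_flags(survivors, sample_cols)
    survivors = {fid: row for fid, row in survivors.items() if fid not in t_flags}
    r_subs = rare_subnetworks(survivors, sample_cols, subnetwork_of)
    return {fid for fid in survivors if subnetwork_of[fid] not in r_subs}


def subnetwork_sums(matrix_rows, sample_cols, subnetwork_of):
    sums = {}
    for fid, row in matrix_rows.items():
        sub = subnetwork_of[fid]
        acc = sums.setdefault(sub, {c: 0.0 for c in sample_cols})
        for c in sample_cols:
            acc[c] += row[c]
    return sums


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, by the textbook rule."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = pvalues[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def balanced_two_way_ss(cell_means, n_per_cell):
    """Closed-form sums of squares for a balanced two-way layout.

    ``cell_means[(a, b)]`` holds the (noise-free) cell mean; with zero
    within-cell noise the observed SS equal these exactly.
    """
    a_levels = sorted({a for a, _ in cell_means})
    b_levels = sorted({b for _, b in cell_means})
    grand = sum(cell_means.values()) / len(cell_means)
    a_means = {
        a: sum(cell_means[(a, b)] for b in b_levels) / len(b_levels) for a in a_levels
    }
    b_means = {
        b: sum(cell_means[(a, b)] for a in a_levels) / len(a_levels) for b in b_levels
    }
    ss_a = n_per_cell * len(b_levels) * sum((a_means[a] - grand) ** 2 for a in a_levels)
    ss_b = n_per_cell * len(a_levels) * sum((b_means[b] - grand) ** 2 for b in b_levels)
    ss_ab = n_per_cell * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    return ss_a, ss_b, ss_ab


def dunnett_mc_oracle(groups, control, t_observed, draws=1_000_000, seed=123):
    """Monte-Carlo max-t null for Dunnett one-sided p-values.

    Built directly from the definition: simulate Gaussian samples of the
    same group sizes under the null, recompute all t statistics, and take
    the max-t exceedance frequency.  Independent of the package's
    multivariate-t construction.
    """
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    n0 = len(control)
    k = len(groups)
    df = sum(sizes) + n0 - (k + 1)
    sim_control = rng.standard_normal((draws, n0))
    sims = [rng.standard_normal((draws, n)) for n in sizes]
    ss = ((sim_control - sim_control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    for g in sims:
        ss += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt(ss / df)
    ts = np.column_stack(
        [
            (g.mean(axis=1) - sim_control.mean(axis=1))
            / (s * math.sqrt(1 / n + 1 / n0))
            for g, n in zip(sims, sizes)
        ]
    )
    max_t = ts.max(axis=1)
    return [float((max_t >= t).mean()) for t in t_observed]
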