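"""Vectorised permutation engine shared by the ADA test and the comparators.

The key observation: under case/control label permutation the margins of
every per-site 2x2 allele-count table are fixed (case and control subject
counts do not change, and each site's total minor-allele count M_i is a
property of the data).  Every per-site quantity (mid-P, direction, weight)
is therefore a function of a_i alone, the site's minor-allele count in
cases, and can be precomputed into lookup tables indexed by a_i.  One
BLAS matrix product (permutation masks x dosage matrix) yields a_i for all
permutations at once, and everything downstream is table gathers and
reductions.

All methods run on one shared set of permutation masks per invocation, so
P-values across methods are paired (variance reduction in power contrasts).

Sites that are monomorphic in the analysed sample are dropped here: their
table is degenerate in every permutation (P = 1, tied, zero dosage), so
they contribute nothing to any statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import rankdata

from .data import CaseControlData
from .sites import _site_lookup

_EXACT_CAP = 500_000  # refuse exhaustive enumeration beyond this many splits


@dataclass
class Prep:
    """Per-dataset precomputation for the permutation engine."""

    G: np.ndarray          # (n, Ka) float32 dosages, polymorphic sites only
    y: np.ndarray          # (n,) int8 phenotype
    M: np.ndarray          # (Ka,) total minor alleles per active site
    maf: np.ndarray        # (Ka,) pooled-sample MAF per active site
    n_cases: int
    n_controls: int
    # lookup tables indexed [site, a]; a = case minor-allele count
    L_p: np.ndarray        # mid-P
    L_d: np.ndarray        # direction sign {-1, 0, +1}
    L_w: np.ndarray        # Madsen-Browning weight
    active_ids: tuple      # variant IDs of the active (polymorphic) sites
    n_total_sites: int     # before dropping monomorphic sites


def prepare(data: CaseControlData) -> Prep:
    n_cases = data.n_cases
    n_controls = data.n_controls
    M_all = data.genotypes.sum(axis=0).astype(np.int64)
    active = M_all > 0
    G = np.ascontiguousarray(data.genotypes[:, active], dtype=np.float32)
    M = M_all[active]
    amax = int(min(M.max(initial=0), 2 * n_cases))
    Ka = G.shape[1]
    L_p = np.ones((Ka, amax + 1))
    L_d = np.zeros((Ka, amax + 1), dtype=np.int8)
    L_w = np.ones((Ka, amax + 1))
    for i, Mi in enumerate(M.tolist()):
        pm, dirs, w = _site_lookup(int(Mi), n_cases, n_controls)
        k = min(len(pm), amax + 1)
        L_p[i, :k], L_d[i, :k], L_w[i, :k] = pm[:k], dirs[:k], w[:k]
    return Prep(
        G=G,
        y=np.asarray(data.phenotype, dtype=np.int8),
        M=M,
        maf=M / (2 * data.n_subjects),
        n_cases=n_cases,
        n_controls=n_controls,
        L_p=L_p,
        L_d=L_d,
        L_w=L_w,
        active_ids=tuple(v for v, k in zip(data.variant_ids, active) if k),
        n_total_sites=data.n_variants,
    )


def permutation_masks(n: int, n_cases: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """(B, n) float32 indicator matrix of random case sets of size n_cases."""
    u = rng.random((B, n))
    idx = np.argpartition(u, n_cases - 1, axis=1)[:, :n_cases]
    masks = np.zeros((B, n), dtype=np.float32)
    np.put_along_axis(masks, idx, 1.0, axis=1)
    return masks


def exhaustive_masks(n: int, n_cases: int) -> np.ndarray:
    """All C(n, n_cases) case/control label assignments (small n only)."""
    N = comb(n, n_cases)
    if N > _EXACT_CAP:
        raise ValueError(f"exhaustive enumeration over {N} label splits is infeasible")
    masks = np.zeros((N, n), dtype=np.float32)
    for r, combo in enumerate(itertools.combinations(range(n), n_cases)):
        masks[r, list(combo)] = 1.0
    return masks


def case_counts(prep: Prep, masks: np.ndarray) -> np.ndarray:
    """(B, Ka) integer minor-allele counts in cases for each permutation."""
    A = masks @ prep.G  # exact: counts < 2^24 representable in float32
    return A.astype(np.int64)


# ---------------------------------------------------------------------------
# ADA scores and the two-layer min-P adjustment


def ada_scores(prep: Prep, A: np.ndarray, thresholds: np.ndarray):
    """Direction-stratified truncated score vectors for each permutation row.

    Returns (S_D, S_P) of shape (B, J): S_D[b, j] is the weighted sum of
    -ln(p_i) over deleterious-inclined sites with p_i < thresholds[j] under
    the b-th labelling; S_P analogously for protective-inclined sites.
    """
    B, Ka = A.shape
    J = len(thresholds)
    if Ka == 0:
        z = np.zeros((B, J))
        return z, z.copy()
    rows = np.arange(Ka)
    pv = prep.L_p[rows, A]
    dirs = prep.L_d[rows, A]
    contrib = prep.L_w[rows, A] * (-np.log(pv))
    # bucket = first threshold index j with p < theta_j (strict inequality)
    bucket = np.searchsorted(thresholds, pv.ravel(), side="right").reshape(B, Ka)
    offsets = (np.arange(B)[:, None] * (J + 1) + bucket).ravel()
    cd = np.where(dirs > 0, contrib, 0.0).ravel()
    cp = np.where(dirs < 0, contrib, 0.0).ravel()
    S_D = np.bincount(offsets, weights=cd, minlength=B * (J + 1)).reshape(B, J + 1)
    S_P = np.bincount(offsets, weights=cp, minlength=B * (J + 1)).reshape(B, J + 1)
    return S_D.cumsum(axis=1)[:, :J], S_P.cumsum(axis=1)[:, :J]


def combine_scores(S_D: np.ndarray, S_P: np.ndarray, mode: str) -> np.ndarray:
    if S_D.shape != S_P.shape:
        raise ValueError("score vectors must have equal shape")
    if mode == "max":
        return np.maximum(S_D, S_P)
    if mode == "sum":
        return S_D + S_P
    raise ValueError(f"unknown statistic mode {mode!r}")


def minp_adjust(S_obs: np.ndarray, S_perm: np.ndarray, estimator: str = "plus_one"):
    """Min-P adjustment of the per-threshold scores over one threshold grid.

    ``plus_one`` (Monte-Carlo permutations): the observed per-threshold
    P-value is (1 + #{b : S_b >= S_obs})/(B + 1); each permutation's own
    per-threshold P-value is its >=-rank among the B permuted statistics
    divided by B (the observed statistic is left out of that reference
    set).  ``exact`` (exhaustive enumeration): every assignment, observed
    labelling included, is ranked against the full set of N assignments
    with denominator N.

    Returns (per_threshold_p, min_p_observed, adjusted_p, argmin_j).
    """
    B, J = S_perm.shape
    p_obs = np.empty(J)
    p_perm = np.empty((B, J))
    for j in range(J):
        col = S_perm[:, j]
        order = np.sort(col)
        ge_obs = B - np.searchsorted(order, S_obs[j], side="left")
        ge_perm = B - np.searchsorted(order, col, side="left")
        if estimator == "plus_one":
            p_obs[j] = (1 + ge_obs) / (B + 1)
            p_perm[:, j] = ge_perm / B
        elif estimator == "exact":
            # reference set = all assignments; S_obs equals one of the rows
            p_obs[j] = ge_obs / B
            p_perm[:, j] = ge_perm / B
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    minp_obs = float(p_obs.min())
    minp_perm = p_perm.min(axis=1)
    if estimator == "plus_one":
        adjusted = (1 + int((minp_perm <= minp_obs).sum())) / (B + 1)
    else:
        adjusted = int((minp_perm <= minp_obs).sum()) / B
    return p_obs, minp_obs, float(adjusted), int(p_obs.argmin())


# ---------------------------------------------------------------------------
# Comparator statistics (all evaluated on the same masks)


def sigma_midp_stats(prep: Prep, A: np.ndarray) -> np.ndarray:
    """Weighted Fisher combination sum(w_i * -2 ln p_i) over non-tied sites."""
    if A.shape[1] == 0:
        return np.zeros(A.shape[0])
    rows = np.arange(A.shape[1])
    pv = prep.L_p[rows, A]
    dirs = prep.L_d[rows, A]
    contrib = prep.L_w[rows, A] * (-2.0 * np.log(pv))
    return np.where(dirs != 0, contrib, 0.0).sum(axis=1)


def fixed_threshold_stats(prep: Prep, masks: np.ndarray, maf_cut: float) -> np.ndarray:
    """|difference in mean rare-allele count| between cases and controls.

    Qualifying variants have pooled-sample MAF strictly below ``maf_cut``.
    """
    qual = prep.maf < maf_cut
    if not qual.any():
        return np.zeros(masks.shape[0])
    s = prep.G[:, qual].sum(axis=1)
    cs = masks @ s
    total = s.sum()
    diff = cs / prep.n_cases - (total - cs) / prep.n_controls
    return np.abs(diff)


def weighted_sum_stats(prep: Prep, A: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Madsen-Browning rank-sum statistic, two-tailed, weights recomputed
    from each permutation's own controls.

    Each subject's genetic score is sum_i g_i / sqrt(n * qhat_i (1-qhat_i))
    with qhat_i the smoothed control frequency under that labelling; the
    statistic is |sum of case score ranks - its null expectation|.
    """
    B, Ka = A.shape
    n = prep.G.shape[0]
    if Ka == 0:
        return np.zeros(B)
    c = prep.M[None, :] - A  # control minor-allele counts per permutation
    q = (c + 1) / (2 * prep.n_controls + 2)
    w = 1.0 / np.sqrt(prep.n_controls * q * (1.0 - q))
    scores = prep.G @ w.astype(np.float32).T  # (n, B)
    ranks = rankdata(scores, axis=0, method="average")
    ranksum = np.einsum("bi,ib->b", masks.astype(np.float64), ranks)
    return np.abs(ranksum - prep.n_cases * (n + 1) / 2.0)


def _vt_design(prep: Prep):
    """Cumulative per-subject counts at each candidate MAF threshold.

    Candidate thresholds are the distinct observed pooled MAFs; the score
    at threshold t counts minor alleles over variants with MAF <= t.
    Returns (CS (n, T) float32, denom (T,)) where denom is the root of the
    summed squared scores (the Price et al. standardisation; it does not
    depend on the labels, so it is permutation-invariant).
    """
    order = np.argsort(prep.maf, kind="stable")
    maf_sorted = prep.maf[order]
    cum = np.cumsum(prep.G[:, order], axis=1, dtype=np.float32)
    # last column index belonging to each distinct threshold value
    last = np.nonzero(np.r_[maf_sorted[1:] != maf_sorted[:-1], True])[0]
    CS = cum[:, last]
    denom = np.sqrt((CS.astype(np.float64) ** 2).sum(axis=0))
    return CS, denom


def variable_threshold_stats(prep: Prep, masks: np.ndarray) -> np.ndarray:
    """max over MAF thresholds of |z(t)|, z(t) = sum_i (phi_i - phibar) C_i(t)
    / sqrt(sum_i C_i(t)^2)."""
    if prep.G.shape[1] == 0:
        return np.zeros(masks.shape[0])
    CS, denom = _vt_design(prep)
    n = prep.G.shape[0]
    phibar = prep.n_cases / n
    case_sum = masks @ CS
    tot = CS.sum(axis=0)
    z = (case_sum - phibar * tot) / denom
    return np.abs(z).max(axis=1)


def vt_chosen_threshold(prep: Prep) -> float:
    """The MAF threshold maximising |z| on the observed labels."""
    CS, denom = _vt_design(prep)
    mask = prep.y.astype(np.float32)[None, :]
    z = np.abs(variable_threshold_z(prep, mask))
    order = np.sort(np.unique(prep.maf))
    return float(order[int(z.argmax())])


def variable_threshold_z(prep: Prep, masks: np.ndarray) -> np.ndarray:
    CS, denom = _vt_design(prep)
    phibar = prep.n_cases / prep.G.shape[0]
    return ((masks @ CS) - phibar * CS.sum(axis=0)) / denom


def plus_one_pvalue(stat_obs: float, stat_perm: np.ndarray) -> float:
    """(1 + #{b : T_b >= T_obs}) / (B + 1); ties counted against the observed."""
    B = len(stat_perm)
    return (1 + int((stat_perm >= stat_obs).sum())) / (B + 1)
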