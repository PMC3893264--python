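"""Per-variant association evidence.

Each variant is summarised by an allele-count 2x2 table (minor/major allele
by case/control chromosome), from which three quantities are derived:

* a two-sided mid-P value from Fisher's exact test,
* a direction indicator (minor allele commoner in cases, in controls, or tied),
* a Madsen-Browning weight estimated from the controls,
  w = 1 / sqrt(n * qhat * (1 - qhat)) with qhat = (m + 1) / (2n + 2),
  where m is the number of minor alleles among the n control subjects.

Tables are at the allele (chromosome) level, not the carrier level: the
weight formula counts mutant alleles, and the test table follows the same
convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .data import CaseControlData, InputError

__all__ = ["Direction", "SiteResult", "midp_fisher", "direction", "mb_weight", "site_scan"]

# Relative tolerance for declaring two hypergeometric point probabilities
# equal when classifying "as extreme" tables; guards against float noise
# misclassifying genuinely equiprobable tables.
_EQ_RTOL = 1e-12


class Direction(enum.Enum):
    DELETERIOUS_INCLINED = "deleterious_inclined"
    PROTECTIVE_INCLINED = "protective_inclined"
    TIED = "tied"


@dataclass(frozen=True)
class SiteResult:
    """Mid-P value, direction and weight for one variant site."""

    variant_id: str
    p_mid: float
    direction: Direction
    weight: float
    case_count: int      # minor alleles among case chromosomes
    control_count: int   # minor alleles among control chromosomes


def _check_table(a, b, c, d):
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise InputError("table entries must be non-negative integers")
    if a + b <= 0 or c + d <= 0:
        raise InputError("case and control margins must be positive")


def midp_fisher(a: int, b: int, c: int, d: int) -> float:
    """Two-sided mid-P Fisher exact test of the 2x2 table [[a, b], [c, d]].

    Rows are case/control chromosomes, columns minor/major allele counts.
    The two-sided criterion is the point-probability rule: sum the
    probabilities of all tables strictly less probable than the observed
    one, plus half the probability of tables exactly as probable
    (the observed table included).  A monomorphic site (a + c = 0 or
    b + d = 0) has a single attainable table and is assigned P = 1: it
    carries no evidence.  The result is clipped to (0, 1].
    """
    _check_table(a, b, c, d)
    M, amax = a + c, a + b
    N = a + b + c + d
    if M == 0 or M == N:
        return 1.0
    support = np.arange(max(0, M - (c + d)), min(M, amax) + 1)
    pmf = hypergeom.pmf(support, N, M, amax)
    p_obs = pmf[support == a][0]
    less = pmf < p_obs * (1.0 - _EQ_RTOL)
    equal = np.abs(pmf - p_obs) <= _EQ_RTOL * p_obs
    p = pmf[less].sum() + 0.5 * pmf[equal].sum()
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def direction(a: int, b: int, c: int, d: int) -> Direction:
    """Compare minor-allele frequency in cases (a/(a+b)) vs controls (c/(c+d)).

    Uses exact integer cross-multiplication, so ties are exact.
    """
    _check_table(a, b, c, d)
    lhs, rhs = a * (c + d), c * (a + b)
    if lhs > rhs:
        return Direction.DELETERIOUS_INCLINED
    if lhs < rhs:
        return Direction.PROTECTIVE_INCLINED
    return Direction.TIED


def mb_weight(m: int, n: int) -> float:
    """Madsen-Browning weight from m minor alleles among n control subjects.

    qhat = (m + 1)/(2n + 2) is the smoothed control minor-allele frequency;
    the weight 1/sqrt(n * qhat * (1 - qhat)) up-weights variants rare in
    controls.  The +1 smoothing keeps qhat in (0, 1), so the weight is
    always finite and positive.
    """
    if n < 1:
        raise InputError("need at least one control subject")
    if not 0 <= m <= 2 * n:
        raise InputError("control minor-allele count must be in [0, 2n]")
    q = (m + 1) / (2 * n + 2)
    return float(1.0 / np.sqrt(n * q * (1.0 - q)))


@lru_cache(maxsize=4096)
def _site_lookup(M: int, n_cases: int, n_controls: int):
    """Lookup tables over a = case minor-allele count for fixed margins.

    For a site with M total minor alleles among 2*n_cases case chromosomes
    and 2*n_controls control chromosomes, returns read-only arrays indexed
    by a in [0, min(M, 2*n_cases)]:

    ``pm``      two-sided mid-P values,
    ``dir``     +1 deleterious-inclined / -1 protective-inclined / 0 tied,
    ``weight``  Madsen-Browning weight from the implied control count M - a.

    Under label permutation the margins and M are invariant, so every
    permuted statistic is a gather into these tables; this is what makes
    the permutation engine cheap.
    """
    ncc, nuc = 2 * n_cases, 2 * n_controls
    N = ncc + nuc
    lo, hi = max(0, M - nuc), min(M, ncc)
    support = np.arange(lo, hi + 1)
    size = hi + 1  # index directly by a; entries below lo never occur
    pm = np.ones(size)
    dirs = np.zeros(size, dtype=np.int8)
    weights = np.empty(size)
    if 0 < M < N:
        pmf = hypergeom.pmf(support, N, M, ncc)
        # all-pairs comparison on the (small) support: support size <= 2n+1
        less = pmf[None, :] < pmf[:, None] * (1.0 - _EQ_RTOL)
        equal = np.abs(pmf[None, :] - pmf[:, None]) <= _EQ_RTOL * pmf[:, None]
        mid = (np.where(less, pmf[None, :], 0.0).sum(axis=1)
               + 0.5 * np.where(equal, pmf[None, :], 0.0).sum(axis=1))
        pm[lo:] = np.clip(mid, np.finfo(float).tiny, 1.0)
        dirs[lo:] = np.sign(support * nuc - (M - support) * ncc).astype(np.int8)
    weights[:] = 1.0
    a_valid = np.arange(lo, size)  # entries below lo are never gathered
    q = (M - a_valid + 1) / (2 * n_controls + 2)
    weights[lo:] = 1.0 / np.sqrt(n_controls * q * (1.0 - q))
    for arr in (pm, dirs, weights):
        arr.setflags(write=False)
    return pm, dirs, weights


def site_scan(data: CaseControlData) -> list[SiteResult]:
    """One :class:`SiteResult` per variant, in input order.

    Expects MAF-filtered (minor-polarised) data.  Deterministic; permuting
    the variant columns permutes the results identically.
    """
    case = data.phenotype == 1
    n_cases, n_controls = data.n_cases, data.n_controls
    a_vec = data.genotypes[case].sum(axis=0)
    m_vec = data.genotypes[~case].sum(axis=0)
    out = []
    for vid, a, m in zip(data.variant_ids, a_vec.tolist(), m_vec.tolist()):
        pm, dirs, weights = _site_lookup(int(a + m), n_cases, n_controls)
        out.append(
            SiteResult(
                variant_id=vid,
                p_mid=float(pm[a]),
                direction={1: Direction.DELETERIOUS_INCLINED,
                           -1: Direction.PROTECTIVE_INCLINED,
                           0: Direction.TIED}[int(dirs[a])],
                weight=float(weights[a]),
                case_count=int(a),
                control_count=int(m),
            )
        )
    return out


def site_results_frame(results: list[SiteResult]):
    """Per-site results as a DataFrame (for TSV export)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "case_count": [r.case_count for r in results],
            "control_count": [r.control_count for r in results],
            "p_mid": [r.p_mid for r in results],
            "direction": [r.direction.value for r in results],
            "weight": [r.weight for r in results],
        }
    )
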