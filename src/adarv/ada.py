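"""The ADA test: adaptive combination of per-site P-values.

For a region of K rare variants, per-site mid-P values p_i, direction
indicators and Madsen-Browning weights w_i (see :mod:`adarv.sites`) are
combined into direction-stratified, threshold-truncated scores over a grid
of J candidate truncation thresholds theta_1 < ... < theta_J:

    S^D_j = sum_i 1{site i deleterious-inclined} 1{p_i < theta_j} w_i (-ln p_i)
    S^P_j = sum_i 1{site i protective-inclined}  1{p_i < theta_j} w_i (-ln p_i)

The region statistic at threshold j is S_j = max(S^D_j, S^P_j) (an optional
sum mode S^D_j + S^P_j is provided, but max is recommended: regions usually
harbour more deleterious than protective variation, and max is more
powerful in that regime).  Tied sites (equal case/control minor-allele
frequency) contribute to neither score.

Significance uses a two-layer permutation scheme.  Case/control labels are
shuffled B times; mid-P values, directions and weights are recomputed under
each relabelling, giving permuted scores S_j^(b).  Per-threshold P-values
are converted to a single adjusted P-value by ranking the observed minimum
P-value across thresholds against each permutation's own minimum — the
permutations are allowed their own "optimal" threshold, which is what makes
the adaptive threshold search valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .data import CaseControlData, EmptyRegionError, InputError
from .sites import Direction, SiteResult

__all__ = [
    "DEFAULT_THRESHOLDS",
    "WIDE_THRESHOLDS",
    "AdaConfig",
    "AdaResult",
    "significance_scores",
    "ada_statistic",
    "ada_test",
]

#: Recommended grid: J = 11 thresholds 0.10, 0.11, ..., 0.20.
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.10, 0.201, 0.01), 2))
#: Wider alternative grid: 21 thresholds 0.05, 0.06, ..., 0.25.
WIDE_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.251, 0.01), 2))


@dataclass(frozen=True)
class AdaConfig:
    """Configuration of the ADA test.

    Parameters
    ----------
    thresholds : strictly increasing candidate truncation thresholds in (0, 1)
    n_permutations : number B of label permutations (P-value resolution is
        1/(B+1), so B must be large enough for the significance level of
        interest; a warning is the caller's concern, not an error)
    seed : seed of the permutation random stream
    statistic_mode : "max" (recommended) or "sum"
    """

    thresholds: tuple = field(default=DEFAULT_THRESHOLDS)
    n_permutations: int = 1000
    seed: int = 0
    statistic_mode: str = "max"

    def __post_init__(self):
        th = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", th)
        if len(th) < 1 or any(not 0 < t < 1 for t in th):
            raise InputError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise InputError("thresholds must be strictly increasing")
        if self.n_permutations < 1:
            raise InputError("need at least one permutation")
        if self.statistic_mode not in ("max", "sum"):
            raise InputError("statistic_mode must be 'max' or 'sum'")


@dataclass(frozen=True)
class AdaResult:
    """Observed scores, per-threshold P-values and the adjusted P-value."""

    thresholds: tuple
    S_D: np.ndarray
    S_P: np.ndarray
    S: np.ndarray
    per_threshold_p: np.ndarray
    min_p_observed: float
    adjusted_p: float
    chosen_threshold: float
    n_permutations: int
    statistic_mode: str


def _sites_to_arrays(sites):
    p = np.array([s.p_mid for s in sites])
    w = np.array([s.weight for s in sites])
    d = np.array(
        [
            1 if s.direction is Direction.DELETERIOUS_INCLINED
            else -1 if s.direction is Direction.PROTECTIVE_INCLINED
            else 0
            for s in sites
        ]
    )
    return p, w, d


def significance_scores(sites: list[SiteResult], thresholds) -> tuple[np.ndarray, np.ndarray]:
    """Compute (S^D, S^P) over the threshold grid from per-site results.

    A site contributes w_i * (-ln p_i) to S^D_j (S^P_j) when it is
    deleterious-inclined (protective-inclined) and p_i is strictly below
    theta_j; tied sites contribute to neither.
    """
    if not sites:
        raise InputError("need at least one site")
    th = np.asarray(thresholds, dtype=float)
    p, w, d = _sites_to_arrays(sites)
    contrib = w * (-np.log(p))
    below = p[:, None] < th[None, :]
    S_D = np.where((d == 1)[:, None] & below, contrib[:, None], 0.0).sum(axis=0)
    S_P = np.where((d == -1)[:, None] & below, contrib[:, None], 0.0).sum(axis=0)
    return S_D, S_P


def ada_statistic(S_D, S_P, mode: str = "max") -> np.ndarray:
    """Combine the direction-stratified scores: elementwise max (default) or sum."""
    S_D, S_P = np.asarray(S_D, dtype=float), np.asarray(S_P, dtype=float)
    if S_D.shape != S_P.shape:
        raise InputError("S_D and S_P must have equal length")
    return _engine.combine_scores(S_D, S_P, mode)


def ada_test(
    data: CaseControlData,
    config: AdaConfig | None = None,
    *,
    exhaustive: bool = False,
) -> AdaResult:
    """Run the full ADA test on MAF-filtered case-control data.

    With ``exhaustive=True`` all C(n, n_cases) label assignments are
    enumerated instead of Monte-Carlo sampling (tiny samples only); the
    adjusted P-value is then exact over the permutation distribution.
    Deterministic given ``config.seed``.
    """
    config = config or AdaConfig()
    thresholds = np.asarray(config.thresholds)
    prep = _engine.prepare(data)
    n = data.n_subjects

    a_obs = _engine.case_counts(prep, prep.y.astype(np.float32)[None, :])
    SD_obs, SP_obs = _engine.ada_scores(prep, a_obs, thresholds)
    S_obs = _engine.combine_scores(SD_obs, SP_obs, config.statistic_mode)[0]

    if exhaustive:
        masks = _engine.exhaustive_masks(n, data.n_cases)
        estimator = "exact"
        B = masks.shape[0]
    else:
        rng = np.random.default_rng(config.seed)
        masks = _engine.permutation_masks(n, data.n_cases, config.n_permutations, rng)
        estimator = "plus_one"
        B = config.n_permutations

    A = _engine.case_counts(prep, masks)
    SD_perm, SP_perm = _engine.ada_scores(prep, A, thresholds)
    S_perm = _engine.combine_scores(SD_perm, SP_perm, config.statistic_mode)
    p_obs, minp_obs, adjusted, jmin = _engine.minp_adjust(S_obs, S_perm, estimator)

    return AdaResult(
        thresholds=config.thresholds,
        S_D=SD_obs[0],
        S_P=SP_obs[0],
        S=S_obs,
        per_threshold_p=p_obs,
        min_p_observed=minp_obs,
        adjusted_p=adjusted,
        chosen_threshold=float(thresholds[jmin]),
        n_permutations=B,
        statistic_mode=config.statistic_mode,
    )
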