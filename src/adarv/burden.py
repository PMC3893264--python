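"""Comparator region tests run under the shared permutation framework.

Five tests, all two-tailed, all assessed by case/control label permutation
with the add-one estimator (1 + #{T_b >= T_obs}) / (B + 1):

* ``sigma_midp`` — weighted Fisher combination sum_i w_i (-2 ln p_i^mid)
  over sites with unequal case/control minor-allele counts (the
  non-adaptive ancestor of the ADA statistic).
* ``t1`` / ``t5`` — fixed-threshold burden tests: each subject's genetic
  score is the total minor-allele count over variants with pooled MAF
  below 1% / 5%; the statistic is |mean case score - mean control score|.
* ``ws`` — the Madsen-Browning weighted-sum rank test: dosages inversely
  weighted by the binomial SD of the control-estimated frequency, subjects
  ranked by weighted score, statistic = |case rank sum - null expectation|;
  the weights are recomputed from each permutation's own controls.
* ``vt`` — the variable-threshold test: over every candidate MAF threshold
  t (the distinct observed pooled MAFs) compute
  z(t) = sum_i (phi_i - phibar) C_i(t) / sqrt(sum_i C_i(t)^2),
  where C_i(t) is subject i's minor-allele count over variants with
  MAF <= t; the statistic is max_t |z(t)| (centred counts in the
  numerator, root of the summed squared scores in the denominator, after
  Price et al.'s standardisation).

:func:`compare_methods` evaluates any subset of these (plus ADA) on one
shared set of permutation masks, so the resulting P-values are paired.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import _engine
from .ada import AdaConfig, ada_test
from .data import CaseControlData, InputError

__all__ = [
    "Method",
    "BurdenResult",
    "sigma_midp_test",
    "fixed_threshold_test",
    "weighted_sum_test",
    "variable_threshold_test",
    "compare_methods",
]


class Method(enum.Enum):
    SIGMA_MIDP = "sigma_midp"
    T1 = "t1"
    T5 = "t5"
    WS = "ws"
    VT = "vt"


@dataclass(frozen=True)
class BurdenResult:
    statistic: float
    p_value: float
    method: Method


def _perm_setup(data: CaseControlData, B: int, seed: int):
    prep = _engine.prepare(data)
    rng = np.random.default_rng(seed)
    masks = _engine.permutation_masks(data.n_subjects, data.n_cases, B, rng)
    obs_mask = prep.y.astype(np.float32)[None, :]
    return prep, masks, obs_mask


def _stat_fn(method: Method, prep, maf_cut=None):
    if method is Method.SIGMA_MIDP:
        return lambda masks: _engine.sigma_midp_stats(prep, _engine.case_counts(prep, masks))
    if method in (Method.T1, Method.T5):
        cut = maf_cut if maf_cut is not None else (0.01 if method is Method.T1 else 0.05)
        return lambda masks: _engine.fixed_threshold_stats(prep, masks, cut)
    if method is Method.WS:
        return lambda masks: _engine.weighted_sum_stats(
            prep, _engine.case_counts(prep, masks), masks
        )
    if method is Method.VT:
        return lambda masks: _engine.variable_threshold_stats(prep, masks)
    raise InputError(f"unknown method {method}")


def _run(method: Method, data, B, seed, maf_cut=None) -> BurdenResult:
    if B < 1:
        raise InputError("need at least one permutation")
    prep, masks, obs_mask = _perm_setup(data, B, seed)
    fn = _stat_fn(method, prep, maf_cut)
    t_obs = float(fn(obs_mask)[0])
    p = _engine.plus_one_pvalue(t_obs, fn(masks))
    return BurdenResult(statistic=t_obs, p_value=p, method=method)


def sigma_midp_test(data: CaseControlData, B: int = 1000, seed: int = 0) -> BurdenResult:
    """Weighted Fisher combination of per-site mid-P values (tied sites excluded)."""
    return _run(Method.SIGMA_MIDP, data, B, seed)


def fixed_threshold_test(
    data: CaseControlData, maf_cut: float, B: int = 1000, seed: int = 0
) -> BurdenResult:
    """Fixed-threshold burden test; ``maf_cut`` 0.01 for T1, 0.05 for T5."""
    if not 0 < maf_cut <= 0.5:
        raise InputError("maf_cut must be in (0, 0.5]")
    method = Method.T1 if maf_cut <= 0.01 else Method.T5
    return _run(method, data, B, seed, maf_cut=maf_cut)


def weighted_sum_test(data: CaseControlData, B: int = 1000, seed: int = 0) -> BurdenResult:
    """Madsen-Browning weighted-sum rank test, two-tailed."""
    return _run(Method.WS, data, B, seed)


def variable_threshold_test(data: CaseControlData, B: int = 1000, seed: int = 0) -> BurdenResult:
    """Price et al. variable-threshold test, two-tailed."""
    return _run(Method.VT, data, B, seed)


def compare_methods(
    data: CaseControlData,
    methods=("ada", "sigma_midp", "t1", "t5", "ws", "vt"),
    B: int = 1000,
    seed: int = 0,
    thresholds=None,
) -> dict:
    """P-values of several region tests on one shared permutation stream.

    Returns a dict mapping method name to P-value; ``"ada"`` uses the
    adjusted P-value of the ADA test (default threshold grid unless
    ``thresholds`` is given).  Sharing the masks pairs the methods'
    Monte-Carlo noise, which is what a power comparison wants.
    """
    prep, masks, obs_mask = _perm_setup(data, B, seed)
    out = {}
    for name in methods:
        if name == "ada":
            cfg = AdaConfig(
                thresholds=thresholds if thresholds is not None else AdaConfig().thresholds,
                n_permutations=B,
                seed=seed,
            )
            out[name] = ada_test(data, cfg).adjusted_p
            continue
        method = Method(name)
        fn = _stat_fn(method, prep)
        out[name] = _engine.plus_one_pvalue(float(fn(obs_mask)[0]), fn(masks))
    return out
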