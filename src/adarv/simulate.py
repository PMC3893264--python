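"""Disease-model simulation: haplotype pools, PAR-parameterised effect
sizes, multiplicative penetrance, and prospective case/control sampling.

The pool generator emulates coalescent-simulated sequence data at the two
properties the region tests are sensitive to: a rare-dominated MAF
spectrum (density proportional to 1/x on [5e-5, 0.05], so most sites are
rare) and inter-site dependence (blocks of sites are copied between
haplotypes, the sample-level analogue of shared ancestry).  A designated
subset of rare sites (population MAF < 1%) is causal; a fraction r_isk %
of them is deleterious, the remainder protective.

Effect sizes come from the population attributable risk (PAR): the
genotype relative risk of a deleterious causal variant with population
MAF q is GRR = 1 + PAR / ((1 - PAR) q); a protective variant gets the
reciprocal.  Disease risk is multiplicative across causal alleles,
P(affected | g) = min(1, f0 * prod_j GRR_j ^ g_j), with baseline
penetrance f0 = 1%.  Subjects are sampled prospectively: chromosome pairs
are drawn from the pool with replacement and assigned by a Bernoulli
affection draw until the case and control quotas are filled.

A consequence of this parameterisation (relevant to power asymmetries):
for equal MAF and PAR, a deleterious variant has a larger case-control
odds ratio than the reciprocal of a protective variant's, OR_D > 1/OR_P.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .data import CaseControlData, InputError

__all__ = [
    "HaplotypePool",
    "DiseaseModel",
    "REGION_PRESETS",
    "region_preset",
    "generate_pool",
    "par_to_grr",
    "affection_probability",
    "sample_case_control",
]

#: d causal variants -> number of neutral variants in the region preset
#: (~3.6 kb with ~60 neutral sites for d=3 up to ~25.6 kb with ~400 for d=20).
REGION_PRESETS = {3: 60, 5: 100, 10: 200, 15: 300, 20: 400}

_MAF_RANGE = (5e-5, 0.05)
_CAUSAL_MAX_MAF = 0.01


def region_preset(d: int) -> int:
    """Neutral-variant count of the region preset with d causal variants."""
    try:
        return REGION_PRESETS[d]
    except KeyError:
        raise InputError(f"no region preset for d={d}; presets: {sorted(REGION_PRESETS)}")


@dataclass(frozen=True)
class HaplotypePool:
    """A pool of 2N haplotypes over K sites with designated causal sites."""

    haplotypes: np.ndarray    # (2N, K) uint8
    maf: np.ndarray           # (K,) population MAFs the sites were drawn at
    causal_idx: np.ndarray    # (d,) indices of causal sites
    is_protective: np.ndarray  # (d,) bool, aligned with causal_idx

    @property
    def n_chromosomes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


@dataclass(frozen=True)
class DiseaseModel:
    """Per-site GRRs implied by a PAR under multiplicative penetrance."""

    par: float
    f0: float
    grr: np.ndarray          # aligned with the pool's causal_idx
    r_isk: float

    @classmethod
    def from_pool(cls, pool: HaplotypePool, par: float, f0: float = 0.01,
                  r_isk: float | None = None) -> "DiseaseModel":
        grr = np.array(
            [
                par_to_grr(par, float(pool.maf[j]), protective=bool(prot))
                for j, prot in zip(pool.causal_idx, pool.is_protective)
            ]
        )
        if r_isk is None:
            d = len(pool.causal_idx)
            r_isk = 100.0 * (d - int(pool.is_protective.sum())) / d if d else 100.0
        return cls(par=par, f0=f0, grr=grr, r_isk=r_isk)


def _rare_skewed_maf(rng, size, lo, hi):
    """Draw from density proportional to 1/x on [lo, hi] (log-uniform)."""
    return lo * (hi / lo) ** rng.random(size)


def generate_pool(
    K_neutral: int,
    d: int,
    r_isk: float,
    seed,
    n_chromosomes: int = 10_000,
    block_size: int = 25,
    copy_prob: float = 0.4,
) -> HaplotypePool:
    """Generate a haplotype pool with d causal and K_neutral neutral sites.

    Site MAFs are drawn from the 1/x spectrum on [5e-5, 0.05].  Causal
    sites are sampled among sites with MAF < 1%; ceil(d * r_isk / 100) of
    them are marked deleterious, the rest protective.  Linkage is induced
    block-wise: sites are partitioned into blocks of ``block_size``, and
    within each block a fraction ``copy_prob`` of haplotypes replaces its
    block with a copy from a random non-copying haplotype.  Copying whole
    blocks makes rare alleles at nearby sites co-occur on duplicated
    haplotypes, so sample LD is positive while each site's marginal
    frequency stays at its MAF.
    """
    if d < 1:
        raise InputError("need at least one causal site")
    if not 0 <= r_isk <= 100:
        raise InputError("r_isk must be a percentage in [0, 100]")
    rng = np.random.default_rng(seed)
    K = K_neutral + d
    lo, hi = _MAF_RANGE
    for _attempt in range(10):
        maf = _rare_skewed_maf(rng, K, lo, hi)
        rare = np.nonzero(maf < _CAUSAL_MAX_MAF)[0]
        if len(rare) >= d:
            break
    else:
        raise InputError(
            f"could not draw {d} sites with MAF < {_CAUSAL_MAX_MAF} in 10 attempts"
        )
    causal_idx = np.sort(rng.choice(rare, size=d, replace=False))

    H = (rng.random((n_chromosomes, K)) < maf[None, :]).astype(np.uint8)
    for start in range(0, K, block_size):
        block = slice(start, min(start + block_size, K))
        copiers = np.nonzero(rng.random(n_chromosomes) < copy_prob)[0]
        donors_pool = np.setdiff1d(np.arange(n_chromosomes), copiers, assume_unique=True)
        if len(copiers) == 0 or len(donors_pool) == 0:
            continue
        donors = rng.choice(donors_pool, size=len(copiers))
        H[copiers, block] = H[donors, block]

    # effect-direction assignment drawn last: pools generated from the same
    # seed share haplotypes and causal sites across r_isk values (paired runs)
    n_del = ceil(d * r_isk / 100.0)
    is_protective = np.ones(d, dtype=bool)
    is_protective[rng.choice(d, size=n_del, replace=False)] = False
    return HaplotypePool(
        haplotypes=H, maf=maf, causal_idx=causal_idx, is_protective=is_protective
    )


def par_to_grr(par: float, maf: float, protective: bool = False) -> float:
    """Genotype relative risk implied by a per-variant PAR at population MAF.

    Deleterious: GRR = 1 + PAR / ((1 - PAR) * maf); protective: the
    reciprocal, so the effect direction is flipped while PAR = 0 maps to
    GRR = 1 in both cases.
    """
    if not 0 <= par < 1:
        raise InputError("par must be in [0, 1)")
    if not 0 < maf < 0.5:
        raise InputError("maf must be in (0, 0.5)")
    grr = 1.0 + par / ((1.0 - par) * maf)
    return 1.0 / grr if protective else grr


def affection_probability(genotype, model: DiseaseModel) -> np.ndarray:
    """P(affected) for dosage vector(s) over the causal sites.

    Multiplicative across causal sites and alleles:
    min(1, f0 * prod_j GRR_j ^ g_j).  Accepts a (d,) vector or an (m, d)
    matrix of dosages; returns a scalar-shaped or (m,) array.
    """
    g = np.atleast_2d(np.asarray(genotype, dtype=float))
    logp = np.log(model.f0) + g @ np.log(model.grr)
    p = np.minimum(np.exp(logp), 1.0)
    return p[0] if np.asarray(genotype).ndim == 1 else p


def sample_case_control(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_cases: int = 500,
    n_controls: int = 500,
    seed=0,
    max_draws: int | None = None,
) -> CaseControlData:
    """Draw chromosome pairs with replacement until the case and control
    quotas are filled; surplus draws in a filled stratum are discarded.

    Raises an error (with the affection rate in the message) if the quota
    is not reached within ``max_draws`` subject draws — a guard against
    models whose marginal affection probability is too extreme.
    """
    rng = np.random.default_rng(seed)
    if max_draws is None:
        max_draws = int(200 * (n_cases + n_controls) / model.f0)
    Hc = pool.haplotypes[:, pool.causal_idx]
    case_pairs, control_pairs = [], []
    drawn = 0
    batch = max(4 * (n_cases + n_controls), int(1.3 * n_cases / model.f0))
    while (len(case_pairs) < n_cases or len(control_pairs) < n_controls) and drawn < max_draws:
        m = min(batch, max_draws - drawn)
        i1 = rng.integers(0, pool.n_chromosomes, size=m)
        i2 = rng.integers(0, pool.n_chromosomes, size=m)
        drawn += m
        g_causal = (Hc[i1].astype(np.int16) + Hc[i2]).astype(float)
        p_aff = np.atleast_1d(affection_probability(g_causal, model))
        affected = rng.random(m) < p_aff
        need_case = n_cases - len(case_pairs)
        need_ctrl = n_controls - len(control_pairs)
        ci = np.nonzero(affected)[0][:need_case]
        ui = np.nonzero(~affected)[0][:need_ctrl]
        case_pairs.extend(zip(i1[ci], i2[ci]))
        control_pairs.extend(zip(i1[ui], i2[ui]))
    if len(case_pairs) < n_cases or len(control_pairs) < n_controls:
        rate = model.f0
        raise RuntimeError(
            f"quota not reached in {drawn} draws "
            f"({len(case_pairs)}/{n_cases} cases, {len(control_pairs)}/{n_controls} "
            f"controls; baseline penetrance {rate:g})"
        )
    pairs = np.array(case_pairs + control_pairs)
    G = (pool.haplotypes[pairs[:, 0]].astype(np.int8)
         + pool.haplotypes[pairs[:, 1]].astype(np.int8))
    y = np.r_[np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    ids = tuple(f"v{i+1}" for i in range(pool.n_sites))
    return CaseControlData(genotypes=G, phenotype=y, variant_ids=ids)
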