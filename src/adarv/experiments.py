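"""Type-I error and power experiments over the disease-model simulator.

The harness draws haplotype pools, samples case/control panels under a
PAR-parameterised disease model, applies the 5% combined-sample MAF
filter, and evaluates the requested region tests.  All methods (and all
ADA threshold grids) within one replicate share the same data and the
same permutation masks, so power contrasts between methods are paired.

The default scale is a desk-scale profile (tens of pools, tens to
hundreds of replicates, B in the hundreds); the full design the method
was originally evaluated at (200 pools x 1000 null replicates with
B = 10,000) is reachable by raising the same knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .ada import DEFAULT_THRESHOLDS
from .data import EmptyRegionError, maf_filter
from .simulate import DiseaseModel, generate_pool, region_preset, sample_case_control

__all__ = ["ExperimentGrid", "scenario_pvalues", "run_type1", "run_power", "plot_power"]

_BURDEN = ("sigma_midp", "t1", "t5", "ws", "vt")


@dataclass(frozen=True)
class ExperimentGrid:
    """Scenario grid and Monte-Carlo budget for the experiment harness.

    ``scenarios`` is a list of (r_isk %, par, d) triples; ``n_datasets``
    haplotype pools are drawn per scenario with ``n_replicates``
    case/control panels each, and every test uses ``B`` permutations.
    """

    scenarios: tuple = ((100, 0.003, 20),)
    n_datasets: int = 20
    n_replicates: int = 25
    alpha_levels: tuple = (0.01, 0.05)
    methods: tuple = ("ada",) + _BURDEN
    B: int = 500
    seed: int = 0
    thresholds: tuple = DEFAULT_THRESHOLDS

    def __post_init__(self):
        for r_isk, par, d in self.scenarios:
            if not (0 <= r_isk <= 100 and 0 <= par < 1 and d >= 1):
                raise ValueError(f"scenario out of range: {(r_isk, par, d)}")
        if self.n_datasets < 1 or self.n_replicates < 1 or self.B < 1:
            raise ValueError("replicate counts and B must be >= 1")


def _ada_grid_pvalues(prep, a_obs, A, grids):
    """Adjusted ADA P-values for several threshold grids on shared masks."""
    union = np.array(sorted({t for g in grids.values() for t in g}))
    SD_obs, SP_obs = _engine.ada_scores(prep, a_obs, union)
    S_obs = _engine.combine_scores(SD_obs, SP_obs, "max")[0]
    SD, SP = _engine.ada_scores(prep, A, union)
    S = _engine.combine_scores(SD, SP, "max")
    out = {}
    for name, grid in grids.items():
        cols = np.searchsorted(union, np.asarray(grid))
        _, _, adj, _ = _engine.minp_adjust(S_obs[cols], S[:, cols])
        out[name] = adj
    return out


def _replicate_pvalues(data, methods, ada_grids, B, rng):
    """P-values of every requested method on one case/control panel."""
    try:
        data = maf_filter(data, 0.05)
    except EmptyRegionError:
        return {m: 1.0 for m in list(ada_grids) + [m for m in methods if m != "ada"]}
    prep = _engine.prepare(data)
    masks = _engine.permutation_masks(data.n_subjects, data.n_cases, B, rng)
    obs_mask = prep.y.astype(np.float32)[None, :]
    need_counts = "ada" in methods or "sigma_midp" in methods or "ws" in methods
    A = _engine.case_counts(prep, masks) if need_counts else None
    a_obs = _engine.case_counts(prep, obs_mask) if need_counts else None
    out = {}
    if "ada" in methods:
        out.update(_ada_grid_pvalues(prep, a_obs, A, ada_grids))
    for m in methods:
        if m == "ada":
            continue
        if m == "sigma_midp":
            obs = float(_engine.sigma_midp_stats(prep, a_obs)[0])
            perm = _engine.sigma_midp_stats(prep, A)
        elif m in ("t1", "t5"):
            cut = 0.01 if m == "t1" else 0.05
            obs = float(_engine.fixed_threshold_stats(prep, obs_mask, cut)[0])
            perm = _engine.fixed_threshold_stats(prep, masks, cut)
        elif m == "ws":
            obs = float(_engine.weighted_sum_stats(prep, a_obs, obs_mask)[0])
            perm = _engine.weighted_sum_stats(prep, A, masks)
        elif m == "vt":
            obs = float(_engine.variable_threshold_stats(prep, obs_mask)[0])
            perm = _engine.variable_threshold_stats(prep, masks)
        else:
            raise ValueError(f"unknown method {m!r}")
        out[m] = _engine.plus_one_pvalue(obs, perm)
    return out


def scenario_pvalues(
    r_isk: float,
    par: float,
    d: int,
    *,
    n_datasets: int,
    n_replicates: int,
    B: int,
    seed: int,
    methods=("ada",),
    ada_grids: dict | None = None,
    n_cases: int = 500,
    n_controls: int = 500,
) -> pd.DataFrame:
    """Per-replicate P-values for one (r_isk, par, d) scenario.

    One row per replicate; one column per method (ADA appears once per
    entry of ``ada_grids``, default a single ``"ada"`` column with the
    recommended grid).  Deterministic given ``seed``.
    """
    if ada_grids is None:
        ada_grids = {"ada": DEFAULT_THRESHOLDS}
    K_neutral = region_preset(d)
    rows = []
    for ds in range(n_datasets):
        pool = generate_pool(K_neutral, d, r_isk, seed=np.random.SeedSequence((seed, 1, ds)))
        model = DiseaseModel.from_pool(pool, par=par, r_isk=r_isk)
        for rep in range(n_replicates):
            data = sample_case_control(
                pool, model, n_cases, n_controls,
                seed=np.random.SeedSequence((seed, 2, ds, rep)),
            )
            rng = np.random.default_rng(np.random.SeedSequence((seed, 3, ds, rep)))
            pv = _replicate_pvalues(data, methods, ada_grids, B, rng)
            pv["dataset"] = ds
            pv["replicate"] = rep
            rows.append(pv)
    df = pd.DataFrame(rows)
    return df.set_index(["dataset", "replicate"])


def _reject_table(pvals: pd.DataFrame, alpha_levels) -> pd.DataFrame:
    recs = []
    n = len(pvals)
    for col in pvals.columns:
        for alpha in alpha_levels:
            rate = float((pvals[col] <= alpha).mean())
            recs.append(
                {
                    "method": col,
                    "alpha": alpha,
                    "rate": rate,
                    "se": float(np.sqrt(rate * (1 - rate) / n)),
                    "n": n,
                }
            )
    return pd.DataFrame(recs)


def run_type1(grid: ExperimentGrid) -> pd.DataFrame:
    """Empirical type-I error per method x nominal level (PAR forced to 0).

    Uses the d = 20 region preset (the widest region, the hardest
    multiplicity setting) regardless of the power scenarios in ``grid``.
    """
    pv = scenario_pvalues(
        80, 0.0, 20,
        n_datasets=grid.n_datasets,
        n_replicates=grid.n_replicates,
        B=grid.B,
        seed=grid.seed,
        methods=grid.methods,
        ada_grids={"ada": grid.thresholds},
    )
    return _reject_table(pv, grid.alpha_levels)


def run_power(grid: ExperimentGrid) -> pd.DataFrame:
    """Empirical power per method x scenario (paired replicates per scenario)."""
    frames = []
    for idx, (r_isk, par, d) in enumerate(grid.scenarios):
        pv = scenario_pvalues(
            r_isk, par, d,
            n_datasets=grid.n_datasets,
            n_replicates=grid.n_replicates,
            B=grid.B,
            seed=grid.seed + idx,
            methods=grid.methods,
            ada_grids={"ada": grid.thresholds},
        )
        tab = _reject_table(pv, grid.alpha_levels)
        tab.insert(0, "r_isk", r_isk)
        tab.insert(1, "par", par)
        tab.insert(2, "d", d)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def plot_power(power_table: pd.DataFrame, path) -> None:
    """Three-panel power plot: power vs r_isk, vs PAR, and vs d."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharey=True)
    panels = [("r_isk", "% deleterious (r_isk)"), ("par", "PAR"), ("d", "causal variants (d)")]
    for ax, (var, label) in zip(axes, panels):
        for (method, alpha), sub in power_table.groupby(["method", "alpha"]):
            sub = sub.sort_values(var)
            if sub[var].nunique() < 2:
                continue
            ax.plot(sub[var], 100 * sub["rate"], marker="o",
                    label=f"{method} (α={alpha:g})")
        ax.set_xlabel(label)
    axes[0].set_ylabel("power (%)")
    handles, labels = axes[0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper center", ncol=4, fontsize=8)
    fig.tight_layout(rect=(0, 0, 1, 0.9))
    fig.savefig(path, dpi=120)
    plt.close(fig)
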