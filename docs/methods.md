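# Methods notes

## The statistic

ADA tests a region of K variants for association with a binary phenotype.
All per-site computation is at the allele (chromosome) level: site i's
2×2 table counts minor/major alleles on the 2·n_case case chromosomes and
2·n_ctrl control chromosomes. Three per-site quantities feed the statistic:

* **Mid-P value** `p_i`: two-sided Fisher exact test under the
  hypergeometric null, point-probability criterion — the probability of all
  tables strictly less probable than the observed one plus *half* the
  probability of tables exactly as probable (the observed table included).
  Mid-P is used instead of the standard exact P because the exact P of a
  discrete table is conservative (its null mean exceeds 0.5) and the
  combination statistic aggregates many such P-values; mid-P has null mean
  exactly 0.5 (checked by simulation in the test suite).
* **Direction**: deleterious-inclined if the minor-allele frequency is
  larger in cases, protective-inclined if larger in controls, tied if equal
  (exact integer cross-multiplication; ties carry no direction and
  contribute to neither score).
* **Weight** `w_i = 1/√(n·q̂_i·(1−q̂_i))` with `q̂_i = (m_i+1)/(2n+2)`
  estimated from the n control subjects (Madsen–Browning). The +1 smoothing
  keeps q̂ in (0,1), so weights are finite; the weight is decreasing in the
  control count — variants rare in controls are up-weighted.

Per-site evidence is combined per truncation threshold θ_j as
`S^D_j = Σ 1{del} 1{p_i < θ_j} w_i (−ln p_i)` and the analogous `S^P_j`;
the region statistic is `S_j = max(S^D_j, S^P_j)`. The per-site
contribution is `w·(−ln p)` rather than `w·(−2 ln p)`: the factor 2
rescales every observed and permuted statistic identically and cancels in
permutation ranks (σ-MidP, which is reported as a raw statistic, keeps the
conventional −2 ln p). Truncation uses the *strict* inequality `p < θ`.
A sum mode (`S^D_j + S^P_j`) is available behind
`statistic_mode="sum"`; max is the default because coding and regulatory
regions typically harbour more deleterious than protective variation, and
max is the more powerful statistic in that asymmetric regime.

## Permutation scheme and estimators

Case/control labels are permuted B times with the case count fixed.
Weights, directions and mid-P values are **recomputed inside every
permutation** — they are functions of which subjects are labelled controls,
and freezing them at their observed values would test a different (and not
exactly valid) null. Because the table margins are permutation-invariant,
every per-site quantity is a function of the site's case minor-allele
count alone; the engine therefore precomputes per-site lookup tables and
obtains all B permuted score vectors from one BLAS matrix product, making
recomputation essentially free.

Estimator conventions (all standard, all chosen for validity):

* Observed vs permuted: `p_j = (1 + #{b: S_j^(b) ≥ S_j}) / (B+1)` — the
  add-one estimator guarantees p > 0 and exact validity; ties count
  against the observed statistic (conservative).
* Within-permutation ranks (needed for each permutation's own minimum
  P-value): `p_j^(b) = #{b′: S_j^(b′) ≥ S_j^(b)} / B`, ranked against the
  B permuted statistics only (leave-observed-out; including the observed
  value is an equally valid convention and changes ranks by at most 1/B).
* Adjusted P-value: `(1 + #{b: minP^(b) ≤ minP_obs}) / (B+1)`, so
  `adjusted_p ∈ [1/(B+1), 1]`; B must exceed 1/α for the target level α
  (B = 1000 resolves 0.001).
* `ada_test(..., exhaustive=True)` replaces Monte-Carlo permutations by
  enumeration of all C(n, n_cases) label assignments (denominator N, the
  observed labelling being one of the N); practical only for tiny n, used
  by the enumeration-oracle tests.

One vectorised random stream (numpy `default_rng(seed)`) generates all B
masks per invocation; per-permutation independent sub-streams were
considered for parallel execution but rejected — the engine is already
vectorised across permutations, and a single stream keeps the permutation
set bit-reproducible from one integer seed.

Numerical details: equiprobability of hypergeometric point masses is
declared at relative tolerance 1e-12 (guards against float noise splitting
genuinely equiprobable tables); mid-P values are clipped to (0, 1];
monomorphic-in-sample sites are assigned p = 1, direction = tied, and are
dropped inside the engine (they contribute zero to every score in every
permutation, so this is exactly equivalent and saves ~30% of the columns);
a region that is entirely monomorphic yields adjusted_p = 1.

## Comparators

All five comparators share the ADA permutation stream and the add-one
estimator, and are two-tailed via absolute statistics:

* **σ-MidP**: `Σ w_i (−2 ln p_i)` over non-tied sites.
* **T1 / T5**: per-subject count of minor alleles over variants with
  pooled-sample MAF strictly below 1% / 5%; statistic = |mean case −
  mean control score|.
* **WS**: Madsen–Browning rank sum of weighted per-subject scores,
  |ranksum − n_case(n+1)/2|, average ranks for ties, weights recomputed
  from each permutation's own controls.
* **VT**: `z(t) = Σ_i (φ_i − φ̄) C_i(t) / √(Σ_i C_i(t)²)` maximised over
  candidate thresholds t, statistic = max |z|. Candidate thresholds are
  the distinct observed pooled MAFs and the score counts variants with
  MAF ≤ t: with a strict `<` at the candidate values the smallest
  threshold would select no variants and a single-variant region would be
  untestable, so the inclusive convention is the coherent reading. The
  denominator is label-invariant, which makes the permutation loop one
  matrix product.

## The disease-model simulator

`generate_pool` stands in for coalescent-simulated haplotypes. It
reproduces the two features the region tests are actually sensitive to:

* **Rare-dominated MAF spectrum**: site MAFs are log-uniform (density ∝
  1/x) on [5·10⁻⁵, 0.05]; causal sites are drawn among sites with
  MAF < 1%.
* **Inter-site dependence**: sites are partitioned into blocks of 25; in
  each block 40% of the 10,000 haplotypes replace their block with a copy
  from a random non-copying haplotype. Block duplication is the
  sample-level analogue of shared ancestry: rare alleles at nearby sites
  co-occur on duplicated haplotypes, giving positive sample LD while
  leaving each site's marginal frequency at its MAF. A consequence of
  *any* LD scheme is that realised column frequencies scatter more than
  binomially, so the generator check asserts that >90% of columns fall
  within 3 binomial SE, not all of them.

Region presets map the causal count d ∈ {3, 5, 10, 15, 20} to
{60, 100, 200, 300, 400} neutral sites. Effect sizes come from the
population attributable risk: `GRR = 1 + PAR/((1−PAR)·q)` for a
deleterious variant of MAF q, the reciprocal for a protective one, so
PAR = 0 gives GRR = 1 in both directions. Disease risk is multiplicative,
`P(aff|g) = min(1, f0·Π GRR_j^{g_j})` with baseline penetrance f0 = 1%
(the min-clip keeps the probability valid for extreme multi-carrier
genotypes; at the default parameters it essentially never binds).
Sampling is prospective with replacement until 500 cases and 500 controls
are drawn, with a draw cap that aborts with a diagnostic if the marginal
affection rate makes the quota unreachable. This parameterisation implies
an effect-size asymmetry — for equal MAF and PAR the deleterious odds
ratio exceeds the reciprocal of the protective one — which the test suite
verifies by Monte-Carlo and which explains why power is lowest at small
(but nonzero) deleterious fractions rather than at 50%.

What the generator does **not** emulate: realistic recombination-driven
LD decay (block copying is exchangeable within blocks and absent between
them), population growth or selection shaping the frequency spectrum, and
genotyping error. Calibration conclusions (type-I error) are insensitive
to these; absolute power levels are not, so power figures should be read
as reproducing the *regime and ordering* of the original experiments
rather than haplotype-exact values.

## Experiment scales

Monte-Carlo scales were chosen as the largest runs that keep the full
suite and the acceptance script comfortably interactive on one CPU:
null calibration uses 20 pools × 100 panels (2000 replicates) with
B = 1000; power runs use 20 pools × 25 panels (500 replicates) with
B = 1000; both threshold grids are evaluated on identical replicates and
permutations, as are all comparators (paired design). The `ada benchmark`
command defaults to a lighter desk profile (B = 500) and exposes the
original full-scale profile behind a flag.

## Known limitations

* Binary phenotypes only; no covariate adjustment. The recipe used in the
  resequencing literature — regress the quantitative trait on covariates,
  dichotomise the residuals at chosen percentiles, drop subjects with
  missing genotypes — is a preprocessing step outside the package.
* Permutation P-values only; no analytic approximation for very small α
  (genome-wide use would need B in the millions or an adaptive stopping
  rule).
* Missing genotypes are handled by dropping subjects, which is wasteful
  when missingness is heavy; no imputation.
* Kernel-machine tests (SKAT family) are out of scope as comparators.
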