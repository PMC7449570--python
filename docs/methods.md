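# Methods

## Disease model and effect size

A multiplicative per-allele model links the population minor allele
frequency `p`, relative risk `γ`, and prevalence `K` to group frequencies

    p_case = p γ / [1 + p(γ − 1)],   p_control = (p − K p_case) / (1 − K),

which satisfy the total-probability identity `K p_case + (1−K) p_control = p`
by construction. Models in which the implied control frequency leaves [0, 1]
(e.g. prevalence too large for the given `p`, `γ`) are rejected rather than
clipped. Genotype variances use Hardy–Weinberg proportions within each
disease group, `v = 2q(1−q)`; under the multiplicative model the case group
departs from HWE only at second order, and the enumeration test confirms
agreement with the exact conditional variance to three significant figures
at the parameters of interest.

The standardized effect size is

    η = 2(p_case − p_control) / sqrt[(1+s)(v_case + v_control/s) + 4Δ²],

with `Δ = p_case − p_control` and `s` the case:control ratio (cases per
control). The radical is exactly the pooled-variance standardization of the
two-sample genotype-mean difference: with case fraction `f = s/(1+s)` the
combined-sample (mixture) genotype variance is
`f v_case + (1−f) v_control + f(1−f)(2Δ)²`, and multiplying by
`(1+s)²/s` — the factor from `1/n_case + 1/n_control` — expands to the
expression above. Consequently `η√N` is the expected value of the two-sample
Z statistic computed with the pooled variance estimate, which is how the
Monte Carlo simulator computes it; the simulation oracle (mean Z over
20,000 replicates vs `η√N`) agrees to within 3 standard errors and pins
this reading of the formula.

`η² × (effective sample size)` is the noncentrality of the 1-df chi-square
association test.

## Combined test and analytic power

For `n` sequenced and `m` imputed participants the subsample statistics are
combined as `Z = √c Z_seq + √(1−c) Z_imp` with `c = n/(n + r²m)`; `Z` is
asymptotically N(λ, 1) with `λ = η√(n + r²m)`. Two-sided power at level α is

    Power = Φ(λ − z₁₋α/₂) + Φ(−λ − z₁₋α/₂),

identically α at λ = 0. The default α is 5×10⁻⁸ (conventional genome-wide
threshold), exposed as a parameter.

## Empirical weighted power estimator

Expected power for a variant with population MAF `p` averages per-variant
analytic power over a quality table measured (or generated) at the design's
panel size `n`:

    Power(m, n) = Σ_j w_j C_nj Power(λ_nj) / Σ_j w_j,

where `C_nj = I(panel MAC ≥ 5 and r²_nj ≥ 0.3)` is the imputability
indicator and `w_j = w_j^MAF · w_j^PS · (row weight)`. Choices that matter:

- **r² threshold comparison** is non-strict (≥ 0.3) to match the indicator
  definition; a `r2_strict` flag flips it. The two conventions differ only
  on exact ties, which have measure zero in measured tables.
- **Non-imputable variants keep their weight** in the denominator while
  contributing zero power. This makes the weighted imputable probability an
  upper bound on power and produces the characteristic plateau of power
  below 1 as `m → ∞`.
- **w^MAF** is the ratio of the model-implied Poisson probability of the
  variant's sample MAC (mean `2N(s·p_case + p_control)/(s+1)`) to the
  empirical proportion of table variants at that MAC. Both numerator and
  denominator use the table's evaluation sample size `N` by default, so the
  ratio compares like with like; a `gwas_n` option substitutes a different
  sample size in the numerator.
- **w^PS** compares the model-implied and observed probabilities that a
  variant of the given MAF is population-specific, using per-bin empirical
  fractions (default bin edges 0.1%, 0.25%, 0.5%, 5%, 50% on the folded
  MAF, with a catch-all bin below 0.1%; half-open intervals). If a record's
  flag is impossible under its bin's empirical fraction (fraction exactly 0
  for a flagged variant, or 1 for an unflagged one) its weight is set to 0
  with a logged warning.
- **η is computed once** from the population MAF of the disease model, not
  per record: the per-variant quantities that vary are `r²` and
  imputability, not the hypothesized effect.
- Tables aggregated by MAF bin (rows carrying a `weight` column of variant
  counts) are supported transparently; the row weight multiplies the two
  adjustment weights.

A zero total weight (disease-model MAC distribution disjoint from the
table's MAC support) is an error, not a silent zero.

## Quality tables

Tables are TSV (gzip-transparent) with one row per variant and key columns
(population, array, panel size, evaluation N) constant per file. Sample
frequencies above 0.5 are folded onto the minor allele on read and flagged
in a provenance column. Variants absent from the reference panel carry a
missing r² and panel MAC 0 and are never imputable. Imputation r² computed
from paired true/imputed genotype matrices is the squared Pearson
correlation across samples; it is undefined (missing) when either vector is
constant.

Designs at panel sizes between measured tables use per-variant linear
interpolation of r² and panel MAC between the bracketing tables, matched by
variant id, with no extrapolation outside the measured range. The
imputability rule is applied to the interpolated values (an interpolated
panel MAC of 2.5 is not imputable). A missing r² interpolated against a
measured one is treated as 0 on the missing side; missing at both ends stays
missing. Linear interpolation is deliberately conservative — it introduces
no model beyond the measured endpoints.

## Synthetic quality-table generator

The generator emulates the structure of masked-imputation experiments, not
any particular dataset: per-variant MAF is drawn with density ∝ 1/p on
[10⁻⁴, 0.5]; the probability of being population-specific decays
exponentially in MAF (scale 1%, max 0.5); mean r² follows a saturation
curve `r2_max(array) · x/(x + n50(MAF))` in the effective panel size
`x = panel_n + 0.05 × external panel size` (population-specific variants
receive no external contribution), with `n50` growing as MAF falls
(30 × (0.01/MAF)^0.7) and per-variant r² Beta-distributed with
concentration 30; panel MACs are binomial in the panel haplotypes. Array
ceilings default to 0.82 / 0.90 / 0.93 for the Core, OmniExpress, Omni2.5.
Draws are coupled across panel sizes and arrays through common per-variant
quantiles, so each variant's quality is monotone in panel size by
construction. Defaults (2,000 variants, panel sizes 0–2,000, external panel
30,000, evaluation N 3,412) mirror the scale of reference-panel-augmentation
experiments in admixed cohorts.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, array-specific marker placement, imputation-software
artifacts, and admixture heterogeneity. Tests on synthetic tables therefore
validate the estimator's arithmetic, weighting, monotonicity, and bounds —
not the realism of any particular quality surface; real use should feed
measured quality tables.

## Monte Carlo simulator

Each replicate draws HWE genotypes at `p_case`/`p_control` (deterministic
case/control split at the design's case fraction; random subsampling of who
is sequenced is equivalent to independent draws under the model). Imputed
dosages are `D = G + ε` with Gaussian noise scaled to the population
genotype mixture variance so that corr(G, D)² converges to the target r²
(the imputation process is blind to case status, hence the mixture
variance); dosages are unclipped for statistics and only clipped on file
export. Subsample statistics use the pooled-variance two-sample form;
replicates with a constant combined sample give Z = 0.

Simulations are batched to hold roughly 2×10⁷ scalar draws in memory at a
time and are fully reproducible from a single integer seed.

**Finite-sample behaviour worth knowing:** for rare variants with very small
subsamples (expected subsample minor allele count below ~5) the discrete
allele-count statistic is slightly conservative (type-I error ≈ 0.045 at
α = 0.05), and at power ≈ 1 the simulated rejection rate can sit a few 10⁻⁴
above the analytic value. Both are properties of the exact statistic, not
errors; calibration tests are therefore run in the asymptotic regime the
formula assumes (common variants, moderate subsample sizes), and power
agreement is checked at designs sized to λ ≈ z_crit where the comparison is
most sensitive.

## Optimizer

The search is exhaustive over the (n, m, array) grid — n over available
(or interpolable) panel sizes, m in configurable steps (default 50) — so
optimality is by enumeration; a property test keeps it equal to an
independent brute-force loop in case pruning is ever added. Costs are held
in integer cents; budget feasibility is inclusive (cost ≤ budget). Ties are
broken by lower cost, then lower n, then lower m (cheaper and simpler
logistics first). Infeasible searches return an explicit result carrying the
maximum power found rather than raising.

## Numerical choices

- Poisson sample-MAC pmf truncated where cumulative mass reaches 1 − 10⁻¹²,
  giving finite support for the MAF weights; total-variation distance to
  the exact binomial-mixture law is below 0.01 for MAF ≤ 1% at the sample
  sizes tested.
- Normal quantiles and CDFs via scipy; power is computed in the
  tail-symmetric form `Φ(λ−z) + Φ(−λ−z)`, accurate for both tiny and
  near-one powers.
- Monte Carlo checks use 20,000 replicates and 3-standard-error bands, with
  the standard error evaluated at the analytic value being tested.

## Limitations

Binary traits under a multiplicative model only (the model tag is the
extension point); no covariate adjustment; no LD-proxy power for
non-imputable variants (their power is assumed zero, which is conservative
for common variants); single-study optimization (a design optimal for one
study need not maximize meta-analysis power); cost model covers sequencing
and genotyping only, not recruitment or sample collection.
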