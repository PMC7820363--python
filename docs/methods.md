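# Methods

## The mixture model

An *informative site* is a polymorphic site or a substitution relative to an
outgroup. At a site with `n` sampled alleles, the allele count `k` under
neutrality is taken to follow the genome-wide SFS `g_n(k)`, normalized
within each sample-size stratum. Near a locus where balancing selection
maintains allelic classes at equilibrium frequencies, a completely linked
neutral site's alleles ride on one of the balanced haplotype classes, so its
count is approximately binomial around the class frequency. With probability
of complete linkage modelled as `α_A(d) = exp(−A·d)` (distance `d` in cM,
decay `A` per cM), the per-site probability is the convex mixture

    f_{n,x,A}(k, d) = α_A(d) h_{n,x}(k) + (1 − α_A(d)) g_n(k).

Five variants adapt the support to the available data:

| variant | polarity | support of k          | substitutions        |
|---------|----------|-----------------------|----------------------|
| `2`     | derived  | 1..n                  | k = n                |
| `0`     | derived  | 1..n−1                | excluded             |
| `1`     | derived  | {polymorphic, k = n}  | dichotomized         |
| `2MAF`  | minor    | 0..⌊n/2⌋              | k = 0                |
| `0MAF`  | minor    | 1..⌊n/2⌋              | excluded             |

The balanced component for a single class at frequency `x` is the binomial
pmf truncated/folded to the variant support and renormalized over it. The
biallelic model composes the derived- and ancestral-class components with
equal weight, `(h_{n,x} + h_{n,1−x})/2`, making the statistic symmetric
under `x ↔ 1 − x`; frequencies are therefore canonicalized to `(0, 0.5]`.

**Folded-component normalization.** For the folded (MAF) component the
numerator `Bin(k) + Bin(n−k)·1{k ≠ n/2}` summed over minor counts equals
exactly 1 (each unfolded count is covered once), so the `2MAF` component is
used in that already-normalized form; a denominator of
`1 − (1−x)^n` would leave a distribution summing to `1/(1−(1−x)^n)`. The
poly-only folded variant divides by `1 − Bin(0) − Bin(n)`, which equals its
numerator sum, so it is proper as printed.

**Multiallelic extension.** For `m ≥ 2` balanced allelic classes with
frequency vector `(x_1..x_m)` on the open simplex, each class's component is
normalized over the variant support first and the per-class components are
averaged with uniform weight `1/m`. The order of operations matters:
normalizing per class *before* averaging is what makes `m = 2` with classes
`(x, 1−x)` reproduce the biallelic composition exactly (the per-class
truncation denominators `1 − (1−x)^n` and `1 − x^n` differ, so mixing the
raw binomial kernels first and normalizing afterwards would not reduce).
Class labels are exchangeable; class vectors are canonicalized in
nondecreasing order, and the grid over the simplex enumerates sorted
compositions of the grid step. `m` is fixed by the user, not optimized over.

## The scan

For a test site, the null composite log-likelihood is `Σ_i ln g(k_i)` and
the alternative is `Σ_i ln f(k_i, d_i)` over informative sites, treated as
independent (a composite, not a true, likelihood — linked sites are
correlated, which is why raw `B` values are ranked rather than referred to a
χ² distribution). `B = 2·max_{(x,A)} [ln L_a − ln L_0]`, with the degenerate
null (`α ≡ 0`) always in the candidate set, so `B ≥ 0`.

Sites with `α_A(d)` below a cutoff contribute numerically identical terms to
both likelihoods; they are skipped, giving each `A` an inclusion radius
`ln(1/cutoff)/A` in cM. The cutoff default is `10⁻⁸`. Windowing is therefore
adaptive: large-`A` (narrow) candidates read few sites, small-`A` (wide)
candidates read many.

Defaults and numerical choices:

* **x grid**: 0.01 to 0.50 in steps of 0.01 (biallelic). Multiallelic
  default step 0.05 — compositions at step 0.01 for `m = 3` would already
  exceed 800 grid points; both steps are configurable.
* **A grid**: 20 values log-uniform on [1, 10⁵] per cM, spanning footprint
  half-widths `ln2/A` from ~0.7 cM down to ~7×10⁻⁶ cM (multi-Mb to sub-kb at
  ~1 cM/Mb). Production grids are a user decision; these are sane defaults.
* **Distances** are `|genPos_i − genPos_test|` in cM; when the input has no
  genetic positions they fall back to `physPos × rate` with a configurable
  uniform rate, default 10⁻⁶ cM/bp (the approximate human genome-wide
  average).
* **Tie-breaking** at equal likelihood: the null candidate wins ties at 0;
  among grid candidates, smallest `A`, then the first (lexicographically
  smallest) `x` in deterministic grid order.
* Binomial pmfs are computed in log space via log-gamma, stable for `n` in
  the thousands; component tables are cached per `(variant, n, x)` and
  shared across test sites, which cannot change values (the per-site scores
  are recomputed for every test position).
* The background conditions on the exact `n` at each site. A site whose `n`
  has no background stratum, or whose `(n, k)` cell has zero background
  mass, is a hard error instructing the user to build the background from
  the dataset being scanned — no hypergeometric projection across sample
  sizes is attempted (a documented possible extension).
* Poly-only variants (`0`, `0MAF`) have no support for substitution
  records; such records are excluded at model construction and counted in
  `BalancingScan.n_dropped`.
* Null-optimal test sites report `B = 0` with NaN sentinels for `x̂`/`Â` and
  `n_sites = 0`.

## Equilibrium calculators

Overdominant fitnesses are `1`, `1 + h·s`, `1 + s` for ancestral homozygote,
heterozygote and mutant homozygote; `h > 1` gives an interior equilibrium at
mutant frequency `h/(2h − 1)`, independent of the magnitude of `s`. The
calculator iterates the deterministic (infinite-population) viability
recursion `p' = p·w̄_mut/w̄`. Because the plain map contracts at rate
`1 − O(s)`, Steffensen (Aitken Δ²) acceleration is applied to the same step
function, and the converged fixed point is polished by a bracketed root
solve on the one-generation displacement — the displacement suffers
catastrophic cancellation for very weak selection, which otherwise caps
accuracy near 10⁻⁹. A plain `biallelic_trajectory` helper exposes the raw
recursion, along which mean fitness is nondecreasing.

With `m` distinct mutant alleles at one site, multiple mutations in one
genotype multiply: a mutant_i/mutant_j heterozygote has fitness
`(1 + h·s)²`, while mutant homozygotes have `1 + s`. (For s = 0.001 and
h = 20 this cross-mutant fitness is 1.02² = 1.0404.) The multiallelic
recursion updates the full state including the ancestral allele,
`x_i' = x_i (Wx)_i / (xᵀWx)`, from a near-symmetric start (mutants at
`(1−ε)/m`, ancestral at ε = 10⁻³) until `max|Δx| < 10⁻¹²`. Under this
scheme the ancestral allele's marginal fitness (`1 + hs`) is below the
mutants' (which enjoy the `(1+hs)²` cross-heterozygotes), so it is driven
out and the mutants settle at `1/m` each; the result reports the residual
ancestral frequency and a loss flag explicitly. Deterministic recursions
are used on purpose: they are exactly reproducible and are what printed
equilibrium values reflect; a stochastic Wright–Fisher simulator is out of
scope.

## Synthetic data

`neutral_dataset` draws allele counts i.i.d. from the background spectrum
(sample sizes drawn from the per-stratum totals); `synth_footprint` places
sites at regular spacing around a center and draws each count from the exact
mixture `f` at its distance, given true `(x0, A0)`. Both are seeded and
deterministic, and the footprint generator emits a JSON sidecar recording
the distributional truth.

The default background used in tests and the acceptance script is the
standard-neutral expectation `ξ_n(k) ∝ θ/k` with a substitution mass at
`k = n` from outgroup divergence — defaults chosen to resemble a human-like
dataset (per-site θ ≈ 10⁻³, ~5 Myr divergence, giving ≈2.8 substitutions
per polymorphic site, `n = 50` lineages). Problem sizes in the shipped
studies — 2,000 sites per 50-kb replicate, 50 recovery replicates, hundreds
of neutral datasets of 100 sites — were chosen to resemble the 50-kb
simulated sequences typical for this kind of power study while keeping the
whole suite comfortably interactive.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: linkage disequilibrium between sites
(draws are independent given the truth; real footprints have correlated
genealogies), recombination-rate variation, mutation-rate heterogeneity,
demography beyond what the supplied background SFS encodes, and ancestral
misidentification. Recovery results on these datasets are a correctness
check of the estimator under its own assumptions, not a power study.

## Heterozygote-excess filter

The one-tailed test conditions on the allele-count margins: with `n_A`
copies of allele A among `2N` gametes, the heterozygote count under
Hardy–Weinberg follows the exact conditional (Levene) distribution
`P(h) ∝ 2^h / [((n_A−h)/2)! h! ((n_a−h)/2)!]` over `h` with the parity of
`n_A`; the P-value is the upper tail at the observed count, and sites with
`P` below a threshold (default 10⁻⁴; 10⁻² is a common choice for sparser
non-human panels) are removed. "Fisher's exact test for HWE" in the
literature sometimes denotes this conditional construction and sometimes a
literal 2×2 table; the conditional form is the default here, with a 2×2
Fisher on the allele-pairing table available as `method="fisher2x2"` for
comparison. Monomorphic sites return `P = 1`.

## Known limitations

* No significance calibration: `B` does not follow a χ² distribution (the
  composite likelihood ignores site correlations and the effective degrees
  of freedom vary along the genome); obtaining P-values requires mass
  simulation under an explicit demographic null, which this package leaves
  to the user.
* Single-scaffold scans; no cross-`n` SFS projection; no ancestral
  misidentification correction.
* The multiallelic component uses the uniform-class-mixture generalization,
  chosen because it reduces exactly to the biallelic composition at
  `m = 2`; alternative weightings (e.g. frequency-weighted class
  membership) are conceivable and not implemented.
* The exponential linkage kernel is a phenomenological proxy for LD decay,
  not a coalescent-derived spectrum; `Â` should be compared only among
  regions with similarly high scores.
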