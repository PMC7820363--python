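# balscan

Composite likelihood ratio scans for **long-term balancing selection** — the
*B*-statistic family — for population-genomic data with per-site allele
counts and an outgroup.

Balancing selection (heterozygote advantage, negative frequency dependence,
…) keeps two or more alleles segregating for very long times. Its genomic
footprint is an excess of sites at intermediate allele frequencies near the
balanced locus, decaying with recombination distance. `balscan` detects such
footprints by modelling the allele count *k* (out of *n* sampled alleles) at
an informative site *d* centimorgans from a putatively balanced test locus
as a two-component mixture:

```
f_{n,x,A}(k, d) = α_A(d) · h_{n,x}(k) + [1 − α_A(d)] · g_n(k),      α_A(d) = e^{−A·d}
```

* `g_n(k)` — the genome-wide site frequency spectrum (SFS), the neutral
  background;
* `h_{n,x}(k)` — a normalized binomial around the equilibrium frequency
  `x`, averaged over the balanced allelic classes (for the biallelic model,
  the classes `x` and `1 − x`; for `m` balanced alleles, a class vector on
  the simplex);
* `α_A(d)` — the probability of complete linkage to a balanced class, with
  free decay rate `A > 0` per cM that sets the footprint size.

Each test site is scored with the maximized composite likelihood ratio

```
B = 2 [ ln L_a(x̂, Â) − ln L_0 ],     L_a = Π_i f(k_i, d_i),   L_0 = Π_i g(k_i),
```

optimized over a grid of `(x, A)`. Five variants accept different input
types: **B2** (derived allele counts + substitutions), **B2maf** (minor
counts, folded), **B1** (polymorphism/substitution dichotomy), **B0** /
**B0maf** (polymorphisms only). Because the null model is nested in the
alternative, `B ≥ 0` always; larger values indicate a better fit of the
balanced mixture. Raw scores are reported ranked by `B` — significance
calibration against an explicit demographic null is deliberately out of
scope.

The package also provides:

* deterministic overdominance equilibrium calculators (bi- and multiallelic,
  with the multiplicative fitness rule for multiple mutant alleles at one
  site), used to connect fitness parameters `(s, h)` to equilibrium
  frequencies `x`;
* a synthetic-footprint generator that draws scan-ready datasets from the
  mixture model itself, for parameter-recovery experiments;
* a one-tailed exact heterozygote-excess test (conditional on allele-count
  margins) for filtering genotyping artifacts before a scan.

## Worked example

Simulate a balanced footprint (true equilibrium frequency `x0 = 0.3`, decay
`A0 = 1000`/cM, 2,000 sites of `n = 50` lineages spanning 50 kb) on a
neutral background, then scan it:

```python
from balscan import (BalancingScan, FootprintSpec, expected_neutral_background,
                     normalize_background, synth_footprint)

bg = expected_neutral_background(50)          # genome-wide background counts
g2 = normalize_background(bg, "2")            # null spectrum for the B2 model
spec = FootprintSpec(x0=0.3, A0=1000.0, n_sites=2000, n_samples=50,
                     site_spacing=25, center=30_000, seed=1)
sites, truth = synth_footprint(spec, g2)

model = BalancingScan(sites.to_dataframe(), bg, variant="2", test_site_policy=10)
res = model.fit()
print(res.summary())
```

```
Balancing-selection composite likelihood ratio scan
=====================================================
Model variant:        B2   (m = 2 balanced classes)
Informative sites:    2000
Test sites scored:    200
x grid:               50 points, A grid: 20 points
alpha cutoff:         1e-08
-----------------------------------------------------
max B:                273.958  at physPos 30000
  x_hat = 0.32  A_hat = 784.76  sites used = 1877
mean B:               14.6641
B > 0 fraction:       0.400
```

The peak lands exactly on the simulated center (physPos 30000), the
estimated equilibrium frequency `x̂ = 0.32` is one grid step from the truth
0.3, and `Â ≈ 785`/cM is close to the true decay 1000/cM. Rows near the
peak (`res.frame`):

```
 physPos  genPos        CLR  x_hat     A_hat  n_sites
   29500 0.02950 245.192434   0.32 784.75997     1877
   29750 0.02975 268.699756   0.32 784.75997     1877
   30000 0.03000 273.958280   0.32 784.75997     1877
   30250 0.03025 263.897381   0.32 784.75997     1877
   30500 0.03050 238.860163   0.32 784.75997     1877
```

`CLR` is the B score; `n_sites` counts the informative sites inside the
inclusion window at `Â` (sites with `α_Â(d) ≥ 10⁻⁸`). Far from the
footprint the score drops to 0 with NaN sentinels for `x̂`/`Â` — the null
model wins there.

The same workflow is available from the shell:

```sh
balscan build-background chr1.tsv chr2.tsv -o genome.spect
balscan simulate --x0 0.3 --a0 1000 --seed 1 --spect genome.spect -o footprint.tsv
balscan scan footprint.tsv --model B2 --spect genome.spect --test-every 10 -o scan.tsv
balscan filter genotypes.tsv --threshold 1e-4 -o kept.tsv   # HWE het-excess QC
```

## Layout

| module                 | contents                                                   |
|------------------------|------------------------------------------------------------|
| `balscan.sites`        | `SiteRecord` / `SiteTable` containers                      |
| `balscan.sfs`          | background SFS aggregation, normalization, folding         |
| `balscan.mixture`      | linkage weight, balanced components, per-site mixture      |
| `balscan.scan`         | composite likelihoods, grid scan, `BalancingScan` model    |
| `balscan.dynamics`     | equilibrium recursions, synthetic dataset generators       |
| `balscan.hwe`          | exact heterozygote-excess test and site filter             |
| `balscan.io`, `.cli`   | TSV dialects, run logs, `balscan` command-line tool        |

See `docs/methods.md` for the model details, numerical choices and known
limitations.
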