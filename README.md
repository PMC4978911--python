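# driftbarrier

Estimation of insertion-deletion (indel) and base-substitution mutation
rates from mutation-accumulation (MA) experiments, and a comparative test
of the drift-barrier hypothesis: that selection refines replication
fidelity only until the advantage of a further improvement drops below the
power of genetic drift, ~1/N<sub>e</sub>, so the genome-wide deleterious
mutation rate should rise as effective population size falls.

The package is aimed at population geneticists working with MA-line
sequencing or cross-species mutation-rate compilations.  It provides:

- **`ma_synthesis`** — synthetic MA experiments (Poisson mutation accrual
  over `u·n·T`, ~100× per-site read-count configurations, dual aligner
  indel callsets) and neutral-coalescent population samples, all seeded and
  with ground truth retained;
- **`consensus_calling`** — consensus base calling from per-site
  forward/reverse count configurations, across-line shared-variant
  screening, gap-call merging into indel *events*, and dual-callset
  concordance filtering;
- **`rate_estimation`** — u = m/(nT) with SE √(u/(nT)) per line,
  pooled SE s/√N, and generations from transfer logs
  (T = mean log₂ colony cells × transfers);
- **`popgen_diversity`** — Watterson's θ_s = S/(a_n·L), pairwise π_s, and
  N<sub>e</sub> = θ/(2u) (haploids) or θ/(4u) (diploids);
- **`comparative_analysis`** — log₁₀–log₁₀ OLS of the indel burden
  u_id·G_e on N<sub>e</sub>, phylogenetically independent contrasts fitted
  through the origin, and antimutator thresholds from
  s·t·Δu_id·G_e = 1/N<sub>e</sub>;
- a packaged 15-species table (7 bacteria, 8 eukaryotes) and taxonomy
  tree, plus a `driftbarrier` CLI tying the stages into one pipeline.

## Worked example

Recompute every comparative fit from the packaged species table and tree:

```sh
$ driftbarrier reproduce --outdir reproduction
fig1a: slope=-0.730 intercept=2.233 r2=0.899 p=7.74e-08 d.f.=13 within_expected=True
fig1b: slope=-0.874 intercept=3.482 r2=0.875 p=3.15e-07 d.f.=13 within_expected=True
fig3: slope=0.925 intercept=-1.456 r2=0.922 p=1.47e-08 d.f.=13 within_expected=True
unicellular: slope=-0.523 intercept=0.538 r2=0.691 p=0.00287 d.f.=8 within_expected=True
pic: slope=-0.582 r2=0.815 p=4.03e-06 d.f.=13 within_expected=True
u_id/u_bs across species: 5.7% - 46.1%
```

`fig1a` is the regression log₁₀(u_id·G_e) = 2.23 − 0.73·log₁₀N<sub>e</sub>
across all 15 species: a 10-fold increase in effective population size
lowers the per-generation indel burden on the effective genome about
5-fold, with r² = 0.90 — strong support for a drift barrier on indel-rate
evolution.  `fig1b` repeats the fit counting constrained noncoding DNA in
the genome size, `fig3` shows indel and base-substitution rates scale
nearly proportionally (slope 0.92) even though they arise and are repaired
by different pathways, `unicellular` restricts to the 10 unicellular
species, and `pic` is the contrast regression through the origin on the
15-taxon tree (branch lengths 1.0), which removes phylogenetic
non-independence and leaves the relationship intact.  The written
`reproduction/` directory holds the fits, contrasts, per-species
antimutator thresholds, and an N<sub>e</sub>-consistency table.

A full synthetic pipeline — simulate an MA experiment and population
sample, call mutations, estimate rates and diversity — runs with:

```sh
driftbarrier simulate --seed 1 --outdir run1
```

and a library-level parameter-recovery check:

```python
from driftbarrier.cli_io import recovery_experiment
res = recovery_experiment(n_sites=10**6, n_lines=50, T=2000,
                          u_bs=1e-9, u_id=2e-10, seed=1)
print(res["u_bs"].mean_u, res["u_bs"].se_pooled)   # ~1e-9 ± ~1e-10
```

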