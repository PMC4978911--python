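# Methods

## Overview

`driftbarrier` implements the full analysis chain behind a comparative test
of the drift-barrier hypothesis (DBH) for insertion-deletion (indel)
mutation rates: estimating per-site per-generation mutation rates from
mutation-accumulation (MA) line sequencing, converting silent-site diversity
into effective population sizes, and regressing the genome-wide indel burden
against the power of drift, with and without phylogenetic correction.  A
synthetic-data generator reproduces the statistical structure of MA
sequencing and of neutral population samples so that every estimator can be
validated against known ground truth.

## Mutation-rate estimation

For one MA line, the rate of a mutation class is

    u = m / (n T),        SE(u) = sqrt(u / (n T)),

with `m` the number of called mutations, `n` the number of callable
nucleotide sites in that line, and `T` the number of generations elapsed.
The per-line SE is the Poisson standard error of the count.  The pooled
estimate across `N` lines is the **unweighted** mean of the per-line rates
with

    SE_pooled = s / sqrt(N),

`s` being the SD of the per-line rates.  The unweighted mean is kept even
when per-line `n` differs, for fidelity to the SE formula it is paired with;
lines with `n = 0` are dropped with a warning rather than propagating NaN.

The indel rate `u_id` counts *events*: a merged run of contiguous gap calls
of one sign is one event irrespective of its length, because one frameshift
disrupts a coding region regardless of how many base pairs it spans.  Events
longer than 9 bp are classed "large" (the boundary between the "< 10 bp" and
"> 9 bp" phrasings is the same cut; length exactly 10 is large).

Generations are estimated from transfer logs as
`T = mean(log2(viable colony cells)) x number of transfers`, i.e. the log2
of the colony census defines cell divisions per single-colony bottleneck.

## Consensus calling

Sequencing of each line is summarised per site as eight read counts
(forward/reverse for A, C, G, T).  A base is the line's consensus when its
pooled count fraction is >= 0.8 with coverage >= 10 and at least 2 reads on
each strand (defaults; all thresholds configurable).  A substitution is
called for line *i* when its consensus differs from the majority consensus
of the *other* lines; if the line's base ties for the others' majority the
site is ambiguous and nothing is called.  Variants shared by more than
`max_lines_sharing` (default 1) lines are flagged as putative ancestral
polymorphisms or systematic artefacts, written to a diagnostics table, and
excluded from `m` — the across-line frequency screen.  `n` is the number of
sites passing the same thresholds in that line, so every called event lies
on a counted site.

Indels are called only from the intersection of two per-line callsets
emulating independent aligners: per-base gap calls are merged into events,
then events are matched across callsets by kind within a 3-bp positional
slop, with exact length agreement required for short events.  Matching is
greedy by position with each partner used once; for realistically sparse
indel landscapes (spacing >> slop) this equals the optimal matching, which
the tests verify by brute force.

## Synthetic data

The generator's defaults mirror the study design it emulates: ~100x mean
Poisson coverage per site, an even forward/reverse split in expectation,
independent per-read errors (default 1e-3) to a uniformly chosen other
base, and per-line mutation counts drawn as a single Poisson aggregate with
mean `u * n * T` — totals are all the estimators see, and single-organism
bottlenecking makes selection negligible, so per-transfer placement is not
modelled.  Mutation positions are uniform, with overlapping events rejected
and re-drawn.  Signed indel lengths default to 85% short (1-9 bp, truncated
geometric, p = 0.5) and 15% large (10-200 bp, uniform), a stylized stand-in
for the short/large split observed in bacterial MA data (the species-level
length spectra are not published); the distribution is fully configurable.
Aligner callset B jitters event positions by up to 1 bp and either callset
can carry Poisson aligner-specific false gap calls, which the dual-callset
intersection removes.

Features of real data deliberately not modelled: read-level artefacts
(quality scores, mapping ambiguity, paralogy), coverage loss over deleted
intervals (site counts carry the substitution channel only; indels are
observed through the gap callsets), contamination, and backup-plate (4°)
growth — `T` is taken as estimated from the transfer log.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the idealized error model, not robustness to alignment pathology.

Population samples come from a hand-rolled Kingman coalescent:
exponential coalescence times at rate k(k-1)/2, mutations placed on
branches as Poisson with rate `theta * L / 2` per unit coalescent time,
infinite sites (every mutation a new 0/1 column).  The sampler is
cross-checked in the tests against `msprime` and against the analytic
expectations E[S] = theta * L * a_n and E[pi] = theta * L.

## Diversity and effective population size

Watterson's estimator is `theta_s = S / (a_n L)` with
`a_n = sum_{i<n} 1/i`; pi is the average pairwise heterozygosity per site,
`(n/(n-1)) * mean_site 2p(1-p)`.  Under neutrality both estimate the
population mutation rate `2 N_e u` (haploids) or `4 N_e u` (diploids), so
`N_e = diversity / (2 u_bs)` or `/ (4 u_bs)`.  theta_s is preferred over
pi_s when both are available (lower evolutionary sampling variance from
genome-wide segregating-site counts).  Sites with more than two alleles
would be counted once (infinite-sites convention).

The packaged species table stores the published per-species values exactly
as printed (scaled columns) together with group, ploidy, and diversity-type
assignments; the reader resolves them to absolute units.  Ploidy
assignments use the haploid convention for all seven bacteria plus
*C. reinhardtii* and *S. cerevisiae*, and the diploid convention for the
six remaining eukaryotes — the assignments that reproduce the published
N_e values arithmetically.  Because the published N_e values were computed
from unrounded inputs, the consistency check propagates the half-ulp
rounding interval of the printed diversity and u_bs through the conversion
and asks whether the printed N_e (within 2 ulp) is attainable; 12 of 15
species pass.  The *M. musculus* row is not reproducible from its printed
inputs under either ploidy convention; the table flags it, and the check
reports rather than forces it.

## Comparative analysis

The genome-wide indel burden is `u_id * G_e` with `G_e` the effective
(proteome-approximated) genome size, or `u_id * (G_c + G_nc)` when
constrained noncoding sites are included.  All regressions are ordinary
least squares on log10-transformed values (delegated to
`scipy.stats.linregress`; the tests verify equality with the closed-form
normal equations to 1e-10 relative).  Slope p-values are two-sided t-tests
with df = n - 2.  The unicellular subset is the seven bacteria plus the
three unicellular eukaryotes, with burden (`u_id G_e`) as the response —
the same response as the full fit.

Phylogenetic non-independence is removed with Felsenstein's independent
contrasts on log10-transformed traits: at each internal node,
`(x_i - x_j)/sqrt(b_i + b_j)`, with the node value the 1/b-weighted average
and the parent branch extended by `b_i b_j / (b_i + b_j)`.  The contrast
regression is fitted through the origin (df = n - 1), orienting each pair
so the predictor contrast is non-negative; zero predictor contrasts add
nothing to the sums but stay in the df.  The through-origin contrast slope
is algebraically identical to the GLS slope under Brownian covariance,
which the tests confirm on random trees.  The packaged 15-taxon tree
follows standard taxonomy (proteobacteria vs firmicutes/mollicutes among
the bacteria; opisthokonts, plants+green algae, and the ciliate among the
eukaryotes) with every branch length 1.0, and is stored as an editable
newick file — the analysis is a function of whatever tree is supplied.

The antimutator threshold solves `s t delta_u_id G_e = 1/N_e` (haploids;
`1/(2 N_e)` diploids) for `delta_u_id`, the smallest reduction in the indel
rate whose selective advantage still beats drift.  Defaults `s = 0.01`
(mean fitness cost per mutation) and `t = 2` generations of linkage are the
standard literature values and are overridable.  The resulting
`delta_u_id / u_id` fraction falls in the ~0.1-1% band for most species in
the packaged table.

## Numerical and design choices

- Coordinates are 0-based half-open internally; emitted VCF/TSV positions
  are 1-based.  Deletions are left-anchored in VCF, so the simulator never
  places a deletion starting at position 0.  Insertions are written with a
  placeholder `N`-run ALT since the generator tracks lengths, not inserted
  sequence; truth files round-trip exactly.
- Consensus ties (no base reaching the fraction threshold, or a line's base
  tying the others' majority) are no-calls, never arbitrary picks.
- The subsampling stability diagnostic for theta averages a configurable
  number of random subsets per sample size to separate the size effect from
  which-alleles noise.
- All generators take explicit integer seeds and are bit-reproducible; the
  pipeline manifest hash covers tool version, configuration (minus output
  paths), and input checksums only, so identical runs hash identically.
- Problem sizes in the recovery tests (50 lines x 1e6 sites x 2000
  generations at 100x coverage) were chosen as a faithful scaled-down MA
  design whose expected counts (~2 substitutions, ~0.4 indel events per
  line) match the low-count regime the estimators face in practice.

## Known limitations

- The caller has no realignment or local assembly; repeat-induced
  mis-mapping is outside the model, so false-positive behaviour on real
  genomes will be worse than on synthetic data.
- The published u_id/u_bs ratio range (quoted as ~2-12%) is not
  reproducible from the published per-species rate table, whose ratios span
  ~6-46%; the reproduction report prints the computed range and does not
  assert the quoted one.
- The exact published tree topology is not recoverable from the text; the
  packaged taxonomy-based topology reproduces the contrast regression
  within a looser tolerance than the ordinary fits.
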