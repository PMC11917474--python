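# Methods

## The problem

Ribosomal DNA (rDNA) sits in tandem arrays of a repeat unit containing the
18S/5.8S/28S rRNA genes and intergenic spacers (IGS). Unequal crossing-over
between misaligned repeats changes the number of units per array and
redistributes sequence variants within it, so rDNA copy number and
within-individual haplotype composition drift measurably over tens of
generations — fast enough to watch in mutation-accumulation (MA) lines of
*Daphnia pulex* propagated by single-individual bottlenecks. This package
implements the full analysis chain for that design: copy-number estimation
from read depth, per-generation change-rate statistics, pooled-SNP
filtering, haplotype deconvolution with diversity and network summaries,
and a forward simulator that generates all the observables with known
ground truth so every stage can be validated end to end.

## Copy-number estimation

The haploid copy number of an rDNA region is the mean per-base read depth
of that region divided by the mean per-base depth of 16 single-copy exons;
diploid copy number is exactly twice the haploid value. Design choices:

* **Exon pooling.** "Mean depth of the 16 exons" is computed as the
  length-weighted pooled per-base mean (equivalently, the mean over the
  concatenated exon positions). An unweighted mean-of-16-means is offered
  as an option; the pooled form is the default because it is the
  lower-variance estimator. The two differ only when exon lengths differ.
* **Mean, not median/mode.** The ratio uses means; medians and modes are
  reported as diagnostics only. Mode ties break to the smallest value.
* **Dead zones.** Reference intervals where reads systematically fail to
  map (lineage divergence, mappability) depress the regional mean. A
  position is consensus-flagged when its depth falls below 5% of the
  sample's positive-depth median in ≥ 90% of samples; flagged runs of
  ≥ 50 nt are reported as dead zones and masked before summarising, and a
  region more than half masked is flagged for exclusion outright. These
  thresholds are new, reproducible stand-ins for what was a manual call on
  the real data, and are exposed as parameters.
* **Outliers.** 1.5 × IQR whiskers with type-7 (linear-interpolation)
  quartiles, pinned so flags are identical across environments; boundary
  equality counts as inside.
* Region lengths (28S 4,376 nt, 18S 2,292 nt, IGS1 trimmed to 571 nt,
  IGS2 trimmed to 3,123 nt) are configuration, not constants.

The estimator is exactly invariant to global depth rescaling, and on
simulated Poisson depth at 100× exon coverage recovers true haploid copy
numbers of 100–650 with relative bias below 1%.

## Change rates

The change rate over an interval is Δ(diploid copy number)/Δ(generations).
Rates from "generation 0" use the median control copy number as the
progenitor baseline (controls only, per lineage; when several control
groups exist the earliest is the default). Rates between repeated
samplings of the same line are computed for every ordered pair of
samplings and exclude the synthetic baseline. Exact-zero rates are counted
as ties and left out of the direction test; with real-valued estimates
they are measure-zero, but the contract is total. The telescoping identity
rate(t1→t3)·Δ13 = rate(t1→t2)·Δ12 + rate(t2→t3)·Δ23 holds exactly and is
property-tested.

Because copy number performs an approximately unbiased random walk, the
*absolute* change rate measured over an interval of length T scales like
T^(−1/2): short intervals expose large transient changes that longer
intervals average away. The interval-bin summary (~30 vs ~77 vs ~106
generations) quantifies this; the suite checks the short-interval mean
exceeds the long-interval mean in ≥ 45/50 simulation replicates.

## Direction χ²

The increase/decrease direction test is a two-category goodness-of-fit
against 1:1 with **no continuity correction** and df = 1:
χ² = (n⁺−E)²/E + (n⁻−E)²/E, E = (n⁺+n⁻)/2. This arithmetic reproduces the
classic worked examples (17 vs 11 → 1.286; 23 vs 54 → 12.48; 19 vs 20 →
0.026) exactly. Direction counts are sometimes reported alongside
df = n − 1 (27 for 28 comparisons), which is inconsistent with a
two-category goodness-of-fit test whose statistic follows df = 1
arithmetic; df = 1 is reported here.

## SNP filtering

Per (sample, site): nucleotide counts below 5 are set to 0; the total is
recomputed over the four nucleotides; cells with recomputed total below 99
are missing. Both rules are strict (<): a count of exactly 5 and a total
of exactly 99 survive. Filtering is idempotent and never increases a
count. Allele 1 is the reference base; a site is dropped as invariant when
its mean reference frequency across samples *with data* exceeds 0.990
(missing cells have no frequency, so they cannot enter the mean — this is
flagged in the site report). Allele 2 is the non-reference nucleotide with
the largest lineage-wide summed count; sites where a third allele's mean
frequency exceeds 0.01 are flagged multi-allelic and excluded from the
biallelic haplotype encoding. All thresholds are parameters with these
defaults.

## Haplotype deconvolution

Model: F ≈ P·H with H ∈ {0,1}^(K×S) the haplotype/allele-2 indicator
matrix and each row of P ∈ R^(N×K) on the probability simplex. The
objective is the Frobenius residual over observed cells; missing cells are
masked, never imputed. The simplex constraint encodes "haplotype
frequencies within an individual sum to 1"; its cost, documented rather
than fixed, is that minor haplotypes carrying low-frequency variants can
be absorbed into major ones.

Fitting alternates two exact conditional minimisations:

* **P-step.** For each sample, least squares on the simplex. Solved
  exactly by enumerating the 2^K − 1 support sets, solving each
  equality-constrained KKT system, and keeping the feasible solution with
  the lowest residual. The optimum's support yields the global optimum,
  any other feasible support yields a valid upper bound, and singleton
  supports are always feasible, so the enumeration is exact. With no
  missing cells the per-support KKT inverses are shared across samples
  and the step is fully vectorised.
* **H-step.** For each SNP column, exhaustive choice among the 2^K binary
  columns (vectorised across sites).

SSE is non-increasing across iterations; iteration stops at relative SSE
change < 1e-8 or 500 iterations. The first restart seeds P by k-means
clustering of the sample rows (smoothed one-hot memberships); remaining
restarts use Dirichlet draws; the best of 20 restarts is kept. Haplotypes
are reported in decreasing mean frequency with lexicographic tie-break, so
labels are deterministic. Duplicate fitted rows (a sign of overfitted K)
are merged with their frequencies summed. A fitted P with column rank
< K — e.g. compositions constant across samples, where the factorisation
is provably non-unique — is flagged `rank_deficient` rather than silently
returned as one arbitrary solution.

**Choosing K.** K never exceeds floor(log2 S): with S informative
biallelic sites one cannot reliably resolve more components than log2(S)
(25 SNPs → cap 4; 42 SNPs → cap 5). Below the cap, K is chosen by an SSE
elbow: models are fitted for k = 1..cap and the selected K is k−1 for the
first k whose relative SSE improvement falls below 5% (the extra
haplotype no longer pays for itself). The tolerance is exposed as a
parameter.

**Diversity and network.** Expected heterozygosity He = 1 − Σ pᵢ² per
sample (bounded by 1 − 1/K); the He-vs-copy-number OLS reports both plain
and adjusted R², since a positive slope is the signature of copy-number
gains preferentially expanding minor haplotypes. Pairwise haplotype
distances are Hamming counts. The haplotype network is a
minimum-spanning network — the union of all minimum spanning trees,
computed by tie-aware group-wise Kruskal and verified against brute-force
spanning-tree enumeration. At K ≤ 5 this is topology-equivalent to a
statistical-parsimony (TCS-style) network; the 95% parsimony connection
limit is deliberately not implemented.

## Statistical battery

All location comparisons flow through one gated procedure: optional
square-root transform → Shapiro–Wilk on pooled within-group residuals
(per-group option available; the pooled default is the conventional
residual-normality check) → ANOVA if the gate passes (Tukey HSD after a
significant ANOVA), Kruskal–Wallis otherwise. Sample exclusions (IQR
outliers or named samples) are an explicit, logged pre-step — never
silent. The gate α is 0.05 and configurable. Shapiro/ANOVA/Tukey/Kruskal
and OLS come from scipy/statsmodels; the contribution here is the gate
logic, the transform and exclusion audit trail, and the direction χ².
Type-I calibration of the t and direction tests under the simulator's
null is asserted at 5% ± 3 points over 500 meta-replicates.

## The simulator

What it emulates:

* **Arrays.** Two haploid arrays per diploid individual, each an ordered
  list of repeat units carrying one of K haplotypes, initialised as
  clustered blocks (the progenitor layout inferred for real arrays).
* **Events.** Each generation, each array independently experiences at
  most one unequal-crossover event with probability ρ. A gain duplicates
  a contiguous block of m units in place (tandem duplication — preserves
  clustering); a loss deletes min(m, n−1) contiguous units (an array
  never empties). m ~ geometric(p = 0.1), gains with probability
  `direction_bias` (0.5 = unbiased). Events are modelled per generation,
  not per unit-pair: this matches the "few major events" picture of rDNA
  turnover and keeps ρ interpretable.
* **Depth.** Per-base exon depth ~ Poisson(d) (negative binomial when
  overdispersion > 0, var = μ + αμ²); rDNA depth has mean d × diploid
  copy number / 2; configured dead-zone intervals are forced to 0.
* **Allele counts.** At each SNP site the true allele-2 frequency is the
  exact fraction of units carrying it; reads are multinomial with
  allele-2 probability f(1−ε) + (1−f)ε/3 and the remaining error mass on
  the two off-target bases; site depth scales with the sample's copy
  number by default (SNP sites sit inside the array).

Default study conditions mirror the cyclically parthenogenetic lineage:
K = 4 haplotypes, S = 25 SNPs, progenitor haploid copy number 190
(diploid 380), ~100 generations, 100× exon depth, ε = 0.001. ρ = 0.2 per
array per generation was fixed once on realism grounds: with geometric
mean event size 10 it yields absolute change rates of order 1 copy per
generation on a ~190-unit haploid array — the observed magnitude in MA
lines — and a few tens of events per ~100 generations.

A vectorised copy-number-only path (`simulate_cn_trajectories`)
implements the same marginal event law without unit tracking, for the
replicate-heavy calibration and interval analyses; its distributional
agreement with the unit-level simulator is unit-tested.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: GC and mappability bias beyond hard dead
zones, inter-chromosomal exchange between the two arrays (real data
cannot distinguish intra- from inter-array recombination; only
intra-array events are modelled), IGS subrepeat structure, selection,
sexual reproduction, treatment-dependent event rates (expressible via
per-treatment ρ overrides, but no effect size is assumed), and
read-level artefacts (no FASTQ simulation).

## Problem sizes and numerical conventions

The bundled analysis runs at the study's own scale (35 samples, 25 SNPs,
14 × 3 trajectory samplings); recovery and calibration suites use 20–500
replicates of the vectorised path, keeping the full test suite under half
a minute on one CPU. Quartiles are type-7 everywhere; TSV is the only
interchange format, with 1-based inclusive coordinates and fixed float
formatting so write→read→write round-trips are byte-identical; all
randomness derives from one seed through named per-stage BLAKE2 streams
(every derived seed < 2³¹).

## Known limitations

* The deconvolution is exact per conditional step but the joint problem
  is combinatorial; multi-restart alternating minimisation can in
  principle land in local optima. Recovery tests bound this empirically
  (exact H recovery with P RMSE < 0.02 in ≥ 18/20 seeds at the study
  scale) rather than theoretically.
* The elbow rule for K is a heuristic; with very unequal haplotype
  frequencies the smallest components may fall below the fit's
  resolution and be absorbed — the known cost of the sum-to-1 contract.
* Dead-zone auto-detection assumes ≥ 2 samples and a shared reference;
  single-sample datasets must supply masks explicitly.
* The direction χ² is asymptotic; at very small counts an exact binomial
  test would be preferable, but the χ² form is retained for continuity
  with the worked examples it reproduces.
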