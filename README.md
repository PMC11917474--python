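# rdnavar

Copy-number and haplotype dynamics of ribosomal DNA (rDNA) in
mutation-accumulation (MA) lines, as a tested analysis pipeline plus a
forward simulator of tandem arrays evolving by unequal crossing-over.

rDNA sits in tandem arrays of repeat units (18S/5.8S/28S genes plus
intergenic spacers). Unequal crossing-over between misaligned repeats
changes the unit count and redistributes sequence haplotypes within the
array, so in clonally propagated *Daphnia pulex* MA lines both copy
number and within-individual haplotype composition drift measurably over
tens of generations. This package is for researchers analysing that kind
of data — per-base depth tables and per-site nucleotide counts from
short-read alignments — and for anyone who wants a ground-truthed
simulator of the whole observation process.

The core quantities:

* **Haploid copy number** of an rDNA region = mean per-base read depth of
  the region ÷ length-weighted mean depth of 16 single-copy exons;
  diploid copy number = 2 × haploid.
* **Change rate** over an interval = Δ(diploid copy number) / Δ(generations),
  from a control-median progenitor baseline or between repeated samplings
  of a line; direction counts are tested against 1:1 with
  χ² = (n⁺−E)²/E + (n⁻−E)²/E, E = (n⁺+n⁻)/2, df = 1, no continuity
  correction.
* **SNP retention**: per (sample, site), nucleotide counts < 5 are zeroed
  and the total recomputed; cells with total < 99 are missing; sites with
  mean reference-allele frequency > 0.990 across samples are dropped.
* **Haplotype deconvolution**: F ≈ P·H with binary haplotypes H (K × S)
  and per-sample simplex frequencies P (N × K), fitted by exact
  alternating steps (simplex least squares per sample; exhaustive binary
  choice per site) from multiple restarts, with K capped at
  floor(log₂ S). Diversity is He = 1 − Σ pᵢ²; haplotype relations are
  summarised by Hamming distances and a minimum-spanning network.

See `docs/methods.md` for the model, assumptions, defaults, and limits.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
data (fixed seed; outputs under `results/`):

```sh
python analysis/01_simulate.py      # datasets + ground truth
python analysis/02_copy_number.py   # depth-ratio estimates, outliers, regressions
python analysis/03_change_rates.py  # baseline + interval change rates
python analysis/04_haplotypes.py    # SNP filtering, deconvolution, He, network
python analysis/05_stats.py         # gated treatment statistics
```

Selected output:

```
28S diploid copy number: range 109-519, mean 367.5
median relative error vs simulated truth: 0.087%
28S ~ 18S: slope 1.000, R^2 1.0000, P 3.36e-104
signed rate vs 0: t = -1.27, P = 0.213 (16 increases, 18 decreases, 1 ties)
direction 1:1 chi-square = 0.118, P = 0.732, df = 1
  short~30 : n = 14, mean |rate| = 0.98, var = 0.88
  long~106 : n = 14, mean |rate| = 0.73, var = 0.18
25 of 25 sites retained (0 invariant, 0 multi-allelic)
selected K = 4 haplotypes (cap floor(log2 25)); fit SSE = 0.0081
haplotype matrix recovered exactly: True
He mean 0.714; He ~ diploid 28S CN: slope 1.77e-04, adj R^2 0.178, P 0.007
```

Reading this: exon-normalised depth ratios recover the simulated diploid
copy numbers to a tenth of a percent, and the two rRNA genes — which
share one array — regress on each other with unit slope. Signed change
rates from the control-median baseline are statistically indistinguishable
from zero (the drift is unbiased), increases and decreases are balanced,
and the ~30-generation sampling interval shows a larger mean absolute
rate than the ~106-generation interval: long intervals average away
transient changes. All 25 simulated SNP sites pass the count filters, the
log₂ cap admits 4 haplotypes, and the deconvolution recovers the true
binary haplotype matrix exactly with frequencies at the sampling-noise
floor. The positive He-vs-copy-number slope reflects gains expanding
minor haplotypes in this realisation.

The same stages are available as a CLI (`rdnavar simulate|copynumber|
rates|variants|haplotypes|stats|run --seed 3 --out rundir`) and as plain
library calls.

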