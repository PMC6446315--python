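# Methods

`popscan` implements a windowed population-genomics scan pipeline for
multi-sample diploid variant calls: diversity and differentiation
statistics, selective-sweep region calling, frequency-based ABBA-BABA
introgression tests, isochore GC segmentation, an allele-frequency-
differential screen, and LD decay.  Every stage is validated on synthetic
cohorts with known truth; this note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Coordinate and data conventions

Variant sites are 1-based (VCF `POS`); windows, regions, segments and BED
output are 0-based half-open.  Genotypes are stored as alternate-allele
dosages 0/1/2 with an explicit missing value; all frequency statistics use
the per-site count of non-missing chromosomes.  Multi-allelic records are
dropped by default (optionally split into one biallelic site per alternate
allele), and sites whose missing fraction exceeds 0.2 are dropped on input
(configurable; the threshold is a pragmatic default, not an estimate).
SNPs and indels travel in one matrix with a per-site class flag because the
isochore stage counts both.

## Windowed diversity statistics

Per-site diversity is the unbiased pairwise heterozygosity
`2 p q n/(n-1)` with `n` the local non-missing chromosome count; window
θπ is the sum over sites (also reported per bp).  Tajima's D uses the
standard `a1..e2` constants with `S` = segregating sites in the window and
the window's **median** `n` for the constants (configurable to a harmonic
rule); the paper-silent alternative of per-site constants changes third
decimals at realistic missingness.  Windows below the SNP threshold
(default 20, after the windowing rule the pipeline adopts) and truncated
terminal windows are flagged and excluded from downstream quantiles.
Window-size selection tiles the genome non-overlappingly at each candidate
size, scores the proportion of windows with ≥ 20 SNPs, and breaks ties
toward the smaller size to retain resolution for short sweeps.

## Weir–Cockerham FST, zFST and the sweep caller

Per-site variance components a (among populations), b (among individuals
within populations) and c (within individuals) follow the two-population
Weir–Cockerham estimator on genotype counts, with per-site sample sizes and
heterozygote proportions from non-missing genotypes.  Window FST is the
**ratio of sums** `Σa / Σ(a+b+c)` over polymorphic sites — standard
practice, stable at low diversity — and negative per-site components are
retained unclamped so sums stay unbiased.  zFST standardizes window FST
over autosomal windows with the n−1 standard deviation; a constant vector
is a hard error.

The sweep caller flags windows that sit simultaneously in the top tail
(default 5%) of window FST and of `log2(πreference/πtarget)`, then merges
flagged windows that overlap or abut into regions.  Two choices deserve
note:

* **Quantile rule.** The threshold is the smallest order statistic with at
  most `(1-q)·n` values at or above it (index `ceil(q·n)` of the sorted
  vector).  This is the "higher" empirical quantile shifted by one rank,
  chosen so the flagged fraction per criterion provably never exceeds
  `1-q`; the conventional `ceil(q·(n-1))` index can flag one window too
  many.
* **SNP gate placement.** The ≥ 20-SNP eligibility gate is evaluated on the
  cross-population polymorphic-site count of the FST table, not on
  per-population segregating sites: a hard-swept window is nearly
  monomorphic in the target population, and a per-population gate would
  silently discard exactly the windows the scan exists to find.  π is
  therefore computed ungated for the ratio; windows whose target π is
  exactly zero carry a missing ratio with a reason code (an ε pseudo-floor
  is available but off by default).

The absolute Tajima's D difference between target and reference is attached
to regions as annotation only — it is not a calling criterion.  A
Mann-Whitney U contrast of in-region windows against the genome-wide
background is provided as a sanity report; by construction of the outlier
cut it is essentially always significant when regions exist.  Gene
annotation joins intervals overlapping a region by ≥ 1 bp under the
half-open convention, and a tally counts in how many population scans each
gene recurs.

## ABBA-BABA D-statistic

Sites are polarized against an outgroup that must be fixed at the site
among its non-missing chromosomes; the derived allele is the one absent
from the outgroup, and outgroup-polymorphic or outgroup-missing sites are
dropped with counts reported.  With derived-allele frequencies `p1, p2, p3`
in three populations,

    D = Σ[(1-p1) p2 p3 - p1 (1-p2) p3] / Σ[(1-p1) p2 p3 + p1 (1-p2) p3].

The outgroup enters only through polarization; its frequency does not
appear in the sums.  Because the estimator carries no analytic variance, a
delete-one block jackknife over contiguous genomic blocks (default 1 Mb)
supplies a standard error and Z score — an addition documented as such.
Fewer than 5 non-empty blocks flags the SE unreliable.  Under the
no-introgression null the jackknife Z is slightly heavy-tailed at ~20
blocks (it is a t-like statistic), which the calibration test accommodates
by rate rather than by distribution.

IBD tract tables (BEAGLE-style TSV) are consumed, never inferred; summaries
report per-population-pair counts, total and mean lengths, and a
configurable per-pair or per-recipient-sample normalization.

## Isochore segmentation

The reference is tiled with fixed windows, each classified by GC over
non-N bases into the five canonical families with left-closed bounds
L1 < 0.37 ≤ L2 < 0.41 ≤ H1 < 0.46 ≤ H2 < 0.53 ≤ H3 (overridable);
windows ≥ 50% N become unclassified gap segments.  Consecutive same-family
windows merge into segments whose GC is the base-weighted mean, so segments
tile each contig exactly.  This transparent classify-and-merge segmenter is
validated on constructed references; it is deliberately simpler than
dynamic-programming segmenters and is the package's own methodological
choice.

Window-size selection for GC computes, per candidate size, the SD of
per-window GC over windows inside runs of ≥ 4 same-family windows, and
picks the smallest size whose relative SD decrease to the next size falls
below 5%.  On a homogeneous reference the SD keeps shrinking as `1/√w`
(pure binomial sampling), no plateau emerges, and the largest candidate is
returned — the plateau rule is only informative when real between-segment
GC structure dominates.

Variant–GC correlation counts SNPs and indels per classified segment and
reports Pearson r and p between segment GC and density per Mb, plus the
per-family share of variants.

## Allele-frequency-differential screen

A site is a hit when the alternate-allele frequency is > 0.8 in one group
and < 0.2 in the other (strict inequalities on non-missing chromosomes)
and Pearson's chi-squared on the 2×2 **allele-count** table (no continuity
correction by default) gives p < 0.001.  Benjamini–Hochberg q-values over
the frequency-passing candidates are reported alongside, but the raw-p
filter is the decision rule.  Consequence classes are joined from an
external annotation table; unmatched hits are labeled, not dropped.

## LD decay

For phased haplotypes, `r² = (p_AB − p_A p_B)² / (p_A q_A p_B q_B)` from
haplotype counts; for unphased dosages the squared Pearson correlation of
dosages is the documented surrogate, flagged in output metadata.  Pairs are
restricted to the same contig within 40 kb, sites below MAF 0.05 are
excluded (paper-silent stabilizer), and the decay curve averages r² in
distance bins, leaving empty bins missing rather than zero.

## The synthetic-data generator

The generator emulates the structure of a multi-breed resequencing cohort,
not its genetics:

* **Sites.** Placed uniformly at ~2 per kb (binomial in the contig
  length).  An optional "Z" contig scales site density by 0.5 to emulate
  the lower diversity of a sex chromosome.
* **Frequencies.** Ancestral frequencies follow a neutral ~1/i spectrum
  over a notional panel of 500 haplotypes (large relative to any sample, so
  the sample spectrum is not truncated near its singleton classes) or a
  Uniform(0.05, 0.95) mode.  Population frequencies are Balding–Nichols,
  `Beta(p(1-F)/F, (1-p)(1-F)/F)`, whose expected Weir–Cockerham FST equals
  the divergence parameter F — giving closed-form parameter-recovery tests
  without coalescent machinery.
* **Haplotypes.** Independent Bernoulli draws by default, or mosaics of K
  founder haplotypes with a per-bp switch rate ρ (Markov founder switching
  between adjacent sites) when LD structure is wanted.
* **Sweeps.** Each segregating site inside the target interval is driven to
  its current major allele on every target haplotype with the given
  fixation probability (ties to the ancestral allele) — the scan consumes
  only the resulting diversity/differentiation pattern, so no forward
  simulation is needed.
* **Introgression.** A fraction f of recipient haplotypes become carriers;
  a carrier is tiled with exponential-length tracts (mean 50 kb), each
  copied from an independently drawn donor haplotype.  A coverage
  parameter < 1 interleaves resident gaps for partial-ancestry carriers;
  the default is full coverage, so f is the donor-ancestry proportion of
  the recipient population.
* **Reference.** GC-block plans draw i.i.d. bases at per-block GC
  probabilities, giving constructed references whose segmentation truth is
  known exactly.

Everything is driven by one mandatory seed through a single
`numpy.random.Generator`; identical configurations are bit-identical.

What the generator does **not** emulate: realistic chicken demography,
recombination hotspots, selection dynamics, sequencing error,
reference-bias or call-rate artifacts, and linked selection.  Passing
tests therefore demonstrate that the estimators recover the signals they
are defined to measure under their own model assumptions — not that those
assumptions hold in any particular empirical cohort.

## Validation scenarios and problem sizes

The validation suite and `scripts/acceptance.py` use desk-scale scenarios
chosen to make each effect measurable with comfortable margins: FST
recovery on 2 × 50 diploids over 10 Mb (~20 000 sites, 20 replicates);
Tajima's D neutrality on a single low-drift population (F = 0.005 — the
neutral condition is minimal divergence) pooled over ≥ 200 windows; sweep
recovery of a 200-kb interval at fixation probability 0.9 (20 replicates);
D-statistic calibration on 40 null and 20 introgressed (f = 0.3)
replicates over 2 × 10 Mb with 1-Mb jackknife blocks; AFD null screens on
20 + 20 diploids; LD decay pooled over 20 mosaic replicates (K = 8,
ρ = 1e-6/bp).  Reruns under a fixed seed are byte-identical end to end.

## Known limitations

* The Balding–Nichols model has no linkage between drift at nearby sites;
  windowed FST noise is therefore milder than in coalescent data, and the
  sweep-recovery rates measured here are upper bounds on power.
* The unphased r² surrogate (dosage correlation) approaches haplotype r²
  only under Hardy–Weinberg proportions.
* The isochore segmenter's boundary precision is one window by
  construction; it does not attempt sub-window boundary refinement.
* The block-jackknife SE needs tens of non-empty blocks to be trustworthy;
  with few contigs and short genomes the Z statistic is anti-conservative.
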