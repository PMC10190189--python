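# Methods

`gbsmedip` implements a two-stage differential-methylation analysis for
GBS-MeDIP libraries — reduced-representation methylomes built by digesting
genomic DNA with PstI, barcoding fragments per sample, enriching the pool
for methylated DNA with an anti-methyl-cytosine antibody, and paired-end
sequencing — together with a truth-tracking simulator that makes the whole
chain testable at desk scale.

## Library model and simulator

**Genome.** Background bases are i.i.d. at a configurable GC fraction
(default 0.42, a mammalian-like value). CpG islands are planted as
intervals whose sequence emits a `CG` dinucleotide with probability 0.6
per step, giving an island CpG density >= 5x background; islands cover
~2% of the genome by default. Because a specific 6-mer occurs once per
~4 kb of random sequence, a few-megabase genome would yield too few
size-selectable fragments; the generator therefore plants PstI sites
(`CTGCAG`) with uniform random spacing, default 150-900 bp, so that
roughly 40% of fragments fall in the 200-500 bp selection window and a
3-4 Mb genome carries 2,000-3,000 selected fragments — enough regions for
calibration studies while keeping runs in seconds.

**Digestion.** Cuts are placed at every exact forward-strand occurrence of
the recognition site, at offset 5 (immediately after the `CTGCA` remnant).
This is coordinate bookkeeping only: the 3'-overhang chemistry of PstI is
not modelled, because the only downstream consequence that matters is that
a valid read 1 begins `barcode + CTGCA` followed by fragment sequence.
Fragments are the intervals between consecutive cuts plus chromosome ends;
`selected` marks lengths within [200, 500] bp.

**Methylome.** Each group's methylome is a per-CpG Bernoulli probability:
`island_meth` inside islands, `baseline_meth` elsewhere. Differential
regions are planted by shifting all CpG probabilities of one group by
+-delta on randomly chosen selected fragments with >= 3 CpGs (the shift
direction is drawn among the feasible signs; infeasible deltas raise).

**Capture.** A molecule carrying `m` methylated CpGs is captured with
probability `(1 - eps) * m / (m + kappa) + eps` — a saturating law with
half-saturation `kappa` (default 1 methylated CpG) and background capture
`eps` (default 0.01). The law is monotone in `m` and plateaus, the
qualitative MeDIP behaviour. With `kappa = 1` the curve saturates by ~3
methylated CpGs, so the default methylation levels (baseline 0.1, islands
0.7) should be read as *capture-scale effective levels* chosen so that a
delta = 0.5 shift moves a typical 10-20-CpG fragment across the dynamic
range of the antibody model; they are not literal mammalian methylome
fractions (real mammalian genomes are ~75% methylated, but an antibody
with such a low half-saturation would see almost no contrast there).

**Sampling and reads.** Per-sample depth is Poisson around
`mean_fragments_per_sample`; molecules are multinomial over selected
fragments with weights equal to the capture law evaluated at the
fragment's *expected* methylated-CpG count under its group's methylome
(PCR is not modelled beyond the stacked-read phenomenon). Read 1 is
`barcode + CTGCA + fragment 5' sequence` on a uniformly chosen strand,
read 2 the reverse complement of the fragment 3' end, both 100 bp with
constant "I" qualities; substitution errors are optional, indels are not
modelled. Every pair carries a truth alignment; gzip members are written
with a zeroed mtime so identical seeds give identical bytes.

## Stage 1 — stack filter, peak calling, counting

**Stacked reads.** PCR duplicates appear as reads stacked on one
(chromosome, start, strand) position. With `lambda_pos` the mean reads
per occupied position, the threshold `n_star` is the smallest stack whose
Poisson upper tail is below `p_stack = 0.001`; each position keeps at most
`max(1, n_star - 1)` reads. The `max(1, .)` guard matters in the sparse
limit: `n_star = 1` means any duplicate is excess, and a literal
`n_star - 1` cap would discard singletons as well. In the count-based
pipeline path the same rule acts as a per-fragment multiplicity cap
(restriction fragments are identical intervals by construction, so
stacking is the norm, `lambda_pos` is large, and the cap only trims
extreme multiplicities).

**ROI calling.** The merged fragment pools of the two groups are scanned
with 300 bp windows at 100 bp steps (matching the 200-500 bp fragment
scale; both configurable), in both directions (each group once as
"treatment"). A window must beat two nulls:

* the scaled control count — tested with the exact conditional binomial,
  `P(X >= x_t | x_t + x_c, N_t / (N_t + N_c))`, the standard calibrated
  comparison of two Poisson counts;
* a global background floor `N_t * window_bp / genome_bp` — tested with
  the Poisson upper tail.

The window p-value is the larger of the two. An alternative
`method="rate"` scores windows as `P(X >= x_t | max(x_c * N_t/N_c,
floor))`, i.e. treats the scaled control count as a known rate. That
variant is anticonservative — the control count carries its own sampling
noise, inflating null z-scores by ~sqrt(2) — and, because stage 2 re-tests
stage-1-selected windows on the same data, the selection bias propagates
into an unacceptable false-discovery proportion among final DMR calls.
The conditional default restores calibration; with a planted effect and
adequate depth it loses little power. Window p-values are BH-adjusted per
direction; windows at q <= 0.1 from either direction are merged
(overlapping or book-ended windows joined) into ROIs that carry their best
window p, with q recomputed across merged ROIs. `control=None` enables
single-pool peak calling against the floor alone. Calling is symmetric
under group swap by construction.

**Counting.** A sample's count for an ROI is the number of its (filtered)
fragments overlapping the ROI by >= 1 bp (half-open intervals; a
book-ended touch does not count). Library sizes are per-sample totals
after stack filtering. For calibration studies with no planted signal the
tested regions are the selected fragments themselves rather than called
peaks — under a global null a correct differential peak caller returns
(almost) nothing, and the fragment universe is the natural region set of
a reduced-representation library.

## CpG coupling, calibration, rms, enrichment score

The coupling value of a region is its CpG count. Per sample, regions are
binned by integer coupling, and an unweighted ordinary-least-squares line
is fitted through the per-bin mean counts from bin 0 up to the bin with
the maximum mean (coverage rises with CpG density and then saturates or
falls; the linear model is only meaningful on the ascending part; if the
curve is flat or descending the fit uses all bins). Relative methylation
scores are `rms = x / max(a + b*c, a + b)` — the floor at coupling 1
prevents blow-up for CpG-free regions. rms is a descriptive layer only;
the differential test operates on raw counts with size factors, because
the statistics come from a count model.

The CpG enrichment score is a relH-style density ratio: CpGs per bp under
the union of covered intervals, divided by CpGs per bp genome-wide.
Uniformly placed coverage scores ~1; methylation-biased capture scores
above 1, increasing with the methylation contrast of CpG-dense territory.

## Stage 2 — exact conditional NB test

Counts are normalized with DESeq-style median-of-ratios size factors
(total-count ratios as fallback when fewer than 10 regions have positive
geometric means), scaled to geometric mean 1. Dispersion is estimated per
region by method of moments on normalized counts after replacing group
means by the grand mean: `phi_hat = max(0, (s^2 - mu) / mu^2)`; the
common dispersion is a 20% trimmed mean of the per-region estimates, and
each region's working value shrinks its raw estimate toward the common one
with prior weight `n0 = 10` against the residual degrees of freedom.

Regions with total contrast count below `minRowSum = 10` are dropped
before testing and before BH. For a tested region with total `T`, the
split of `T` between the groups under equal adjusted means follows a
beta-binomial with shape parameters `S_1/phi` and `S_2/phi`, where `S_g`
sums the group's size factors — the conditional distribution of two
negative-binomial group sums with a shared dispersion, reducing to a
binomial with success probability `S_1/(S_1+S_2)` at `phi = 0`. The
two-sided p-value sums the probabilities of all splits no more probable
than the observed one (ties included within a 1e-8 relative tolerance).
The enumeration is O(T) with vectorized log-gamma terms and is exact at
any realistic total, so no large-sample approximation is used. Two
significance tiers are assigned independently: exploratory at p <= 0.05
and top at BH q <= 0.6. The hypermethylated group is the one with the
larger normalized mean, reported as a direction label (`E>B` style), and
`log2FC = log2((m1 + 0.5)/(m2 + 0.5))` on normalized group means.

## Annotation

DMRs are classified by their midpoint (an explicit convention; start- or
edge-anchoring would be equally defensible) against strand-aware features
with precedence Promoter > 5'UTR > 3'UTR > Exon > Intron > Downstream >
Distal Intergenic. The promoter is the 3 kb upstream of the TSS,
sub-binned at 1 kb; the downstream region is the 300 bp after the TTS.
UTR classes apply only when gene models carry UTR intervals (the simulator
does not emit them). Overlapping genes resolve by precedence, then smaller
|TSS distance|, then lexicographic gene id. Intergenic DMRs take the
nearest gene by |TSS distance|. Signed distances run along the gene's
strand (negative = upstream of the TSS) and are summarized into
leading-digit x power-of-ten magnitude bins ("-2 Kbps", "+20 Kbps", ...).

## Overlaps and over-representation

Venn cells across DMR sets are counted on connected components of the
region-overlap graph (>= 1 shared bp, half-open), one count per component
under its set-membership signature. Pairwise overlap significance uses a
permutation null (default N = 100) that relocates one set's regions
uniformly at random within a placement universe, chromosome-matched and
length-preserving; the `(1 + exceed)/(N + 1)` estimator avoids zero
p-values. The universe defaults to the ROI universe of the contrasts
involved (the sequenced fraction), with the whole genome available as an
alternative. Gene-level overlaps between contrasts are exact set
intersections on annotated gene ids — no permutation.

Over-representation per gene set is the upper-tail hypergeometric
probability of the hit count, BH-adjusted across sets, reported at
FDR <= 0.1. The background universe is the set of genes carrying at least
one tested region, which counters the ascertainment bias of a
reduced-representation library; it is configurable.

## Problem sizes and what the tests show

The packaged calibration runs use 2-3 chromosomes of 1-1.2 Mb (~1,500-
3,000 selected fragments), 9 vs 9 samples, and 20,000-100,000 molecules
per sample — sizes chosen so every study completes in seconds while
leaving >= 2,000 tested regions for null-calibration checks and >= 30 mean
counts per region for recovery checks. Under these conditions the null
fraction of regions at p <= 0.05 is 0.033-0.041 (mildly conservative: the
exact test is discrete and the shrunk dispersion slightly over-covers
Poisson truth), planted-DMR sensitivity through the full two-stage path
is 0.8-1.0 with false-discovery proportions below 0.2, and the null peak
caller emits essentially no ROIs.

The simulator emulates fragment-scale capture bias, group structure,
library-size variation, and PCR stacking. It does not emulate alignment
error, mappability and repeat structure, copy-number variation,
GC-dependent PCR efficiency, or biological between-sample variability
beyond the count model (counts are conditionally Poisson given the
methylome, so dispersion estimates on simulated data hover near zero).
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated generative model, not performance
on real libraries with those additional artifacts.

## Numerical choices

* Exact-test ties: splits within 1e-8 relative probability of the
  observed one count as ties (both the implementation and the test
  oracles use the same rule).
* BH is the plain step-up procedure (statsmodels `fdr_bh`), clipped to 1.
* Stack-threshold search iterates the Poisson survival function from 1
  (thresholds are small integers in practice).
* Degenerate calibration inputs: a single coupling bin raises; a flat or
  descending bin-mean curve fits all bins.
* All randomness flows from one seed through `numpy` `SeedSequence`
  spawning; file outputs are byte-deterministic (sorted writers, pinned
  gzip mtime, sorted JSON keys).
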