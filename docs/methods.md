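# Methods

`cnvpipe` re-implements, as a tested library, a consensus calling
procedure for paired-tissue CGH+SNP microarray data: two independent
aberration detectors run on each hybridization's log2-ratio channel,
their agreement defines high-confidence CNV calls, paired tissues of one
patient are intersected, and copy-neutral LOH is called from the SNP
genotype channel. A synthetic cohort generator with exact ground truth
makes every stage testable without array data, and a small qPCR module
implements the efficiency-corrected copy-number arithmetic used to
validate array calls.

## Signal model and the synthetic generator

A CGH probe reports the log2 ratio of test vs diploid reference DNA. A
clonal event of `c` copies shifts the expected ratio to `log2(c/2)`; an
event carried by a cell fraction `f` (mosaicism) shifts it to
`log2((f*c + (1-f)*2)/2)`, which is strictly monotone in `f` for fixed
`c != 2`. A homozygous deletion (`c = 0`) is floored at −4 rather than
−infinity so the noiseless limit stays finite. Probe noise is i.i.d.
Gaussian with default sd 0.2 per probe — arrays of this class are
commonly quoted at a derivative-level sd of 0.15–0.25, and 0.2 is the
middle of that band; it is a simulation choice, not a measured value.

The SNP channel is a per-probe genotype call in {AA, AB, BB, NC}.
Baseline heterozygosity is 30% per probe; inside copy-neutral LOH events
(and inside clonal hemizygous/homozygous losses) probes are forced
homozygous; a symmetric genotype error (default 0.5%) then corrupts
calls. Two modelling simplifications matter for interpreting results:

* **Each hybridization's genotype channel is an independent draw.**
  There is no fixed per-patient germline genome shared across tissues;
  heterozygosity is treated as sampling noise. Consequently a *chance*
  run of homozygosity in one tissue almost never replicates in the
  paired tissue, and the paired intersection suppresses chance runs
  essentially completely. With a fixed shared germline genome, chance
  runs would replicate in both tissues and at desk-scale SNP spacing
  (~170 kb; 25 consecutive probes span >4 Mb, past the 1.5 Mb filter)
  the false-call rate would be set by single-channel run statistics
  (~0.5/patient), not by the pairing. Passing false-positive tests here
  therefore demonstrates the machinery, not immunity to real
  autozygosity, which on real arrays is instead controlled by the much
  denser SNP grid (25 probes ≈ 0.6 Mb, below the span filter).
* **No B-allele-frequency channel and no partial (mosaic) LOH**: cn-LOH
  detection rests purely on homozygosity runs of hard genotype calls.

The default desk-scale design is a 22-chromosome toy genome (200 Mb
down to 40 Mb linearly, ~2.6 Gb total) carrying 40,000 CGH and 15,000
SNP probes — about one tenth of the 292K/120K density of the emulated
two-channel 400K design — with probes placed uniformly at random without
replacement (vendor designs are gene-centric and irregular; a regular
grid is available). Probe budgets are apportioned to chromosomes by
length with largest-remainder rounding.

### Default cohort composition

The default cohort mirrors the emulated study layout: 10 patients, three
samples each (diseased coronary artery wall CAP, internal mammary artery
IMA, blood), 30–45 germline CNVs per patient drawn from a shared pool of
80 loci (which produces cross-patient recurrence), no somatic events
(the study design's negative result for artery-specific changes), and
eight cn-LOH regions distributed 3/3/1/1 over four patients.

Event amplitudes are dictated by the pipeline's own stated thresholds.
The segmentation arm calls only segments with |mean log2| ≥ 1.0, i.e.
at least as extreme as a homozygous deletion (log2 = −4 floored) or a
4-copy duplication (log2 = 1.0, exactly at the cutoff and therefore a
coin flip under noise). Single-copy changes (×3 gain at +0.585, ×1 loss
at −1.0) cannot robustly clear that cutoff even though the
interval-score arm (0.25 cutoff) finds them easily — the two arms'
thresholds are deliberately asymmetric in the procedure being
re-implemented, and we implement both as stated rather than reconciling
them. The default cohort therefore injects **losses as homozygous
deletions (copies 0, 62% of loci) and gains as 5-copy amplifications
(38%)**, amplitudes the consensus chain can recover; the loss fraction
matches the emulated cohort's 62%. Single-copy and mosaic events remain
fully supported by the generator and are exercised in unit tests, where
their attenuation (e.g. a 0.4-fraction ×3 mosaic at log2 ≈ 0.263) is
asserted against the closed form. CNV loci span 0.6–2.5 Mb (log-uniform;
≥ ~7 CGH probes at default density) and cn-LOH loci 8–12 Mb, large
enough to hold ≥ 25 SNP probes at desk-scale spacing — on the emulated
real design the same 25-probe rule corresponds to ~0.6 Mb.

qPCR plates are simulated directly from the Ct model: a sample with `c`
copies sits `log_E(c/2)` cycles below the 2-copy calibrator on the
target assay while the reference assay is copy-independent, so the
efficiency-corrected ratio recovers `c/2` exactly in the noiseless
limit. Zero-copy samples report a no-amplification Ct of 40.

## Segmentation arm (CBS)

Circular binary segmentation in its basic mean-shift form. For a
segment of n probes the candidate statistic of the arc of k probes
starting after probe i is

    Z(i, k) = |S(i+k) − S(i) − k·mean| / sqrt(k (n − k) / n),

the two-sample t numerator with the segment-wide variance held fixed
(the constant factor cancels in the permutation comparison). The arc
statistic equals its circular complement's, so maximising over linear
intervals covers all circular arcs. A candidate split is accepted when
its permutation p-value is below `alpha` (default 0.01, 1,000
permutations — the re-implemented procedure says only "default
settings", and these give stable decisions at desk scale); the accepted
arc's two boundaries split the segment into up to three pieces which are
re-tested recursively. No rank transform, no segment-undo, no smoothing.

Numerical choices:

* Segments of ≤ 256 probes score every arc length; longer segments use a
  geometric grid of lengths (ratio 1.29) *for observed and permuted
  values alike*, so the permutation test remains an exact test of the
  gridded statistic. Split locations are always refined by exhaustive
  maximisation once a split is accepted; ties go to the smallest (i, j).
* Permutations run in blocks with early stopping that only triggers once
  the p-value provably exceeds `alpha` — decisions are identical to the
  full draw. Each segment's permutation stream is seeded by (seed,
  chromosome, segment bounds), making decisions independent of recursion
  order and of `alpha`, which yields the monotonicity property that
  lowering `alpha` never adds segments.
* Degenerate inputs: segments under 4 probes and constant segments are
  never tested; non-finite log2 values are rejected up front.

Calls require segment mean ≥ +1.0 (gain) or ≤ −1.0 (loss), at least 3
probes, and |median|/MAD ≥ 2, where the MAD is unscaled (no 1.4826
factor — the filter is a unitless ratio, but users comparing against
scaled variants should divide their threshold accordingly). The mean is
thresholded while the median/MAD is filtered because the re-implemented
procedure states both statistics in those roles.

## Interval-score arm (ADM analog)

The vendor's aberration method is proprietary; the documented stand-in
scores a probe interval I as `S(I) = |Σ v_i/σ_i| / sqrt(|I|)` (per-probe
errors σ_i, or a global robust estimate `1.4826·median(|Δv|)/sqrt(2)`
from first differences). Extraction is greedy: the best-scoring interval
(exhaustive O(n²) search per chromosome, exact at desk scale) is
emitted if it reaches the score threshold (default 6.0, the vendor's
shipped default), its probes are removed, and both flanks are
re-searched. Reported intervals then face the stated filters: |mean
log2| ≥ 0.25, ≥ 3 probes, span ≥ 1 kb — applied to the final reported
interval. The score is invariant under sign flips and under common
rescaling of values and errors.

## Consensus and paired-tissue logic

High-confidence = detected by both arms in the same sample: same
chromosome, same state, ≥ 1 bp overlap (the procedure does not quantify
this overlap; reciprocal stringency is reserved for truth matching and
recurrence, where it is configurable at 50%). Transitively overlapping
groups collapse to one call spanning the group's outer boundaries
("envelope" semantics), with probe-weighted mean log2 and a copy
estimate `round(2·2^mean)` that is reported but never filtered on. The
same rule intersects the two tissues of a patient (tissues become the
union); tissue-specific calls are those with no same-state overlap in
the partner tissue — an overlapping opposite-state call does not cancel.
Consensus runs per sample first, then tissues are intersected (the
order is a documented choice; the converse is not implemented).

## cn-LOH

ROH scanning reports maximal runs of consecutive SNP probes whose
heterozygote fraction is ≤ 1% with ≥ 25 probes (both package defaults;
only the 1.5 Mb span rule below is inherited from the re-implemented
procedure), built by growing pure homozygous runs across single
heterozygous probes while the tolerance holds, so endpoints are always
homozygous. Runs overlapping between the two tissues are intersected —
boundaries are the intersection, unlike the CNV envelope, because
homozygosity must hold in both samples — and kept if they span strictly
more than 1,500,000 bp (a run of exactly 1.5 Mb is rejected) and
overlap no CNV call of the same patient.

## Annotation and summaries

Interval length is end − start + 1 (1-based inclusive everywhere;
BED conversion happens only at I/O). Novelty vs a population-CNV
database follows the strict "more than 50%" rule on the fraction *of the
call* covered (the asymmetric reading; a reciprocal mode exists behind a
flag): best overlap exactly 0.5 is still novel. Recurrence matches calls
across patients at ≥ 50% reciprocal overlap with equal state and counts
distinct patients per transitive locus. Cohort summaries report call
counts per patient, size statistics, loss fraction, recurrence and genic
fraction. Gene-set enrichment is the upper-tail hypergeometric test
P(X ≥ k) with BH-FDR correction across sets; both are delegated to
scipy/statsmodels and are checked against enumeration oracles in the
test suite.

## qPCR quantification

Standard-curve efficiency is `E = 10^(−1/slope)` (warning outside
1.6–2.1, not an error). The efficiency-corrected ratio is
`E_t^ΔCt_t / E_r^ΔCt_r` with ΔCt = mean calibrator Ct − mean sample Ct,
replicates averaged on the Ct scale (linear-scale averaging behind a
flag); no outlier rejection is applied. Ratios classify as < 0.6 loss,
0.8–1.2 inclusive two copies, > 1.4 gain; the gaps [0.6, 0.8) and
(1.2, 1.4] are reported as `indeterminate` — a package convention, as
the re-implemented procedure leaves them unstated.

## Reproducibility and problem sizes

One global seed fans out to per-sample child seeds via
`seed·1000003 + patient_idx·131 + tissue_idx (mod 2^31)`; CBS permutation
streams derive from (child seed, chromosome, segment bounds). Identical
config and seed give byte-identical outputs.

The shipped validation uses: the default 10-patient cohort (~40k CGH +
15k SNP probes) for end-to-end recovery; 200 seeded 100-probe pure-noise
chromosomes for split-rate calibration; 200 simulated patient pairs at
default SNP density for the cn-LOH false-call rate; 100-seed simulations
for breakpoint accuracy; and brute-force oracles on instances of ≤ 30
probes (CBS), ≤ 200 probes (interval scores) and N ≤ 12 (hypergeometric
enumeration). These sizes were chosen so the whole suite runs in minutes
on a laptop while keeping every probe-count-dependent filter active.

## Known limitations

* The two arms' call thresholds (±1.0 vs 0.25) are implemented as
  stated; their tension means single-copy events cannot reach
  high-confidence status, which is visible in the default cohort design
  (see above) and should be kept in mind when applying the pipeline to
  real data.
* No GC-wave/dye-bias simulation; the pipeline consumes already
  normalized log2 ratios (only optional median-centering).
* ROH-based cn-LOH cannot see mosaic LOH and, given the independent
  genotype-draw model, the false-positive tests do not probe real
  germline autozygosity (see the generator section).
* The full published CBS refinements (hybrid p-values, pruning, undo)
  are out of scope; the basic algorithm plus permutation test is
  implemented.
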