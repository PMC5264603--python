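# cnvpipe

Consensus CNV and copy-neutral-LOH calling for paired-tissue CGH+SNP
microarray data, with the qPCR copy-number validation arithmetic used to
confirm array calls, and a synthetic cohort generator with exact ground
truth.

## What problem this addresses

Somatic structural variation in diseased tissue is usually sought by
comparing a target tissue against a matched control from the same
person — for example an atherosclerotic coronary artery wall (CAP)
against the patient's intact internal mammary artery (IMA), with blood
as a third compartment. On a combined CGH+SNP array each hybridization
yields a per-probe log2 test/reference intensity ratio (copy number) and
a genotype call channel (homozygosity). `cnvpipe` implements the
analysis chain from normalized log2 ratios onward, for analysts who want
that chain as a reusable, tested library rather than two GUI tools:

* **Two detection arms per sample.** An interval-score detector
  (`cnvpipe.adm`) finds maximal intervals with score
  `S(I) = |Σ v_i/σ_i|/√|I|` ≥ 6 and applies the filters
  |mean log2| ≥ 0.25, ≥ 3 probes, span ≥ 1 kb. Circular binary
  segmentation (`cnvpipe.cbs`) recursively splits each chromosome at the
  maximal arc statistic, accepts splits by permutation test, and calls
  segments with mean log2 beyond ±1.0, ≥ 3 probes and |median|/MAD ≥ 2.
* **Consensus and pairing** (`cnvpipe.consensus`): a call is
  *high-confidence* if both arms detected it (same state, ≥ 1 bp
  overlap), merged to outer boundaries; the two tissues of a patient are
  intersected the same way, and tissue-specific calls are reported
  separately.
* **cn-LOH** (`cnvpipe.cnloh`): runs of homozygosity (≥ 25 SNP probes,
  het fraction ≤ 1%) present in both tissues, intersected, spanning
  > 1.5 Mb, and overlapping no CNV call.
* **Annotation and statistics** (`cnvpipe.annotate`): novelty against a
  population-CNV database (novel unless covered > 50%), gene overlap,
  cross-patient recurrence at 50% reciprocal overlap, cohort summaries,
  hypergeometric gene-set enrichment with BH-FDR.
* **qPCR validation** (`cnvpipe.qpcr`): standard-curve efficiencies
  `E = 10^(−1/slope)`, the efficiency-corrected ratio
  `E_t^ΔCt_t / E_r^ΔCt_r` against a 2-copy calibrator with an
  RNaseP-style reference locus, and the categorical bands
  < 0.6 loss / 0.8–1.2 two copies / > 1.4 gain.
* **Synthetic cohorts** (`cnvpipe.synthetic`): seeded, bit-reproducible
  paired-tissue cohorts with injected gains, losses, cn-LOH runs and
  optional mosaic fractions; a clonal event of `c` copies sits at
  `log2(c/2)`, a mosaic one at `log2((f·c+(1−f)·2)/2)`.

See `docs/methods.md` for the model details, parameter defaults and
known limitations.

## Worked example

```python
from cnvpipe import (EventSpec, PatientSpec, GenomeSpec, NoiseSpec,
                     simulate_cohort, run_pipeline, PipelineParams)

genome = GenomeSpec((("chr1", 30_000_000), ("chr2", 30_000_000)), 2000, 800)
patients = [PatientSpec("p1", germline_events=(
    EventSpec("chr1", 4_000_000, 6_000_000, "loss", 0),      # homozygous deletion
    EventSpec("chr2", 10_000_000, 11_500_000, "gain", 5),    # amplification
    EventSpec("chr2", 18_000_000, 24_000_000, "cnloh", 2),   # copy-neutral LOH
))]
cohort = simulate_cohort(patients, genome, NoiseSpec(log2_sd=0.2, seed=7))
report = run_pipeline(cohort, PipelineParams(seed=7))

for c in report.patients[0].shared:
    print(c.interval.chrom, c.interval.start, c.interval.end,
          c.state, c.copies, round(c.mean_log2, 3), sorted(c.provenance))
for c in report.patients[0].cnloh:
    print(c.interval.chrom, c.interval.start, c.interval.end, c.n_snp, "hmz")
print(report.truth_metrics)
```

prints

```
chr1 4009765 5987433 loss 0 -3.993 ['ADM', 'CBS']
chr2 10037762 11482929 gain 5 1.347 ['ADM', 'CBS']
chr2 17818886 23926241 70 hmz
{'cnv_recall': 1.0, 'cnv_precision': 1.0, 'cnv_n_truth': 2, 'cnv_n_called': 2,
 'cnloh_recall': 1.0, 'cnloh_precision': 1.0, 'cnloh_n_truth': 1, 'cnloh_n_called': 1}
```

Both injected CNVs come back as high-confidence calls shared by CAP and
IMA, with boundaries at the outermost probes inside each event (the
homozygous deletion at its −4 floor, the 5-copy gain near
log2(5/2) ≈ 1.32) and integer copy estimates `round(2·2^mean)`; the
6 Mb homozygous region survives the > 1.5 Mb span filter and the
CNV-overlap exclusion, so it is reported as copy-neutral LOH covering 70
SNP probes.

Calls round-trip through the ISCN array nomenclature used in published
tables, and the qPCR module reproduces the validation arithmetic:

```python
from cnvpipe import parse_iscn, interval_length, pfaffl_ratio, classify_copy
from cnvpipe.qpcr import QpcrAssay

rec = parse_iscn("arr[hg19]10q24.31(101911972-101944947)x3")
interval_length(rec.interval)   # 32976
assay = QpcrAssay("s", target_ct=[27.35, 27.42, 27.38], ref_ct=[27.0, 27.1, 26.9],
                  calibrator_target_ct=[28.0, 28.05, 27.95],
                  calibrator_ref_ct=[27.0, 27.05, 26.95],
                  E_target=1.93, E_ref=2.0)
ratio = pfaffl_ratio(assay)     # 1.5
classify_copy(ratio)            # 'gain'
```

There is also a CLI (`cnvpipe simulate|segment-cbs|segment-adm|consensus|
pair|cnloh|qpcr|run`) operating on tab-separated probe tables, BED files
and YAML configs; `cnvpipe run --seed 1 --out-dir out/` executes the
whole chain on the default simulated cohort and writes per-patient BEDs
plus a JSON manifest of parameters and per-stage counts.

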