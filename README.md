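# amplicall

Variant screening on long nanopore amplicons: an end-to-end, tested
pipeline for detecting somatic SNVs and indels in a single multi-kilobase
PCR product (the motivating case is a ~7 kb *TP53* amplicon spanning exons
2–11) sequenced on an error-prone long-read platform, multiplexed across
patients with PCR barcodes.

Early nanopore 2D reads carry ~15 errors per 100 aligned bases, biased
toward 1–2 nt deletions — far above the allele fractions of interest in
tumor samples. The package implements the screening strategy that makes
calling tractable anyway:

1. **simulate** — generate barcoded noisy amplicon reads with spiked
   variants at set allele fractions (the stand-in for unavailable raw runs);
2. **demux** — assign reads to samples by barcode prefix (edit-distance
   matching), unassignable reads binned;
3. **align** — banded affine-gap *glocal* alignment of each read to the
   amplicon (query end-to-end, reference free ends); external BWA-MEM
   alignments can be injected as SAM instead;
4. **correct** — pileup-consensus error correction that repairs alleles
   below a 10% protection threshold and never touches anything above it;
5. **qc** — read-length summaries, per-class error rates per 100 aligned
   bases, per-position coverage;
6. **call** — Varscan-style thresholds (depth ≥ 50; ≥ 10 supporting reads
   for SNVs, ≥ 13 for indels; VAF ≥ 0.01; one-sided Fisher exact p ≤ 0.05
   against an error-only null), with adjacent co-occurring SNVs merged into
   MNVs and VCF output;
7. **annotate** — plus-strand genomic HGVS (`g.7577144A>G` dialect),
   protein consequences on a minus-strand gene model (`p.Leu265Pro`),
   IARC-style table lookup;
8. **filter** — the false-positive cascade: drop intronic non-splice and
   silent changes, drop calls below the Sanger validation limit (15% SNV /
   20% indel), and drop variants recurring across samples (systematic
   artifacts). Rejected calls are kept with their reasons.

## The statistics at the core

At a pileup column with depth *d*, an alternate allele with *a* supporting
reads is tested against an idealized error-only column at per-base error
rate *e*: one-sided Fisher exact test on
`[[a, r], [round(d·e), round(d·(1−e))]]` where *r* counts reference-allele
reads; *e* defaults to 0.15 for raw reads and 0.05 after correction.
Reported allele fraction follows the Varscan convention
`VAF = reads2 / (reads1 + reads2)`, which stays nearly unbiased when
superimposed errors thin both alleles' support.

Correction is frequency-gated consensus: at columns with depth ≥ 20, a read
base / insertion / deletion whose column frequency is below `protect_frac`
= 0.10 is replaced by (or removed in favor of) the column consensus;
anything at ≥ 10% is untouched, so a 16% variant survives while the 4–7%
random error floor is erased.

## Worked example

Simulate one sample of 200 full-length reads from a 7-kb synthetic
amplicon with a 35% SNV spiked at offset 2500 and a 45% 1-nt deletion at
offset 5200, then align, correct, and call on the raw branch:

```python
from amplicall.fixtures import synthetic_amplicon
from amplicall.simulate import SimConfig, SampleSpec, SpikeVariant, simulate_sample
from amplicall.align import align_reads
from amplicall.pileup import build_pileup
from amplicall.correct import correct_reads, CorrectionParams
from amplicall.call import CallerConfig, call_variants
from amplicall.qc import assess_errors

ref = synthetic_amplicon(7000, seed=11)
spikes = [SpikeVariant(2500, ref.sequence[2500], "T", 0.35),
          SpikeVariant(5200, ref.sequence[5200], "", 0.45)]
cfg = SimConfig(samples=[SampleSpec("CLL_A", "", spikes)], n_reads=200,
                full_length_fraction=1.0, seed=1)
reads = simulate_sample(ref, cfg, "CLL_A")
alns, _ = align_reads([(r.read_id, r.sequence) for r in reads], ref,
                      band=256, sample_id="CLL_A")
print(f"raw error rate:       {assess_errors(alns, ref).total_per100:.2f} per 100 aligned bases")
corrected = correct_reads(alns, build_pileup(alns, ref), CorrectionParams())
print(f"corrected error rate: {assess_errors(corrected, ref).total_per100:.2f} per 100 aligned bases")
for c in call_variants(build_pileup(alns, ref), CallerConfig(baseline_error=0.15), ref, "CLL_A"):
    print(f"{c.var_class}  g.{c.genomic_pos}  {c.ref_allele}>{c.alt_allele}  "
          f"vaf={c.vaf:.3f}  p={c.p_value:.2e}")
```

prints

```
raw error rate:       13.92 per 100 aligned bases
corrected error rate: 0.75 per 100 aligned bases
SNV  g.1002501  G>T  vaf=0.343  p=1.03e-05
DEL  g.1004557  CT>C  vaf=0.220  p=4.91e-02
DEL  g.1005198  CG>C  vaf=0.419  p=5.49e-09
```

Both spikes are recovered close to their simulated fractions (0.343 vs
0.35; 0.419 vs 0.45). The third row is a borderline noise deletion that
single-sample calling cannot exclude — exactly the class of artifact the
recurrence filter removes once several samples are screened together, since
the same systematic deletion recurs in each of them.

## Command line

The `amplicall` command exposes the full workflow (`run`) and each stage
separately (`simulate`, `demux`, `align`, `correct`, `qc`, `call`,
`annotate`, `filter`), all driven by one YAML config; every stage reads and
writes standard files (FASTQ, SAM, VCF, TSV) so externally produced
alignments or call sets can be injected mid-pipeline. `amplicall run`
writes, per branch (`raw`, `corrected`): SAM, error/coverage TSVs, VCF,
annotated TSV, a final screening report plus rejected-variants table, and a
run manifest with per-stage read counts. See `tests/test_pipeline.py` for a
complete config example; the gene model TSV has columns
`exon_number, start, end, strand, cds_start, cds_end` (1-based inclusive
genomic coordinates; strand and CDS bounds constant across rows).

## Caveats

The recurrence filter assumes the same true mutation is unlikely to occur
in multiple samples of one run; for strong hotspot mutations this
assumption can misfire, which is why rejected variants are always written
out with their reasons rather than discarded. See `docs/methods.md` for the
model, parameter rationale, and known limitations.
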