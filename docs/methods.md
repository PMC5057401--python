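# Methods

## Problem setting

A single long PCR amplicon (model case: ~7 kb covering all coding exons of
a tumor-suppressor gene on the minus strand) is sequenced on a high-error
long-read platform, with up to 12 samples multiplexed per run via PCR
barcodes. Somatic variants of interest sit at allele fractions of roughly
15–60%. The raw per-read error rate (~15 errors per 100 aligned bases,
deletion-biased, indel events of 1–2 nt) exceeds those fractions, so naive
calling is dominated by noise. The pipeline combines frequency-gated
consensus correction, threshold-plus-Fisher calling, and orthogonal
filters (effect class, Sanger-validatable fraction, cross-sample
recurrence) to keep sensitivity at screening fractions while suppressing
systematic artifacts.

All internal coordinates are 0-based half-open on the amplicon; everything
reported is 1-based plus-strand genomic HGVS, bridged by the amplicon's
genomic anchor.

## Synthetic data generator

No raw runs are distributable, so the generator is a first-class module
that defines the study conditions for every test:

* **Error profile** (defaults): substitutions 0.05/base, insertions
  0.03/base, deletions 0.07/base — 0.15 total with the deletion bias —
  with geometric event lengths of mean 1.5 nt. The per-class split is a
  calibrated choice: only the 15% total, the deletion dominance and the
  1–2 nt event size are externally characterized quantities.
* **Read lengths**: a read is full-length with probability 0.6, otherwise
  a uniformly placed fragment of ≥ 150 nt — a dominant full-length peak
  plus a tail of break products. Tests that need uniform depth set the
  full-length fraction to 1.
* **Haplotypes**: each read carries each spiked variant independently with
  probability equal to its VAF, so the realized carrier fraction is
  binomial around the nominal value; truth labels per read are emitted for
  the test harness.
* **Barcodes**: 12 bundled 24-mers with pairwise edit distance ≥ 8. The
  barcode prefix is prepended *intact* (errors corrupt only the
  amplicon-derived bases): sample assignment is treated as a controlled
  design variable, not a modeled error process. Demultiplexer tolerance to
  barcode damage is exercised directly in unit tests instead.
* **Determinism**: one RNG stream per (run seed, sample id), derived by
  hashing, so per-sample output is independent of sample ordering.
* **Qualities** are uniform placeholders; no stage consumes them.

What the generator does *not* emulate: signal-level artifacts, context-
dependent (e.g. homopolymer-conditioned) error rates beyond what alignment
induces, chimeras, strand asymmetries, quality-score correlation. Passing
tests therefore demonstrate the pipeline's behavior under idealized
independent-error noise at the stated rates, not performance on any
particular real flowcell.

## Alignment

Reads are placed by a banded three-state (Gotoh) affine-gap dynamic
program in glocal mode: the query aligns end-to-end, reference overhang is
free. Defaults: match +2, mismatch −3, gap open −5, gap extend −2; band
half-width 256 for 7-kb reads. Because deletion-biased errors make a read
systematically shorter than its reference span, the band is centered on a
guide line interpolated between the approximate start and end of the read
on the reference (found by an edit-distance infix scan); the band then
only has to absorb local random-walk excursions (standard deviation ~40 nt
over 7 kb at default rates). If the band never reaches the final row, the
read is realigned unbanded. Ties prefer M over D over I, making CIGARs
deterministic. Reads under 30 nt are rejected; alignments under 60%
identity are dropped and counted. Property tests assert equality with an
independent full-matrix DP on pairs up to 300 bp.

An important, quantified property of optimal alignment at 15% error: when
a random insertion lands within ~4 nt of a true deletion, explaining both
as substitutions scores better than two gaps, so ~15–25% of deletion
carriers at a locus lose their gap to mismatches (context-dependent).
Downstream choices compensate (see calling).

## Pileup, correction

The pileup tallies per-column A/C/G/T counts and deleted reads
(depth = bases + deletions), insertion events keyed by (preceding column,
inserted sequence), deletion events as whole per-read runs, and supporting
read indices for non-reference observations.

Correction (defaults: `protect_frac` 0.10, `min_depth_correct` 20)
replaces any read observation whose column frequency is below the
protection threshold with the column consensus (base substitution,
insertion removal, deletion fill-in); nothing at ≥ 10% is modified, and
columns shallower than 20 reads are left alone. 0.10 sits below the 15%/20%
reporting limits — no reportable variant can be erased — and above the
raw per-allele noise floor (~2–7%). Decisions are made against the pileup
of the *input* alignments, which yields exact idempotence: surviving
alleles keep their exact column frequencies (deletion fill-ins convert
del-counts into base counts without changing depth), so a second pass
changes nothing. Consensus ties break to highest count, then reference
base, then alphabetical. On default simulations the raw ~14–15 per 100
drops below 1 per 100; residual errors are concentrated at columns where
alignment has collapsed homopolymer deletions above the protection
threshold.

## Variant calling

Per the Varscan parameterization: column depth ≥ 50; supporting reads ≥ 10
(SNV) / ≥ 13 (indel); VAF ≥ 0.01; one-sided Fisher exact p ≤ 0.05 for
enrichment of the alternate allele over an idealized error-only column at
`baseline_error` (0.15 raw branch, 0.05 corrected branch). The exact
2×2 construction is `[[alt, ref], [round(d·e), round(d·(1−e))]]`.

Two measurement conventions matter at high error rates and are deliberate:

* **VAF = reads2/(reads1+reads2)** (Varscan's frequency), not
  alt/column-depth. Errors superimposed on carrier reads remove ~15% of a
  variant's support; they thin reference support nearly equally, so the
  ratio recovers the true fraction almost unbiasedly on raw reads, while
  alt/depth is attenuated by ~0.85×. (After correction the denominator is
  restored to near-full depth but masked carrier deletions are not
  recoverable, so corrected-branch deletion fractions read ~0.08 low at
  default error rates; raw-branch values are the more faithful frequency
  estimates, mirroring the practice of reporting raw-read frequencies
  alongside corrected calls.)
* **Deletion support is covering-based**: a candidate run is supported by
  every read whose deleted run covers it, so a carrier deletion fused with
  an adjacent random deletion still counts. Candidates whose
  left-normalized alleles coincide are merged, keeping the best-supported.

Adjacent called SNVs are merged into an MNV when ≥ 80% of each side's
supporting reads are shared; the merged call keeps the shared-read count
and the more conservative (larger) member p-value. Indels are emitted
VCF-anchored and left-normalized. VCF 4.2 is written with per-sample
DP/AD/AF/PVAL fields; the reader recomputes VAF from AD/DP so round trips
are exact.

## Annotation and filters

Effects are classified on the transcript model: intronic positions within
2 nt of an exon boundary (the canonical splice dinucleotides) are
`splice`; other intronic — and exonic non-CDS (UTR) — positions are
non-affecting (`intronic`). Coding SNVs are classified codon-locally
(alleles complemented onto the coding strand for minus-strand genes);
MNVs and indels by full mutated-CDS translation, giving `silent`,
`missense`, `nonsense`, `frameshift` (with `fs*K` stop offsets) or
`inframe_indel`. Genomic descriptions use the compact screening dialect
(`g.7577121_7577122GC>TT`); the strict `delins` form is kept in a parallel
field. Protein descriptions use three-letter codes; stops are `*`.

The filter cascade flags, per candidate: `EFFECT_EXCLUDED` (intronic
non-splice, silent), `BELOW_SANGER_LIMIT` (VAF < 0.15 for SNV/MNV, < 0.20
for indels — the practical validation limits of Sanger electropherograms),
`RECURRENT` (identical genomic description called in more than one sample
of the batch). Recurrence is counted over *called candidates* before the
other filters, which is what makes it effective: systematic artifacts
(e.g. homopolymer deletion collapse) are called in every sample and are
therefore removed everywhere, regardless of their fraction. The final
report contains exactly the unflagged rows; rejected rows are written with
reasons, because the recurrence assumption is probabilistic and can
misfire on genuine hotspot mutations. Filtering is idempotent and
independent of sample order.

## Numerical and design notes

* Fisher p-values come from `scipy.stats.fisher_exact`; tests pin them to
  exact rational hypergeometric tail sums at 1e-12.
* The DP kernel is numba-compiled; scores are integers, so banded/unbanded
  equality is exact.
* The toy fixture gene (~1.5 kb, three exons, 200-codon minus-strand CDS
  with UTR stubs) is generated deterministically at run time; effect
  classification is tested exhaustively against an independent
  full-CDS-translation oracle over all coding positions × 3 alternate
  bases.
* Test and acceptance problem sizes are chosen so that binomial noise sits
  well inside the asserted tolerances: error-rate checks use 200 × 7-kb
  reads; variant-recovery checks use 20 seeded runs at depth 1000 on a
  1-kb amplicon, comparing called VAF to the realized per-run carrier
  fraction (the generator's binomial sampling around nominal VAF is
  asserted separately via exact binomial confidence bounds); the
  filter-semantics check uses 6 samples × 600 reads on the toy gene.
* Degenerate inputs: empty read sets yield zeroed/null summaries, not
  errors; deletions touching the amplicon edge are anchored on the
  following base; unassignable barcode matches (none, or more than one
  within tolerance) go to the unassigned bin.

## Known limitations

* Single amplicon, single transcript model; no multi-gene or genome-scale
  mapping, no chimera detection, no base-quality modeling.
* Consensus correction cannot restore carrier support already lost at
  alignment (deletion/insertion cancellation), which is why corrected-
  branch indel fractions read low; a realignment pass after correction
  would not recover it either, since the read sequence itself is noisy.
* The error-only Fisher null ignores context-dependent error structure;
  at raw error rates, alleles below ~20% are near the decision boundary
  and their call status is seed-dependent — by design they are handled by
  the downstream filters rather than the caller.
* The recurrence filter needs several samples per batch to be effective
  and removes true hotspot mutations shared across patients; inspect the
  rejected-variants table in such settings.
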