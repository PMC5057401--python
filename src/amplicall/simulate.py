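"""Synthetic barcoded nanopore-like 2D amplicon reads.

The generator emulates the read regime of a multiplexed MinION amplicon run:
every read is a (possibly fragmented) copy of a single long amplicon with a
sample barcode prepended, corrupted by substitution/insertion/deletion noise
totalling ~15 errors per 100 bases by default, with a deletion bias and
geometric 1–2 nt indel event lengths. Spiked variants at fixed allelic
fractions stand in for true somatic mutations; each read carries each spike
independently with probability equal to its VAF, so the simulated VAF at a
locus is binomial around the nominal value.

No base-quality model is simulated (no downstream stage consumes qualities);
FASTQ qualities are a uniform placeholder.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .refmodel import AmpliconRef

#: Default barcodes (24-mers, pairwise edit distance >= 8), in the spirit of
#: the ONT BC01-BC12 amplicon barcoding set.
DEFAULT_BARCODES = [
    "AGCTTGTTGGCCAGCAAGCACACC",  # BC01
    "GGACAGTCCCTGCGCCGTACACAT",  # BC02
    "GGTGTTTGACTCGCTACGTGACCC",  # BC03
    "ACCTGTCAAGGGGTTAGTCCAATT",  # BC04
    "ACACGTCGCCACTCTCCGCCAAAA",  # BC05
    "CCACAATGCATGCAATAAGAACAC",  # BC06
    "AATAACAGAGCCTGAGAAGCTAGG",  # BC07
    "GGCTCAACTAAGTTGCAGATTCCA",  # BC08
    "TTGGTTATACCACAGTTGAGCCTG",  # BC09
    "TGGGGTGCGGAGTCTTAGTCAGCG",  # BC10
    "TTGCTCCAGACAAAGGGTCTTCCG",  # BC11
    "GAATGTCCAGGCAAGCGAAAGACA",  # BC12
]


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error probabilities with geometric indel event lengths.

    Defaults total 0.15 errors per aligned base with a deletion bias
    (sub 0.05 + ins 0.03 + del 0.07) and mean indel event length 1.5 nt,
    i.e. the raw 2D-read regime of early MinION amplicon data. The exact
    per-class split is a calibrated choice, not a measured constant.
    """

    sub_rate: float = 0.05
    ins_rate: float = 0.03
    del_rate: float = 0.07
    indel_len_mean: float = 1.5

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 0.5:
                raise ValidationError("error rates must lie in [0, 0.5)")
        if self.indel_len_mean < 1:
            raise ValidationError("indel_len_mean must be >= 1")

    @property
    def ins_event_rate(self) -> float:
        return self.ins_rate / self.indel_len_mean

    @property
    def del_event_rate(self) -> float:
        return self.del_rate / self.indel_len_mean


@dataclass(frozen=True)
class SpikeVariant:
    """A variant injected into a fraction ``vaf`` of a sample's reads.

    ``alt_allele`` empty means a pure deletion of ``ref_allele``;
    ``ref_allele`` empty means a pure insertion before ``amplicon_offset``.
    """

    amplicon_offset: int
    ref_allele: str
    alt_allele: str
    vaf: float

    def __post_init__(self):
        if not 0 < self.vaf <= 1:
            raise ValidationError("vaf must lie in (0, 1]")

    def key(self) -> str:
        return f"{self.amplicon_offset}:{self.ref_allele or '-'}>{self.alt_allele or '-'}"


@dataclass
class SampleSpec:
    sample_id: str
    barcode: str
    variants: list[SpikeVariant] = field(default_factory=list)


@dataclass
class SimConfig:
    """Study conditions for one simulated multiplexed run."""

    samples: list[SampleSpec]
    n_reads: int = 200
    error: ErrorProfile = field(default_factory=ErrorProfile)
    full_length_fraction: float = 0.6
    fragment_min_len: int = 150
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.full_length_fraction <= 1:
            raise ValidationError("full_length_fraction must lie in [0, 1]")
        bcs = [s.barcode for s in self.samples]
        if len(set(s.sample_id for s in self.samples)) != len(self.samples):
            raise ValidationError("sample ids must be distinct")
        nonempty = [b for b in bcs if b]
        if len(set(nonempty)) != len(nonempty):
            raise ValidationError("barcodes must be pairwise distinct")
        for i, a in enumerate(nonempty):
            for b in nonempty[i + 1:]:
                d = edlib.align(a, b, task="distance")["editDistance"]
                if d < 3:
                    raise ValidationError(
                        f"barcodes {a!r} and {b!r} have edit distance {d} < 3"
                    )

    def sample(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise ValidationError(f"unknown sample {sample_id!r}")


@dataclass
class SimRead:
    read_id: str
    sequence: str
    sample_id: str
    carries: dict[str, bool]  # spike key -> carried on this read's haplotype
    true_start: int  # haplotype coordinate of fragment start
    true_len: int


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """One independent stream per (run seed, sample id), order-insensitive."""
    digest = hashlib.sha256(f"{seed}:{sample_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def _apply_spikes(ref_seq: str, variants: list[SpikeVariant], carried: list[bool]) -> str:
    seq = ref_seq
    for var, take in sorted(zip(variants, carried), key=lambda t: -t[0].amplicon_offset):
        if not take:
            continue
        o = var.amplicon_offset
        if seq[o:o + len(var.ref_allele)] != var.ref_allele:
            raise ValidationError(
                f"spike ref allele {var.ref_allele!r} does not match reference at offset {o}"
            )
        seq = seq[:o] + var.alt_allele + seq[o + len(var.ref_allele):]
    return seq


def _validate_spikes(ref: AmpliconRef, variants: list[SpikeVariant]) -> None:
    seen = set()
    for v in variants:
        o = v.amplicon_offset
        if o in seen:
            raise ValidationError(f"multiple spike variants at offset {o}")
        seen.add(o)
        if ref.sequence[o:o + len(v.ref_allele)] != v.ref_allele:
            raise ValidationError(
                f"spike ref allele {v.ref_allele!r} does not match reference "
                f"{ref.sequence[o:o + len(v.ref_allele)]!r} at offset {o}"
            )


def _corrupt(template: np.ndarray, error: ErrorProfile, rng: np.random.Generator) -> np.ndarray:
    """Apply substitutions then indel events to an encoded template."""
    n = len(template)
    out = template.copy()
    if error.sub_rate > 0:
        hit = rng.random(n) < error.sub_rate
        # substitute to one of the three other bases, uniformly
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4

    keep = np.ones(n, dtype=bool)
    if error.del_event_rate > 0:
        starts = np.flatnonzero(rng.random(n) < error.del_event_rate)
        if len(starts):
            lens = rng.geometric(1.0 / error.indel_len_mean, size=len(starts))
            for s, ln in zip(starts, lens):
                keep[s:s + ln] = False

    ins_anchors: list[tuple[int, np.ndarray]] = []
    if error.ins_event_rate > 0:
        starts = np.flatnonzero(rng.random(n) < error.ins_event_rate)
        if len(starts):
            lens = rng.geometric(1.0 / error.indel_len_mean, size=len(starts))
            for s, ln in zip(starts, lens):
                ins_anchors.append((s, rng.integers(0, 4, size=ln).astype(np.uint8)))

    pieces: list[np.ndarray] = []
    prev = 0
    for s, ins in ins_anchors:
        pieces.append(out[prev:s][keep[prev:s]])
        pieces.append(ins)
        prev = s
    pieces.append(out[prev:][keep[prev:]])
    return np.concatenate(pieces) if len(pieces) > 1 else pieces[0]


_ENC = {b: i for i, b in enumerate("ACGT")}


def simulate_sample(ref: AmpliconRef, cfg: SimConfig, sample_id: str) -> list[SimRead]:
    """Generate ``cfg.n_reads`` barcoded reads for one sample.

    Per read: each spike variant is carried independently with probability
    equal to its VAF; the read is full-length with probability
    ``full_length_fraction``, otherwise a uniformly placed fragment of length
    >= ``fragment_min_len``; the error profile is applied to the
    amplicon-derived sequence and the barcode is prepended intact (sample
    assignment is a controlled design variable here, not a modeled error
    process). Deterministic for a fixed (seed, sample_id).
    """
    spec = cfg.sample(sample_id)
    _validate_spikes(ref, spec.variants)
    rng = _sample_rng(cfg.seed, sample_id)
    bc = np.array([_ENC[b] for b in spec.barcode], dtype=np.uint8)
    reads: list[SimRead] = []
    for i in range(cfg.n_reads):
        carried = [rng.random() < v.vaf for v in spec.variants]
        hap = _apply_spikes(ref.sequence, spec.variants, carried)
        hap_arr = np.array([_ENC[b] for b in hap], dtype=np.uint8)
        L = len(hap_arr)
        if rng.random() < cfg.full_length_fraction or L <= cfg.fragment_min_len:
            start, flen = 0, L
        else:
            start = int(rng.integers(0, L - cfg.fragment_min_len + 1))
            flen = int(rng.integers(cfg.fragment_min_len, L - start + 1))
        noisy = _corrupt(hap_arr[start:start + flen], cfg.error, rng)
        seq = "".join("ACGT"[b] for b in np.concatenate([bc, noisy]))
        flags = "".join("1" if c else "0" for c in carried)
        read_id = f"{sample_id}|r{i:05d}|v{flags}|s{start}|l{flen}"
        reads.append(SimRead(read_id, seq, sample_id,
                             {v.key(): c for v, c in zip(spec.variants, carried)},
                             start, flen))
    return reads


def simulate_run(ref: AmpliconRef, cfg: SimConfig) -> list[SimRead]:
    """All samples' reads, concatenated in sample order (streams independent)."""
    out: list[SimRead] = []
    for s in cfg.samples:
        out.extend(simulate_sample(ref, cfg, s.sample_id))
    return out


# ------------------------------------------------------------------ FASTQ IO

def write_fastq(reads: list[SimRead], path, quality_char: str = "I") -> None:
    """Write reads as 4-line FASTQ with uniform placeholder quality."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(quality_char) - 33] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTQ."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_truth_table(reads: list[SimRead], path) -> None:
    """TSV of per-read truth labels (test-harness metadata, not pipeline input)."""
    rows = []
    for r in reads:
        row = {"read_id": r.read_id, "sample_id": r.sample_id,
               "true_start": r.true_start, "true_len": r.true_len}
        for k, v in r.carries.items():
            row[f"carries:{k}"] = int(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- demultiplex

@dataclass
class DemuxRead:
    read_id: str
    sequence: str  # barcode-trimmed
    trim_len: int


def demultiplex(
    reads: list[tuple[str, str]],
    barcodes: dict[str, str],
    max_edit: int = 3,
) -> tuple[dict[str, list[DemuxRead]], list[tuple[str, str]]]:
    """Assign reads to samples by barcode prefix matching.

    The first ``2 * barcode_length`` bases of each read are scanned for each
    barcode (edlib infix alignment). A read is assigned iff exactly one
    barcode lies within ``max_edit`` edits; anything else (no hit, or two
    barcodes both within the threshold) goes to the unassigned bin. Assigned
    reads are returned with the barcode prefix trimmed. The assignment
    partitions the input.
    """
    items = list(barcodes.items())
    if len(set(b for _, b in items)) != len(items):
        raise ValidationError("barcodes must be pairwise distinct")
    assigned: dict[str, list[DemuxRead]] = {sid: [] for sid in barcodes}
    unassigned: list[tuple[str, str]] = []
    for read_id, seq in reads:
        hits = []
        for sid, bc in items:
            window = seq[: 2 * len(bc)]
            if not window:
                continue
            res = edlib.align(bc, window, mode="HW", task="locations")
            if 0 <= res["editDistance"] <= max_edit:
                end = res["locations"][0][1] + 1  # inclusive end -> trim point
                hits.append((sid, end))
        if len(hits) == 1:
            sid, end = hits[0]
            assigned[sid].append(DemuxRead(read_id, seq[end:], end))
        else:
            unassigned.append((read_id, seq))
    return assigned, unassigned
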