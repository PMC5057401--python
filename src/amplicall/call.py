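"""Pileup-based SNV and indel calling with Varscan-style thresholds.

A candidate allele at a column becomes a call when all of the following
hold: column depth >= ``min_depth``; supporting reads >= ``min_reads2_snv``
(SNVs) or ``min_reads2_indel`` (indels); allele fraction >= ``min_vaf``; and
a one-sided Fisher exact test against an idealized error-only column at rate
``baseline_error`` gives p <= ``max_p``. The Fisher table compares the
observed (ref, alt) read counts with ``(round(depth*(1-e)), round(depth*e))``
and asks for enrichment of the alternate allele.

Adjacent SNVs supported by essentially the same reads (>= 80% co-occurrence
on both sides) are merged into a single multi-nucleotide variant, so
dinucleotide substitutions are reported as one event. Indel alleles are
emitted VCF-anchored and left-normalized.

Reported allele fractions follow the Varscan convention
``reads2 / (reads1 + reads2)`` — alternate reads over reads supporting
either the reference or the alternate allele. At high raw error rates this
ratio is nearly unbiased for the true allele fraction, because superimposed
errors thin reference and variant support almost equally, whereas dividing
by total column depth systematically understates it. Deletion support
counts every read whose deleted run covers the candidate run, so a carrier
deletion fused with an adjacent random deletion into a longer event still
supports the core call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import fisher_exact

from .errors import ValidationError, VcfFormatError
from .pileup import Pileup
from .refmodel import CODE_TO_BASE, AmpliconRef


@dataclass(frozen=True)
class CallerConfig:
    """Calling thresholds (defaults follow the Varscan parameterization
    used for low-coverage long-amplicon screening: depth 50, 10 supporting
    reads for SNVs and 13 for indels, VAF 0.01, p 0.05)."""

    min_depth: int = 50
    min_reads2_snv: int = 10
    min_reads2_indel: int = 13
    min_vaf: float = 0.01
    max_p: float = 0.05
    baseline_error: float = 0.05  # post-correction regime; use ~0.15 for raw reads

    def __post_init__(self):
        if self.min_reads2_snv < 1 or self.min_reads2_indel < 1:
            raise ValidationError("min_reads2 thresholds must be >= 1")
        if not 0 < self.min_vaf < 1 or not 0 < self.max_p < 1:
            raise ValidationError("min_vaf and max_p must lie in (0, 1)")


@dataclass
class VariantCall:
    """A sample-scoped candidate variant (VCF-style alleles).

    ``depth`` is the number of reads supporting either allele
    (reads1 + reads2); ``vaf`` = alt_reads / depth.
    """

    sample_id: str
    genomic_pos: int  # 1-based, plus strand
    ref_allele: str
    alt_allele: str
    var_class: str  # SNV | INS | DEL | MNV
    depth: int
    alt_reads: int
    vaf: float
    p_value: float
    supporters: tuple = field(default=(), compare=False, repr=False)

    def __post_init__(self):
        if self.alt_reads > self.depth:
            raise ValidationError("alt_reads exceeds depth")


def fisher_p(alt_reads: int, ref_reads: int, depth: int, baseline_error: float) -> float:
    """One-sided Fisher exact p for alt enrichment over an error-only column."""
    null_alt = round(depth * baseline_error)
    null_ref = round(depth * (1 - baseline_error))
    _, p = fisher_exact([[alt_reads, ref_reads], [null_alt, null_ref]], alternative="greater")
    return float(p)


def _passes(cfg: CallerConfig, column_depth: int, alt: int, min_reads2: int, used: int) -> bool:
    return (column_depth >= cfg.min_depth and alt >= min_reads2
            and used > 0 and alt / used >= cfg.min_vaf)


def call_snvs(
    pile: Pileup,
    cfg: CallerConfig,
    ref: AmpliconRef,
    sample_id: str = "",
    mnv_cooccurrence: float = 0.8,
) -> list[VariantCall]:
    """Call SNVs column by column, then merge adjacent co-occurring ones."""
    depth = pile.depth
    calls: list[VariantCall] = []
    for offset in range(len(pile)):
        d = int(depth[offset])
        if d < cfg.min_depth:
            continue
        ref_code = int(pile.ref_enc[offset])
        for b in range(4):
            if b == ref_code:
                continue
            alt = int(pile.base_counts[offset, b])
            ref_reads = int(pile.base_counts[offset, min(ref_code, 3)]) if ref_code < 4 else 0
            used = ref_reads + alt
            if not _passes(cfg, d, alt, cfg.min_reads2_snv, used):
                continue
            p = fisher_p(alt, ref_reads, d, cfg.baseline_error)
            if p > cfg.max_p:
                continue
            call = VariantCall(
                sample_id=sample_id,
                genomic_pos=ref.genomic_anchor + offset,
                ref_allele=ref.sequence[offset],
                alt_allele=CODE_TO_BASE[b],
                var_class="SNV",
                depth=used,
                alt_reads=alt,
                vaf=alt / used,
                p_value=p,
                supporters=tuple(pile.alt_supporters.get((offset, b), ())),
            )
            calls.append(call)
    return _merge_mnvs(calls, ref, mnv_cooccurrence)


def _merge_mnvs(calls: list[VariantCall], ref: AmpliconRef, threshold: float) -> list[VariantCall]:
    """Merge chains of adjacent SNVs carried by the same reads into MNVs."""
    calls = sorted(calls, key=lambda c: c.genomic_pos)
    out: list[VariantCall] = []
    i = 0
    while i < len(calls):
        chain = [calls[i]]
        while i + 1 < len(calls):
            nxt = calls[i + 1]
            cur = chain[-1]
            if nxt.genomic_pos != cur.genomic_pos + 1:
                break
            shared = set(cur.supporters) & set(nxt.supporters)
            if (cur.alt_reads and nxt.alt_reads
                    and len(shared) >= threshold * cur.alt_reads
                    and len(shared) >= threshold * nxt.alt_reads):
                chain.append(nxt)
                i += 1
            else:
                break
        if len(chain) == 1:
            out.append(chain[0])
        else:
            shared = set(chain[0].supporters)
            for c in chain[1:]:
                shared &= set(c.supporters)
            out.append(VariantCall(
                sample_id=chain[0].sample_id,
                genomic_pos=chain[0].genomic_pos,
                ref_allele="".join(c.ref_allele for c in chain),
                alt_allele="".join(c.alt_allele for c in chain),
                var_class="MNV",
                depth=min(c.depth for c in chain),
                alt_reads=len(shared),
                vaf=len(shared) / min(c.depth for c in chain),
                p_value=max(c.p_value for c in chain),
                supporters=tuple(sorted(shared)),
            ))
        i += 1
    return out


def _left_normalize_del(ref_seq: str, start: int, length: int) -> int:
    """Shift a deleted run [start, start+length) left while equivalent."""
    while start > 0 and ref_seq[start - 1] == ref_seq[start + length - 1]:
        start -= 1
    return start


def _left_normalize_ins(ref_seq: str, anchor: int, seq: str) -> tuple[int, str]:
    """Rotate an insertion (after column ``anchor``) left while equivalent."""
    while anchor > 0 and seq[-1] == ref_seq[anchor]:
        seq = ref_seq[anchor] + seq[:-1]
        anchor -= 1
    return anchor, seq


def call_indels(
    pile: Pileup,
    cfg: CallerConfig,
    ref: AmpliconRef,
    sample_id: str = "",
) -> list[VariantCall]:
    """Call insertions and deletions from aggregated pileup events."""
    depth = pile.depth
    ref_seq = ref.sequence
    ref_enc = pile.ref_enc

    def ref_reads_at(offset: int) -> int:
        code = int(ref_enc[offset])
        return int(pile.base_counts[offset, code]) if code < 4 else 0

    # insertions: exact (anchor, sequence) events, merged after normalization
    ins_agg: dict[tuple[int, str], set[int]] = {}
    for anchor, seqs in pile.ins_events.items():
        for seq, readers in seqs.items():
            a, s = _left_normalize_ins(ref_seq, anchor, seq)
            ins_agg.setdefault((a, s), set()).update(readers)

    # deletions: support for a candidate run counts every covering deletion;
    # candidates normalizing to the same allele are merged (best-supported wins)
    by_start: dict[int, list[tuple[int, list[int]]]] = {}
    max_len = 0
    for (s, L), readers in pile.del_events.items():
        by_start.setdefault(s, []).append((L, readers))
        max_len = max(max_len, L)
    del_agg: dict[tuple[int, str], set[int]] = {}
    for (s, L) in pile.del_events:
        # covering support is bounded by the columnwise deletion count
        if pile.del_count[s] < cfg.min_reads2_indel:
            continue
        covering: set[int] = set()
        for s2 in range(max(0, s - max_len + 1), s + 1):
            for L2, readers2 in by_start.get(s2, ()):
                if s2 + L2 >= s + L:
                    covering.update(readers2)
        sn = _left_normalize_del(ref_seq, s, L)
        key = (sn, ref_seq[sn:sn + L])
        if key not in del_agg or len(covering) > len(del_agg[key]):
            del_agg[key] = covering

    calls: list[VariantCall] = []
    for (anchor, payload), readers in sorted(ins_agg.items()):
        d = int(depth[anchor])
        alt = len(readers)
        reads1 = ref_reads_at(anchor)
        used = reads1 + alt
        if not _passes(cfg, d, alt, cfg.min_reads2_indel, used):
            continue
        p = fisher_p(alt, reads1, d, cfg.baseline_error)
        if p > cfg.max_p:
            continue
        base = ref_seq[anchor]
        calls.append(VariantCall(
            sample_id=sample_id, genomic_pos=ref.genomic_anchor + anchor,
            ref_allele=base, alt_allele=base + payload, var_class="INS",
            depth=used, alt_reads=alt, vaf=alt / used, p_value=p,
            supporters=tuple(sorted(readers)),
        ))
    for (s, payload), readers in sorted(del_agg.items()):
        L = len(payload)
        if s == 0 and L >= len(ref_seq):
            continue
        d = int(depth[s])
        alt = len(readers)
        reads1 = ref_reads_at(s)
        used = reads1 + alt
        if not _passes(cfg, d, alt, cfg.min_reads2_indel, used):
            continue
        p = fisher_p(alt, reads1, d, cfg.baseline_error)
        if p > cfg.max_p:
            continue
        if s == 0:  # edge deletion: anchor on the following base
            pos, ref_allele, alt_allele = 0, payload + ref_seq[L], ref_seq[L]
        else:
            pos = s - 1
            ref_allele, alt_allele = ref_seq[s - 1] + payload, ref_seq[s - 1]
        calls.append(VariantCall(
            sample_id=sample_id, genomic_pos=ref.genomic_anchor + pos,
            ref_allele=ref_allele, alt_allele=alt_allele, var_class="DEL",
            depth=used, alt_reads=alt, vaf=alt / used, p_value=p,
            supporters=tuple(sorted(readers)),
        ))
    calls.sort(key=lambda c: (c.genomic_pos, c.alt_allele))
    return calls


def call_variants(pile: Pileup, cfg: CallerConfig, ref: AmpliconRef,
                  sample_id: str = "") -> list[VariantCall]:
    """SNVs/MNVs and indels together, position-sorted."""
    calls = call_snvs(pile, cfg, ref, sample_id) + call_indels(pile, cfg, ref, sample_id)
    calls.sort(key=lambda c: (c.genomic_pos, c.var_class, c.alt_allele))
    return calls


# --------------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=amplicall
##contig=<ID={chrom},length={length_hint}>
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Reads supporting ref,alt">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">
##FORMAT=<ID=PVAL,Number=1,Type=Float,Description="Fisher exact p-value">
"""


def _classify_alleles(ref_allele: str, alt_allele: str) -> str:
    if len(ref_allele) == 1 and len(alt_allele) == 1:
        return "SNV"
    if len(ref_allele) == len(alt_allele):
        return "MNV"
    return "DEL" if len(ref_allele) > len(alt_allele) else "INS"


def write_vcf(calls: list[VariantCall], ref: AmpliconRef, path) -> None:
    """Write VCF 4.2 with one sample column per sample_id."""
    samples = sorted({c.sample_id or "sample" for c in calls}) or ["sample"]
    by_site: dict[tuple[int, str, str], dict[str, VariantCall]] = {}
    for c in calls:
        key = (c.genomic_pos, c.ref_allele, c.alt_allele)
        by_site.setdefault(key, {})[c.sample_id or "sample"] = c
    lines = [_VCF_HEADER.format(chrom=ref.chrom_label,
                                length_hint=ref.genomic_anchor + len(ref))]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
    for (pos, ra, aa), per_sample in sorted(by_site.items()):
        cells = []
        for s in samples:
            c = per_sample.get(s)
            if c is None:
                cells.append(".:.:.:.")
            else:
                cells.append(f"{c.depth}:{c.depth - c.alt_reads},{c.alt_reads}:"
                             f"{c.vaf:.4f}:{c.p_value:.17g}")
        lines.append(f"{ref.chrom_label}\t{pos}\t.\t{ra}\t{aa}\t.\tPASS\t.\t"
                     f"DP:AD:AF:PVAL\t" + "\t".join(cells) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_vcf(path) -> list[VariantCall]:
    """Parse a VCF written by :func:`write_vcf` back into calls.

    VAF is recomputed from AD/DP so the round trip is exact on integer
    fields; malformed lines raise :class:`VcfFormatError` with the 1-based
    line number.
    """
    calls: list[VariantCall] = []
    samples: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise VcfFormatError(lineno, "header has no sample columns")
                samples = fields[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise VcfFormatError(lineno, f"expected >=10 columns, got {len(fields)}")
            try:
                pos = int(fields[1])
            except ValueError:
                raise VcfFormatError(lineno, f"non-integer POS {fields[1]!r}")
            ra, aa = fields[3], fields[4]
            fmt = fields[8].split(":")
            for sample, cell in zip(samples, fields[9:]):
                if cell.startswith("."):
                    continue
                vals = dict(zip(fmt, cell.split(":")))
                try:
                    depth = int(vals["DP"])
                    ad = vals["AD"].split(",")
                    alt = int(ad[1])
                    p = float(vals["PVAL"])
                except (KeyError, IndexError, ValueError) as exc:
                    raise VcfFormatError(lineno, f"bad sample field {cell!r}: {exc}")
                calls.append(VariantCall(
                    sample_id=sample,
                    genomic_pos=pos,
                    ref_allele=ra,
                    alt_allele=aa,
                    var_class=_classify_alleles(ra, aa),
                    depth=depth,
                    alt_reads=alt,
                    vaf=alt / depth if depth else 0.0,
                    p_value=p,
                ))
    return calls
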