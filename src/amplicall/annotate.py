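"""HGVS descriptions, effect classification and the post-calling filters.

The gene of interest sits on the minus strand while variants are reported in
plus-strand genomic HGVS (``g.``), so effect classification complements
alleles into transcript orientation before translating. Genomic descriptions
use the compact reporting dialect common in amplicon screening tables
(``g.7577144A>G``, ``g.7577121_7577122GC>TT``, ``g.7577501del``); the
strictly standard form (``delins`` for multi-nucleotide substitutions) is
kept in a parallel field.

The filter cascade mirrors screening practice for error-prone long reads:

* effect exclusion — intronic non-splice-affecting and silent variants;
* Sanger detection limit — allele fraction below ~15% (SNV) / ~20% (indel)
  cannot be orthogonally validated and is not reported;
* recurrence — the same genomic change called in multiple independent
  samples is treated as a systematic sequencing artifact.

Rejected variants are preserved with their flags rather than discarded,
since the recurrence assumption is probabilistic and can misfire on true
hotspot mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .call import VariantCall
from .errors import CoordinateError, ModelError
from .refmodel import AmpliconRef, AnnotationTable, TranscriptModel, revcomp

EFFECTS = ("intronic", "splice", "silent", "missense", "nonsense", "frameshift", "inframe_indel")
NONCODING_EFFECTS = {"intronic", "splice"}

FLAG_EFFECT = "EFFECT_EXCLUDED"
FLAG_SANGER = "BELOW_SANGER_LIMIT"
FLAG_RECURRENT = "RECURRENT"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate(cds: str) -> str:
    """Translate a CDS, stopping at (and including) the first stop ('*')."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in _STANDARD_TABLE.stop_codons:
            aas.append("*")
            break
        aas.append(_STANDARD_TABLE.forward_table.get(codon, "X"))
    return "".join(aas)


def _aa3(aa: str) -> str:
    return "*" if aa == "*" else seq3(aa)


# ------------------------------------------------------------------ HGVS g.

def _trim_alleles(pos: int, ref_allele: str, alt_allele: str) -> tuple[int, str, str]:
    """Strip shared suffix then prefix; returns (first changed pos, ref, alt)."""
    r, a = ref_allele, alt_allele
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    return pos, r, a


def describe_hgvs_g(call: VariantCall, ref: AmpliconRef) -> str:
    """Plus-strand genomic HGVS in the compact reporting dialect."""
    ref.genomic_to_amplicon(call.genomic_pos)  # raises CoordinateError if outside
    pos, r, a = _trim_alleles(call.genomic_pos, call.ref_allele, call.alt_allele)
    if r and a:
        if len(r) == 1 and len(a) == 1:
            return f"g.{pos}{r}>{a}"
        if len(r) == len(a):
            return f"g.{pos}_{pos + len(r) - 1}{r}>{a}"
        return f"g.{pos}_{pos + len(r) - 1}delins{a}"
    if r:  # pure deletion
        if len(r) == 1:
            return f"g.{pos}del"
        return f"g.{pos}_{pos + len(r) - 1}del"
    # pure insertion between pos-1 and pos
    return f"g.{pos - 1}_{pos}ins{a}"


def describe_hgvs_g_standard(call: VariantCall, ref: AmpliconRef) -> str:
    """Strictly standard HGVS (multi-nt substitutions as delins)."""
    pos, r, a = _trim_alleles(call.genomic_pos, call.ref_allele, call.alt_allele)
    if r and a:
        if len(r) == 1 and len(a) == 1:
            return f"g.{pos}{r}>{a}"
        return f"g.{pos}_{pos + len(r) - 1}delins{a}"
    if r:
        return f"g.{pos}del" if len(r) == 1 else f"g.{pos}_{pos + len(r) - 1}del"
    return f"g.{pos - 1}_{pos}ins{a}"


# --------------------------------------------------------- effect classifier

class CdsContext:
    """Cached reference CDS (transcript orientation) for a model + amplicon."""

    def __init__(self, model: TranscriptModel, ref: AmpliconRef):
        self.model = model
        self.ref = ref
        self.positions = model.cds_genomic_positions()
        bases = []
        for g in self.positions:
            b = ref.sequence[ref.genomic_to_amplicon(g)]
            bases.append(b if model.gene_strand == "+" else revcomp(b))
        self.cds = "".join(bases)
        if len(self.cds) % 3 != 0:
            raise ModelError("CDS length is not a multiple of 3")
        self.protein = _translate(self.cds)

    def strand_base(self, base: str) -> str:
        return base if self.model.gene_strand == "+" else revcomp(base)


def _region_label(model: TranscriptModel, pos: int) -> str:
    kind, num = model.locate(pos)
    return f"{num}-{kind}"


def _diff_protein(ref_p: str, mut_p: str) -> tuple[str, str, int]:
    """(ref_aa, mut_aa, 0-based index) of the first difference."""
    for i, (x, y) in enumerate(zip(ref_p, mut_p)):
        if x != y:
            return x, y, i
    if len(mut_p) > len(ref_p):
        return "", mut_p[len(ref_p)], len(ref_p)
    return ref_p[len(mut_p)], "", len(mut_p)


def classify_effect(
    call: VariantCall,
    model: TranscriptModel,
    ref: AmpliconRef,
    ctx: CdsContext | None = None,
) -> tuple[str, str, str]:
    """Classify a variant; returns (effect, hgvs_p, exon_intron label).

    ``hgvs_p`` is empty for intronic/splice (non-coding) variants, per the
    reporting convention. Exonic positions outside the CDS (UTR) are treated
    as non-affecting and classed "intronic".
    """
    ctx = ctx or CdsContext(model, ref)
    pos, r, a = _trim_alleles(call.genomic_pos, call.ref_allele, call.alt_allele)
    if r and a:
        affected = list(range(pos, pos + len(r)))
    elif r:
        affected = list(range(pos, pos + len(r)))
    else:
        affected = [pos - 1, pos]
    for p in affected:
        ref.genomic_to_amplicon(p)  # coordinate check

    label = _region_label(model, affected[0])
    coding = [p for p in affected if ctx.model.cds_index_of(p) is not None]
    if not coding:
        if any(model.near_splice(p) for p in affected):
            return "splice", "", label
        return "intronic", "", label
    label = _region_label(model, coding[0])

    if r and a and len(r) == len(a):
        if len(r) == 1:
            # codon-local SNV path
            idx = ctx.model.cds_index_of(pos)
            codon_i, codon_p = idx // 3, idx % 3
            codon = ctx.cds[codon_i * 3:codon_i * 3 + 3]
            new = list(codon)
            new[codon_p] = ctx.strand_base(a)
            new = "".join(new)
            ref_aa = ctx.protein[codon_i] if codon_i < len(ctx.protein) else "*"
            mut_aa = ("*" if new in _STANDARD_TABLE.stop_codons
                      else _STANDARD_TABLE.forward_table.get(new, "X"))
            if mut_aa == ref_aa:
                return "silent", f"p.{_aa3(ref_aa)}{codon_i + 1}=", label
            effect = "nonsense" if mut_aa == "*" else "missense"
            return effect, f"p.{_aa3(ref_aa)}{codon_i + 1}{_aa3(mut_aa)}", label
        # MNV: substitute per position in CDS space
        cds = list(ctx.cds)
        for p, base in zip(affected, a):
            i = ctx.model.cds_index_of(p)
            if i is not None:
                cds[i] = ctx.strand_base(base)
        mut_p = _translate("".join(cds))
        if mut_p == ctx.protein:
            return "silent", f"p.{_aa3(ctx.protein[0])}1=", label
        ra_, ma_, i = _diff_protein(ctx.protein, mut_p)
        effect = "nonsense" if ma_ == "*" else "missense"
        return effect, f"p.{_aa3(ra_)}{i + 1}{_aa3(ma_)}", label

    # ----- indels -----
    if r:  # deletion of the run `affected`
        removed = {p for p in affected}
        mut_cds = "".join(
            b for b, g in zip(ctx.cds, ctx.positions) if g not in removed
        )
        indel_len = len(coding)
    else:  # insertion between pos-1 and pos
        i1 = ctx.model.cds_index_of(pos - 1)
        i2 = ctx.model.cds_index_of(pos)
        if i1 is None or i2 is None or abs(i1 - i2) != 1:
            # boundary insertion: treat as non-coding
            if any(model.near_splice(p) for p in affected):
                return "splice", "", label
            return "intronic", "", label
        at = min(i1, i2) + 1
        ins_seq = a if model.gene_strand == "+" else revcomp(a)
        mut_cds = ctx.cds[:at] + ins_seq + ctx.cds[at:]
        indel_len = len(a)

    mut_p = _translate(mut_cds)
    if indel_len % 3 != 0:
        ra_, ma_, i = _diff_protein(ctx.protein, mut_p)
        if i < len(mut_p) and "*" in mut_p[i:]:
            k = mut_p.index("*", i) - i + 1
            fs = f"fs*{k}"
        else:
            fs = "fs*?"
        first_mut = mut_p[i] if i < len(mut_p) else "*"
        if first_mut == "*" and i < len(ctx.protein):
            # frameshift creating an immediate stop
            return "frameshift", f"p.{_aa3(ctx.protein[i])}{i + 1}*", label
        return "frameshift", f"p.{_aa3(ctx.protein[i])}{i + 1}{_aa3(first_mut)}{fs}", label

    # in-frame indel: describe via protein prefix/suffix trimming
    ref_p, alt_p = ctx.protein, mut_p
    lo = 0
    while lo < min(len(ref_p), len(alt_p)) and ref_p[lo] == alt_p[lo]:
        lo += 1
    hi = 0
    while (hi < min(len(ref_p), len(alt_p)) - lo
           and ref_p[len(ref_p) - 1 - hi] == alt_p[len(alt_p) - 1 - hi]):
        hi += 1
    del_seg = ref_p[lo:len(ref_p) - hi]
    ins_seg = alt_p[lo:len(alt_p) - hi]
    if del_seg and not ins_seg:
        if len(del_seg) == 1:
            hp = f"p.{_aa3(del_seg)}{lo + 1}del"
        else:
            hp = f"p.{_aa3(del_seg[0])}{lo + 1}_{_aa3(del_seg[-1])}{lo + len(del_seg)}del"
    elif ins_seg and not del_seg:
        hp = (f"p.{_aa3(ref_p[lo - 1])}{lo}_{_aa3(ref_p[lo])}{lo + 1}"
              f"ins{''.join(_aa3(x) for x in ins_seg)}")
    elif not del_seg and not ins_seg:
        return "silent", f"p.{_aa3(ref_p[0])}1=", label
    else:
        hp = (f"p.{_aa3(del_seg[0])}{lo + 1}_{_aa3(del_seg[-1])}{lo + len(del_seg)}"
              f"delins{''.join(_aa3(x) for x in ins_seg)}")
    return "inframe_indel", hp, label


# ------------------------------------------------------- annotated variants

@dataclass
class AnnotatedVariant:
    call: VariantCall
    hgvs_g: str
    hgvs_g_standard: str
    hgvs_p: str
    exon_intron: str
    effect: str
    functional_domain: str = ""
    iarc_match: bool = False
    filter_flags: set = field(default_factory=set)


def annotate_variants(
    calls: list[VariantCall],
    model: TranscriptModel,
    ref: AmpliconRef,
    table: AnnotationTable | None = None,
) -> list[AnnotatedVariant]:
    """HGVS + effect for each call; optionally match the annotation table."""
    ctx = CdsContext(model, ref)
    out = []
    for c in calls:
        effect, hp, label = classify_effect(c, model, ref, ctx)
        out.append(AnnotatedVariant(
            call=c,
            hgvs_g=describe_hgvs_g(c, ref),
            hgvs_g_standard=describe_hgvs_g_standard(c, ref),
            hgvs_p=hp,
            exon_intron=label,
            effect=effect,
        ))
    if table is not None:
        annotate_against_table(out, table)
    return out


def annotate_against_table(variants: list[AnnotatedVariant], table: AnnotationTable) -> list[AnnotatedVariant]:
    """Exact hgvs_g match against the curated table; unmatched are kept."""
    for v in variants:
        rec = table.lookup(v.hgvs_g)
        if rec is None:
            v.iarc_match = False
            v.functional_domain = ""
        else:
            v.iarc_match = True
            v.functional_domain = rec.functional_domain
    return variants


# ------------------------------------------------------------ filter cascade

@dataclass(frozen=True)
class FilterConfig:
    sanger_limit_snv: float = 0.15
    sanger_limit_indel: float = 0.20
    recurrence_max_samples: int = 1
    exclude_effects: frozenset = frozenset({"intronic", "silent"})

    def __post_init__(self):
        if not 0 < self.sanger_limit_snv < 1 or not 0 < self.sanger_limit_indel < 1:
            raise ValueError("Sanger limits must lie in (0, 1)")


def apply_filters(
    per_sample_variants: dict[str, list[AnnotatedVariant]],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[dict], list[dict]]:
    """Flag variants and split them into (report rows, rejected rows).

    Flags are recomputed from scratch on every invocation, so the operation
    is idempotent and independent of sample ordering. The report contains
    exactly the variants with no flags.
    """
    sample_counts: dict[str, set[str]] = {}
    for sid, variants in per_sample_variants.items():
        for v in variants:
            sample_counts.setdefault(v.hgvs_g, set()).add(sid)

    report: list[dict] = []
    rejected: list[dict] = []
    for sid in sorted(per_sample_variants):
        for v in per_sample_variants[sid]:
            v.filter_flags = set()
            if v.effect in cfg.exclude_effects:
                v.filter_flags.add(FLAG_EFFECT)
            limit = (cfg.sanger_limit_indel if v.call.var_class in ("INS", "DEL")
                     else cfg.sanger_limit_snv)
            if v.call.vaf < limit:
                v.filter_flags.add(FLAG_SANGER)
            if len(sample_counts[v.hgvs_g]) > cfg.recurrence_max_samples:
                v.filter_flags.add(FLAG_RECURRENT)
            row = {
                "sample": sid,
                "genomic_description": v.hgvs_g,
                "protein_description": v.hgvs_p,
                "exon_intron": v.exon_intron,
                "functional_domain": v.functional_domain,
                "effect": v.effect,
                "class": v.call.var_class,
                "frequency_pct": round(100 * v.call.vaf, 2),
                "depth": v.call.depth,
                "p_value": v.call.p_value,
            }
            if v.filter_flags:
                row["reasons"] = ",".join(sorted(v.filter_flags))
                rejected.append(row)
            else:
                report.append(row)
    key = lambda r: (r["sample"], r["genomic_description"])
    return sorted(report, key=key), sorted(rejected, key=key)
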