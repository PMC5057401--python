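import pytest
from Bio.SeqUtils import seq3

from amplicall.annotate import (
    FLAG_EFFECT,
    FLAG_RECURRENT,
    FLAG_SANGER,
    AnnotatedVariant,
    CdsContext,
    FilterConfig,
    annotate_against_table,
    apply_filters,
    classify_effect,
    describe_hgvs_g,
    describe_hgvs_g_standard,
)
from amplicall.call import VariantCall
from amplicall.errors import CoordinateError
from amplicall.refmodel import AmpliconRef, AnnotationRecord, AnnotationTable, revcomp
from helpers import translate_to_stop


def _call(pos, ra, aa, vaf=0.3, sample="S1", depth=200):
    kind = ("SNV" if len(ra) == len(aa) == 1
            else "MNV" if len(ra) == len(aa)
            else "DEL" if len(ra) > len(aa) else "INS")
    alt = int(round(vaf * depth))
    return VariantCall(sample, pos, ra, aa, kind, depth, alt, alt / depth, 1e-10)


def _aa3(aa):
    return "*" if aa == "*" else seq3(aa)


class TestHgvsG:
    """The compact genomic dialect: g.7577144A>G / g.7577121_7577122GC>TT /
    g.7577501del, with standard delins kept in a parallel form."""

    @pytest.fixture()
    def tp53_like(self):
        # synthetic sequence anchored so the classic coordinates exist
        import numpy as np
        rng = np.random.default_rng(12)
        seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 9000)))
        anchor = 7571000
        seq[7577144 - anchor] = "A"
        seq[7577121 - anchor] = "G"
        seq[7577122 - anchor] = "C"
        # fix local contexts so deletions/insertions cannot shift
        seq[7577500 - anchor], seq[7577501 - anchor], seq[7577502 - anchor] = "A", "C", "G"
        for pos, base in zip(range(7577600, 7577604), "ACCG"):
            seq[pos - anchor] = base
        return AmpliconRef("tp53ish", "".join(seq), anchor, "chr17")

    def test_snv(self, tp53_like):
        c = _call(7577144, "A", "G")
        assert describe_hgvs_g(c, tp53_like) == "g.7577144A>G"

    def test_mnv_dialect_and_standard(self, tp53_like):
        c = _call(7577121, "GC", "TT")
        assert describe_hgvs_g(c, tp53_like) == "g.7577121_7577122GC>TT"
        assert describe_hgvs_g_standard(c, tp53_like) == "g.7577121_7577122delinsTT"

    def test_single_deletion(self, tp53_like):
        # VCF-anchored: anchor base at 7577500, C at 7577501 deleted
        c = _call(7577500, "AC", "A")
        assert describe_hgvs_g(c, tp53_like) == "g.7577501del"

    def test_multi_deletion_and_insertion(self, tp53_like):
        c = _call(7577600, "ACC", "A")  # deletes CC at 7577601-7577602
        assert describe_hgvs_g(c, tp53_like) == "g.7577601_7577602del"
        ci = _call(7577600, "A", "ATTG")
        assert describe_hgvs_g(ci, tp53_like) == "g.7577600_7577601insTTG"

    def test_out_of_range_position(self, tp53_like):
        c = _call(1000, "A", "G")
        with pytest.raises(CoordinateError):
            describe_hgvs_g(c, tp53_like)


class TestClassifyEffect:
    def test_exhaustive_snvs_match_translation_oracle(self, toy):
        """Every coding SNV agrees with a full-CDS Biopython translation."""
        ref, model = toy
        ctx = CdsContext(model, ref)
        checked = 0
        for idx, g in enumerate(ctx.positions):
            off = g - ref.genomic_anchor
            ref_base = ref.sequence[off]
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                call = _call(g, ref_base, alt)
                effect, hgvs_p, label = classify_effect(call, model, ref, ctx)
                # oracle: substitute in transcript space, translate fully
                cds = list(ctx.cds)
                cds[idx] = alt if model.gene_strand == "+" else revcomp(alt)
                prot = translate_to_stop("".join(cds))
                ref_prot = translate_to_stop(ctx.cds)
                if prot == ref_prot:
                    assert effect == "silent"
                else:
                    i = next(k for k, (x, y) in enumerate(zip(ref_prot, prot)) if x != y)
                    want = "nonsense" if prot[i] == "*" else "missense"
                    assert effect == want
                    assert hgvs_p == f"p.{_aa3(ref_prot[i])}{i + 1}{_aa3(prot[i])}"
                assert label.endswith("-exon")
                assert (hgvs_p == "") == (effect in ("intronic", "splice"))
                checked += 1
        assert checked == 3 * len(ctx.positions)

    def test_named_missense_on_designed_codon(self, toy):
        """A codon-2 CTG->CCG change on the coding strand reads p.Leu2Pro."""
        ref, model = toy
        ctx = CdsContext(model, ref)
        # find a codon whose middle base can make Leu->Pro (CTN -> CCN)
        for ci in range(1, len(ctx.protein) - 1):
            codon = ctx.cds[ci * 3:ci * 3 + 3]
            if codon.startswith("CT"):
                g = ctx.positions[ci * 3 + 1]
                alt_coding = "C"
                alt = alt_coding if model.gene_strand == "+" else revcomp(alt_coding)
                call = _call(g, ref.sequence[g - ref.genomic_anchor], alt)
                effect, hgvs_p, _ = classify_effect(call, model, ref, ctx)
                assert effect == "missense"
                assert hgvs_p == f"p.Leu{ci + 1}Pro"
                return
        pytest.skip("toy gene lacks a CTN codon")  # pragma: no cover

    def test_splice_window_classification(self, toy):
        ref, model = toy
        _, s, e = model.exons[1]
        for g, want in [(s - 1, "splice"), (s - 2, "splice"), (s - 3, "intronic"),
                        (e + 1, "splice"), (e + 2, "splice"), (e + 3, "intronic")]:
            base = ref.sequence[g - ref.genomic_anchor]
            alt = "A" if base != "A" else "C"
            effect, hgvs_p, label = classify_effect(_call(g, base, alt), model, ref)
            assert effect == want
            assert hgvs_p == ""

    def test_frameshift_matches_oracle(self, toy):
        """1-nt coding deletion: frameshift with fs*K from full translation."""
        ref, model = toy
        ctx = CdsContext(model, ref)
        idx = 30  # CDS index well inside the ORF
        g = ctx.positions[idx]
        off = g - ref.genomic_anchor
        call = _call(g - 1, ref.sequence[off - 1] + ref.sequence[off],
                     ref.sequence[off - 1])
        effect, hgvs_p, _ = classify_effect(call, model, ref, ctx)
        assert effect == "frameshift"
        mut = ctx.cds[:idx] + ctx.cds[idx + 1:]
        prot = translate_to_stop(mut)
        ref_prot = translate_to_stop(ctx.cds)
        i = next(k for k, (x, y) in enumerate(zip(ref_prot, prot)) if x != y)
        k = prot.index("*", i) - i + 1
        assert hgvs_p == f"p.{_aa3(ref_prot[i])}{i + 1}{_aa3(prot[i])}fs*{k}"

    def test_inframe_deletion(self, toy):
        ref, model = toy
        ctx = CdsContext(model, ref)
        # delete one whole codon (transcript-contiguous, genomic run of 3)
        idx = 30 - 30 % 3
        gs = sorted(ctx.positions[idx:idx + 3])
        assert gs[2] - gs[0] == 2  # contiguous in genome
        off = gs[0] - ref.genomic_anchor
        run = ref.sequence[off:off + 3]
        call = _call(gs[0] - 1, ref.sequence[off - 1] + run, ref.sequence[off - 1])
        effect, hgvs_p, _ = classify_effect(call, model, ref, ctx)
        assert effect == "inframe_indel"
        assert hgvs_p.startswith("p.")

    def test_deep_intronic_deletion_is_intronic(self, toy):
        ref, model = toy
        exons_sorted = sorted(model.exons, key=lambda x: x[1])
        gap_lo = exons_sorted[0][2] + 50  # deep inside the first intron
        off = gap_lo - ref.genomic_anchor
        call = _call(gap_lo, ref.sequence[off] + ref.sequence[off + 1],
                     ref.sequence[off])
        effect, hgvs_p, label = classify_effect(call, model, ref)
        assert effect == "intronic"
        assert label.endswith("-intron")


class TestAnnotateAgainstTable:
    def _table(self):
        return AnnotationTable([
            AnnotationRecord("g.7577548C>T", "p.Gly245Ser", "7-exon",
                             "DNA binding", "missense"),
        ])

    def _variant(self, hgvs_g):
        return AnnotatedVariant(
            call=_call(7577548, "C", "T"), hgvs_g=hgvs_g, hgvs_g_standard=hgvs_g,
            hgvs_p="p.Gly245Ser", exon_intron="7-exon", effect="missense",
        )

    def test_match_fills_domain(self):
        v = self._variant("g.7577548C>T")
        annotate_against_table([v], self._table())
        assert v.iarc_match
        assert v.functional_domain == "DNA binding"

    def test_absent_key_kept_with_no_match(self):
        v = self._variant("g.1A>C")
        annotate_against_table([v], self._table())
        assert not v.iarc_match
        assert v.functional_domain == ""

    def test_empty_table(self):
        v = self._variant("g.7577548C>T")
        annotate_against_table([v], AnnotationTable([]))
        assert not v.iarc_match


class TestFilters:
    def _av(self, sample, hgvs, effect="missense", vaf=0.3, kind="SNV"):
        ra, aa = ("A", "G") if kind == "SNV" else ("AT", "A")
        c = VariantCall(sample, 100, ra, aa, kind, 200, int(vaf * 200), vaf, 1e-9)
        return AnnotatedVariant(call=c, hgvs_g=hgvs, hgvs_g_standard=hgvs,
                                hgvs_p="p.X1Y", exon_intron="1-exon", effect=effect)

    def test_sanger_limit_edges(self):
        per = {"S1": [self._av("S1", "g.1A>G", vaf=0.14),
                      self._av("S1", "g.2A>G", vaf=0.15),
                      self._av("S1", "g.3AT>A", vaf=0.19, kind="DEL"),
                      self._av("S1", "g.4AT>A", vaf=0.20, kind="DEL")]}
        report, rejected = apply_filters(per, FilterConfig())
        assert {r["genomic_description"] for r in report} == {"g.2A>G", "g.4AT>A"}
        reasons = {r["genomic_description"]: r["reasons"] for r in rejected}
        assert reasons["g.1A>G"] == FLAG_SANGER
        assert reasons["g.3AT>A"] == FLAG_SANGER

    def test_effect_exclusion_keeps_splice(self):
        per = {"S1": [self._av("S1", "g.1A>G", effect="intronic"),
                      self._av("S1", "g.2A>G", effect="silent"),
                      self._av("S1", "g.3A>G", effect="splice"),
                      self._av("S1", "g.4A>G", effect="nonsense")]}
        report, rejected = apply_filters(per, FilterConfig())
        assert {r["genomic_description"] for r in report} == {"g.3A>G", "g.4A>G"}
        assert all(FLAG_EFFECT in r["reasons"] for r in rejected)

    def test_recurrent_removed_everywhere(self):
        """The same change in 3 of 6 samples is flagged in all 3."""
        per = {f"S{i}": [] for i in range(1, 7)}
        for s in ("S1", "S3", "S5"):
            per[s].append(self._av(s, "g.9A>G"))
        per["S2"].append(self._av("S2", "g.7A>G"))
        report, rejected = apply_filters(per, FilterConfig())
        assert [r["genomic_description"] for r in report] == ["g.7A>G"]
        assert len(rejected) == 3
        assert all(r["reasons"] == FLAG_RECURRENT for r in rejected)

    def test_idempotent_and_order_independent(self):
        base = {"S1": [self._av("S1", "g.1A>G"), self._av("S1", "g.2A>G", vaf=0.1)],
                "S2": [self._av("S2", "g.1A>G")]}
        r1 = apply_filters(base, FilterConfig())
        r2 = apply_filters(base, FilterConfig())  # second application
        assert r1 == r2
        shuffled = {k: base[k] for k in sorted(base, reverse=True)}
        assert apply_filters(shuffled, FilterConfig()) == r1
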