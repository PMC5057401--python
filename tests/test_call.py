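import numpy as np
import pytest

from amplicall.align import AlignedRead, align_reads
from amplicall.call import (
    CallerConfig,
    VariantCall,
    call_indels,
    call_snvs,
    call_variants,
    fisher_p,
    read_vcf,
    write_vcf,
)
from amplicall.errors import VcfFormatError
from amplicall.fixtures import synthetic_amplicon
from amplicall.pileup import build_pileup
from amplicall.simulate import SampleSpec, SimConfig, SpikeVariant, simulate_sample
from helpers import exact_fisher_greater


def _reads_with_allele(ref, depth, alt_count, pos, alt):
    """depth full-span reads, alt_count of them carrying alt at pos."""
    out = []
    for i in range(depth):
        q = list(ref.sequence)
        if i < alt_count:
            q[pos] = alt
        q = "".join(q)
        mism = int(i < alt_count)
        out.append(AlignedRead(f"r{i}", "S", 0, [("M", len(ref))], q, mism, mism))
    return out


def _reads_with_deletion(ref, depth, del_count, pos, length=1):
    out = []
    for i in range(depth):
        if i < del_count:
            q = ref.sequence[:pos] + ref.sequence[pos + length:]
            cigar = [("M", pos), ("D", length), ("M", len(ref) - pos - length)]
            out.append(AlignedRead(f"r{i}", "S", 0, cigar, q, length, 0))
        else:
            out.append(AlignedRead(f"r{i}", "S", 0, [("M", len(ref))], ref.sequence, 0, 0))
    return out


class TestFisher:
    @pytest.mark.parametrize("depth,alt,e", [
        (50, 5, 0.05), (50, 20, 0.05), (100, 12, 0.05), (100, 3, 0.15),
        (200, 10, 0.05), (200, 70, 0.05), (200, 40, 0.15), (150, 25, 0.01),
    ])
    def test_matches_exact_hypergeometric_tail(self, depth, alt, e):
        """scipy route equals exact rational tail summation to 1e-12."""
        ref_reads = depth - alt
        c = round(depth * e)
        d = round(depth * (1 - e))
        p = fisher_p(alt, ref_reads, depth, e)
        exact = float(exact_fisher_greater(alt, ref_reads, c, d))
        assert abs(p - exact) <= 1e-12

    def test_strong_signal_example(self, small_ref):
        """Depth 200, alt 70 (35%): called with vanishing p."""
        alt = "A" if small_ref.sequence[100] != "A" else "C"
        alns = _reads_with_allele(small_ref, 200, 70, 100, alt)
        pile = build_pileup(alns, small_ref)
        calls = call_snvs(pile, CallerConfig(), small_ref, "S")
        (c,) = [x for x in calls if x.genomic_pos == small_ref.genomic_anchor + 100]
        # exact tail for [[70,130],[10,190]] is ~5.97e-15
        exact = float(exact_fisher_greater(70, 130, 10, 190))
        assert c.p_value == pytest.approx(exact, abs=1e-12)
        assert c.p_value < 1e-13
        assert c.vaf == pytest.approx(0.35)

    def test_p_monotone_in_alt_reads(self):
        """At fixed depth 50, Fisher p is non-increasing in alt count."""
        ps = [fisher_p(a, 50 - a, 50, 0.05) for a in range(1, 51)]
        assert all(x >= y - 1e-15 for x, y in zip(ps, ps[1:]))


class TestThresholds:
    def test_min_reads2_snv_edge(self, small_ref):
        alt = "A" if small_ref.sequence[100] != "A" else "C"
        alns = _reads_with_allele(small_ref, 200, 9, 100, alt)
        pile = build_pileup(alns, small_ref)
        assert not call_snvs(pile, CallerConfig(), small_ref)

    def test_min_depth_edge(self, small_ref):
        alt = "A" if small_ref.sequence[100] != "A" else "C"
        alns = _reads_with_allele(small_ref, 49, 20, 100, alt)
        pile = build_pileup(alns, small_ref)
        assert not call_snvs(pile, CallerConfig(), small_ref)

    def test_deletion_called_with_direct_count(self, small_ref):
        """1-nt deletion supported by 80/200 reads -> one DEL at vaf 0.40."""
        alns = _reads_with_deletion(small_ref, 200, 80, 120)
        pile = build_pileup(alns, small_ref)
        calls = call_indels(pile, CallerConfig(), small_ref, "S")
        assert len(calls) == 1
        assert calls[0].var_class == "DEL"
        assert calls[0].vaf == pytest.approx(0.40)
        assert calls[0].alt_reads == 80

    def test_min_reads2_indel_edge(self, small_ref):
        alns = _reads_with_deletion(small_ref, 200, 12, 120)
        pile = build_pileup(alns, small_ref)
        assert not call_indels(pile, CallerConfig(), small_ref)

    def test_no_call_violates_config(self, small_ref):
        spike = SpikeVariant(200, small_ref.sequence[200],
                             "A" if small_ref.sequence[200] != "A" else "C", 0.3)
        cfg = SimConfig(samples=[SampleSpec("S1", "", [spike])], n_reads=120,
                        full_length_fraction=1.0, seed=8)
        reads = simulate_sample(small_ref, cfg, "S1")
        alns, _ = align_reads([(r.read_id, r.sequence) for r in reads],
                              small_ref, band=48)
        pile = build_pileup(alns, small_ref)
        caller = CallerConfig(baseline_error=0.15)
        for c in call_variants(pile, caller, small_ref, "S1"):
            assert c.alt_reads >= (caller.min_reads2_indel
                                   if c.var_class in ("INS", "DEL")
                                   else caller.min_reads2_snv)
            assert c.vaf >= caller.min_vaf
            assert c.p_value <= caller.max_p
            assert c.alt_reads <= c.depth


class TestMnvMerging:
    def test_cooccurring_adjacent_snvs_merge(self, small_ref):
        """GC->TT style dinucleotide substitutions merge into one MNV."""
        pos = 100
        alns = []
        for i in range(200):
            q = list(small_ref.sequence)
            if i < 80:
                q[pos] = "T" if small_ref.sequence[pos] != "T" else "A"
                q[pos + 1] = "T" if small_ref.sequence[pos + 1] != "T" else "A"
            q = "".join(q)
            mism = 2 if i < 80 else 0
            alns.append(AlignedRead(f"r{i}", "S", 0, [("M", len(small_ref))], q, mism, mism))
        pile = build_pileup(alns, small_ref)
        calls = call_snvs(pile, CallerConfig(), small_ref, "S")
        assert len(calls) == 1
        assert calls[0].var_class == "MNV"
        assert len(calls[0].ref_allele) == 2
        assert calls[0].alt_reads == 80

    def test_independent_adjacent_snvs_stay_separate(self, small_ref):
        pos = 100
        alns = []
        for i in range(200):
            q = list(small_ref.sequence)
            if i < 40:
                q[pos] = "T" if small_ref.sequence[pos] != "T" else "A"
            elif i < 80:
                q[pos + 1] = "T" if small_ref.sequence[pos + 1] != "T" else "A"
            q = "".join(q)
            mism = int(i < 80)
            alns.append(AlignedRead(f"r{i}", "S", 0, [("M", len(small_ref))], q, mism, mism))
        pile = build_pileup(alns, small_ref)
        calls = call_snvs(pile, CallerConfig(), small_ref, "S")
        assert sorted(c.var_class for c in calls) == ["SNV", "SNV"]


class TestRecovery:
    def test_deletion_spike_recovered_from_raw_reads(self):
        """A 45% 1-nt deletion is recovered within +-0.07 at depth 400."""
        ref = synthetic_amplicon(1000, seed=2)
        spike = SpikeVariant(600, ref.sequence[600], "", 0.45)
        cfg = SimConfig(samples=[SampleSpec("S1", "", [spike])], n_reads=400,
                        full_length_fraction=1.0, seed=5)
        reads = simulate_sample(ref, cfg, "S1")
        alns, _ = align_reads([(r.read_id, r.sequence) for r in reads], ref, band=48)
        pile = build_pileup(alns, ref)
        calls = call_indels(pile, CallerConfig(baseline_error=0.15), ref, "S1")
        hits = [c for c in calls if c.var_class == "DEL"
                and abs(c.genomic_pos - (ref.genomic_anchor + 599)) <= 1]
        assert hits
        assert abs(max(hits, key=lambda c: c.alt_reads).vaf - 0.45) <= 0.07


class TestVcf:
    def _random_calls(self, ref, n=50, seed=0):
        rng = np.random.default_rng(seed)
        calls = []
        used = set()
        while len(calls) < n:
            off = int(rng.integers(1, len(ref) - 2))
            if off in used:
                continue
            used.add(off)
            kind = ["SNV", "INS", "DEL"][int(rng.integers(0, 3))]
            base = ref.sequence[off]
            if kind == "SNV":
                ra, aa = base, "ACGT"[("ACGT".index(base) + 1) % 4]
            elif kind == "INS":
                ra, aa = base, base + "ACGT"[int(rng.integers(0, 4))]
            else:
                ra, aa = base + ref.sequence[off + 1], base
            depth = int(rng.integers(60, 300))
            alt = int(rng.integers(13, depth // 2))
            calls.append(VariantCall(
                sample_id=f"S{int(rng.integers(1, 4))}",
                genomic_pos=ref.genomic_anchor + off,
                ref_allele=ra, alt_allele=aa, var_class=kind,
                depth=depth, alt_reads=alt, vaf=alt / depth,
                p_value=float(rng.random() * 1e-3),
            ))
        return calls

    def test_roundtrip(self, small_ref, tmp_path):
        calls = self._random_calls(small_ref)
        p = tmp_path / "x.vcf"
        write_vcf(calls, small_ref, p)
        back = read_vcf(p)
        key = lambda c: (c.genomic_pos, c.ref_allele, c.alt_allele, c.sample_id)
        assert sorted(back, key=key) == sorted(calls, key=key)

    def test_pysam_parses_output(self, small_ref, tmp_path):
        import pysam
        p = tmp_path / "x.vcf"
        write_vcf(self._random_calls(small_ref, n=10), small_ref, p)
        with pysam.VariantFile(str(p)) as vf:
            recs = list(vf)
        assert len(recs) == 10
        assert all(r.pos >= 1 for r in recs)

    def test_empty_header_only(self, small_ref, tmp_path):
        p = tmp_path / "empty.vcf"
        write_vcf([], small_ref, p)
        body = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert body == []
        assert read_vcf(p) == []

    def test_af_four_decimals_and_one_based_pos(self, small_ref, tmp_path):
        c = VariantCall("S1", small_ref.genomic_anchor + 5, small_ref.sequence[5],
                        "A" if small_ref.sequence[5] != "A" else "C",
                        "SNV", 200, 70, 0.35, 1e-20)
        p = tmp_path / "one.vcf"
        write_vcf([c], small_ref, p)
        data = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        fields = data.split("\t")
        assert int(fields[1]) == small_ref.genomic_anchor + 5
        assert "0.3500" in fields[9]

    def test_malformed_line_reports_line_number(self, small_ref, tmp_path):
        p = tmp_path / "bad.vcf"
        write_vcf(self._random_calls(small_ref, n=2), small_ref, p)
        lines = p.read_text().splitlines()
        lines[-1] = "\t".join(["chrom", "notanint"] + lines[-1].split("\t")[2:])
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(VcfFormatError) as err:
            read_vcf(p)
        assert err.value.line_number == len(lines)
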