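"""Bundled synthetic fixtures: a toy minus-strand gene and random amplicons.

Everything here is generated deterministically at call time — no data files
ship with the package. The toy gene is the default substrate for unit tests
of coordinate mapping, effect classification and the filter cascade; a real
gene region (e.g. a user-supplied TP53 FASTA + model table) can be used
instead through the normal file readers but is never required.
"""

from __future__ import annotations

import numpy as np

from .refmodel import AmpliconRef, TranscriptModel, revcomp

_STOPS = {"TAA", "TAG", "TGA"}

TOY_ANCHOR = 150_001
_TOY_LEN = 1500
# amplicon offsets (0-based, inclusive) of the exons; transcript order is
# reversed because the toy gene sits on the minus strand
_TOY_EXON_OFFSETS = {1: (1100, 1349), 2: (600, 849), 3: (200, 399)}
_TOY_CDS_OFFSETS = (250, 1299)  # genomic-low, genomic-high


def synthetic_amplicon(length: int, seed: int = 0, anchor: int = 1_000_001,
                       name: str = "synthetic_amplicon", chrom: str = "syn_chr") -> AmpliconRef:
    """A uniformly random A/C/G/T amplicon of the requested length."""
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
    return AmpliconRef(name=name, sequence=seq, genomic_anchor=anchor, chrom_label=chrom)


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons-2) random non-stop codons + TAA, 5'->3'."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join("ACGT"[b] for b in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def toy_gene(seed: int = 7) -> tuple[AmpliconRef, TranscriptModel]:
    """A ~1.5-kb amplicon carrying a 3-exon, 200-codon minus-strand gene.

    The CDS (600 nt) spans parts of all three exons; UTR stubs flank it so
    exonic non-coding positions exist. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, size=_TOY_LEN)))

    exons = [
        (num, TOY_ANCHOR + lo, TOY_ANCHOR + hi)
        for num, (lo, hi) in sorted(_TOY_EXON_OFFSETS.items())
    ]
    model = TranscriptModel(
        gene_strand="-",
        exons=exons,
        cds_start=TOY_ANCHOR + _TOY_CDS_OFFSETS[0],
        cds_end=TOY_ANCHOR + _TOY_CDS_OFFSETS[1],
    )

    # paint the coding sequence onto the plus strand (reverse-complemented)
    cds_positions = model.cds_genomic_positions()
    cds = _random_coding_sequence(len(cds_positions) // 3, rng)
    assert len(cds) == len(cds_positions)
    for base, gpos in zip(cds, cds_positions):
        seq[gpos - TOY_ANCHOR] = revcomp(base)

    ref = AmpliconRef(
        name="toygene_amplicon",
        sequence="".join(seq),
        genomic_anchor=TOY_ANCHOR,
        chrom_label="toy_chr",
    )
    # the painted CDS must translate cleanly (guards against fixture drift)
    check = "".join(revcomp(ref.sequence[g - TOY_ANCHOR]) for g in cds_positions)
    assert check == cds
    return ref, model
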