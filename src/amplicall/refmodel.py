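"""Amplicon reference, transcript model and annotation-table containers.

Coordinate conventions used throughout the package:

* internal amplicon coordinates are 0-based half-open;
* all reported/HGVS coordinates are 1-based genomic on the plus strand,
  regardless of the strand the gene is encoded on (the convention used for
  ``g.`` descriptions of TP53, a minus-strand gene);
* the bridge between the two frames is :class:`AmpliconRef.genomic_anchor`,
  the 1-based plus-strand genomic coordinate of the amplicon's first base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, FormatError, ModelError, ValidationError

_VALID_BASES = set("ACGTN")

# integer encoding shared with the aligner and pileup machinery
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_TO_BASE = "ACGTN"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return "".join(CODE_TO_BASE[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconRef:
    """A single amplicon sequence anchored on the plus-strand genome.

    ``genomic_anchor`` is the 1-based genomic coordinate of amplicon offset 0;
    genomic position of offset ``i`` is ``genomic_anchor + i``, a bijection
    over the amplicon.
    """

    name: str
    sequence: str
    genomic_anchor: int
    chrom_label: str = "chrom"

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValidationError("amplicon sequence must be non-empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValidationError(f"non-IUPAC characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def encoded(self) -> np.ndarray:
        return encode_seq(self.sequence)

    def amplicon_to_genomic(self, offset: int) -> int:
        """Map a 0-based amplicon offset to its 1-based genomic position."""
        if not 0 <= offset < len(self):
            raise CoordinateError(f"offset {offset} outside amplicon [0, {len(self)})")
        return self.genomic_anchor + offset

    def genomic_to_amplicon(self, pos: int) -> int:
        """Map a 1-based genomic position to its 0-based amplicon offset."""
        offset = pos - self.genomic_anchor
        if not 0 <= offset < len(self):
            raise CoordinateError(
                f"genomic position {pos} outside amplicon "
                f"[{self.genomic_anchor}, {self.genomic_anchor + len(self) - 1}]"
            )
        return offset


def read_reference(path, anchor: int, chrom: str = "chrom", name: str | None = None) -> AmpliconRef:
    """Read the first record of a FASTA file as an :class:`AmpliconRef`.

    The sequence is uppercased; any character outside A/C/G/T/N raises
    :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if set(seq) - _VALID_BASES or not seq:
        raise FormatError(f"record {rec.id!r} contains non-IUPAC characters (or is empty)")
    return AmpliconRef(name=name or rec.id, sequence=seq, genomic_anchor=int(anchor), chrom_label=chrom)


def write_reference(ref: AmpliconRef, path) -> None:
    """Write the amplicon as FASTA, wrapped at 60 columns."""
    rec = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    SeqIO.write([rec], str(path), "fasta")


@dataclass
class TranscriptModel:
    """Exon/CDS layout of a (possibly minus-strand) gene inside the amplicon.

    ``exons`` are ``(exon_number, genomic_start, genomic_end)`` with 1-based
    inclusive plus-strand genomic bounds, sorted by genomic coordinate and
    non-overlapping. Exon numbers follow transcript order, so for a
    minus-strand gene exon 1 has the highest genomic coordinates.
    ``cds_start``/``cds_end`` are the genomic (plus-strand) bounds of the
    coding region, ``cds_start <= cds_end``. Positions within
    ``splice_window`` nt of an exon boundary (on the intron side) are treated
    as splice-affecting.
    """

    gene_strand: str  # '+' or '-'
    exons: list[tuple[int, int, int]]
    cds_start: int
    cds_end: int
    splice_window: int = 2

    def __post_init__(self):
        if self.gene_strand not in ("+", "-"):
            raise ValidationError("gene_strand must be '+' or '-'")
        self.exons = sorted(self.exons, key=lambda e: e[1])
        prev_end = -1
        for _, s, e in self.exons:
            if s > e:
                raise ValidationError(f"exon with start {s} > end {e}")
            if s <= prev_end:
                raise ValidationError("exons overlap")
            prev_end = e
        if len(self.cds_genomic_positions()) % 3 != 0:
            raise ModelError("concatenated CDS length is not a multiple of 3")

    # ------------------------------------------------------------------ CDS

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcript (5'->3') order."""
        pos: list[int] = []
        exons = self.exons if self.gene_strand == "+" else list(reversed(self.exons))
        for _, s, e in exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo > hi:
                continue
            rng = range(lo, hi + 1) if self.gene_strand == "+" else range(hi, lo - 1, -1)
            pos.extend(rng)
        return pos

    def cds_index_of(self, pos: int) -> int | None:
        """0-based CDS index of a genomic position, or None if non-coding."""
        if not hasattr(self, "_cds_index"):
            self._cds_index = {g: i for i, g in enumerate(self.cds_genomic_positions())}
        return self._cds_index.get(pos)

    def codon_of(self, pos: int) -> tuple[int, int] | None:
        """(codon_index, position_in_codon), both 0-based, or None."""
        idx = self.cds_index_of(pos)
        if idx is None:
            return None
        return idx // 3, idx % 3

    # --------------------------------------------------------------- regions

    def locate(self, pos: int) -> tuple[str, int]:
        """Classify a genomic position as ('exon', n) or ('intron', n).

        Intron *n* lies between exon *n* and exon *n+1* in transcript order.
        Positions outside all exons and beyond the terminal exons are labelled
        as flanking introns of the terminal exons.
        """
        for num, s, e in self.exons:
            if s <= pos <= e:
                return ("exon", num)
        # between which genomic exons?
        for (na, _sa, ea), (nb, sb, _eb) in zip(self.exons, self.exons[1:]):
            if ea < pos < sb:
                return ("intron", min(na, nb))
        # outside the gene body: label with the nearest exon's number
        nearest = min(self.exons, key=lambda x: min(abs(pos - x[1]), abs(pos - x[2])))
        return ("intron", nearest[0])

    def near_splice(self, pos: int) -> bool:
        """True for intronic positions within splice_window of an exon edge."""
        kind, _ = self.locate(pos)
        if kind == "exon":
            return False
        for _, s, e in self.exons:
            if 0 < s - pos <= self.splice_window or 0 < pos - e <= self.splice_window:
                return True
        return False


def read_gene_model(path) -> TranscriptModel:
    """Read a transcript model from a 6-column TSV.

    Columns: exon_number, start, end, strand, cds_start, cds_end.
    ``strand``/``cds_start``/``cds_end`` must be identical on every row (they
    describe the transcript, not the exon).
    """
    df = pd.read_csv(path, sep="\t", dtype={"exon_number": int, "start": int, "end": int})
    required = {"exon_number", "start", "end", "strand", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene model missing columns: {sorted(missing)}")
    if df["strand"].nunique() != 1 or df["cds_start"].nunique() != 1 or df["cds_end"].nunique() != 1:
        raise FormatError("strand/cds_start/cds_end must be constant across rows")
    exons = [(int(r.exon_number), int(r.start), int(r.end)) for r in df.itertuples()]
    return TranscriptModel(
        gene_strand=str(df["strand"].iloc[0]),
        exons=exons,
        cds_start=int(df["cds_start"].iloc[0]),
        cds_end=int(df["cds_end"].iloc[0]),
    )


def write_gene_model(model: TranscriptModel, path) -> None:
    rows = [
        {
            "exon_number": n,
            "start": s,
            "end": e,
            "strand": model.gene_strand,
            "cds_start": model.cds_start,
            "cds_end": model.cds_end,
        }
        for n, s, e in model.exons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Annotation table (reformatted IARC-style variant table)
# --------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "genomic_description",
    "protein_description",
    "exon_intron",
    "functional_domain",
    "effect_class",
]


@dataclass(frozen=True)
class AnnotationRecord:
    genomic_description: str
    protein_description: str
    exon_intron: str
    functional_domain: str
    effect_class: str
    extra: tuple = field(default=(), compare=False)


@dataclass
class AnnotationTable:
    """Lookup table from HGVS ``g.`` description to curated annotation."""

    records: list[AnnotationRecord]

    def __post_init__(self):
        keys = [r.genomic_description for r in self.records]
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        if dupes:
            raise ValidationError(f"duplicate genomic_description keys: {dupes}")
        self._index = {r.genomic_description: r for r in self.records}

    def lookup(self, genomic_description: str) -> AnnotationRecord | None:
        """Return the record for an HGVS g. key, or None (never raises)."""
        return self._index.get(genomic_description)

    def __len__(self) -> int:
        return len(self.records)


def read_annotation_table(path) -> AnnotationTable:
    """Read a 5+-column TSV annotation table (extra columns kept as payload)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    extra_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    records = [
        AnnotationRecord(
            *(str(row[c]) for c in ANNOTATION_COLUMNS),
            extra=tuple((c, str(row[c])) for c in extra_cols),
        )
        for _, row in df.iterrows()
    ]
    return AnnotationTable(records)


def write_annotation_table(table: AnnotationTable, path) -> None:
    rows = []
    for r in table.records:
        d = {c: getattr(r, c) for c in ANNOTATION_COLUMNS}
        d.update(dict(r.extra))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
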