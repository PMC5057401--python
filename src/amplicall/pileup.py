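"""Per-reference-position pileup built from aligned reads.

The pileup is the shared substrate of error correction and variant calling.
Per column it tallies A/C/G/T counts and deleted reads; insertion events are
keyed by the column they follow and their exact inserted sequence; deletion
events are kept as whole per-read runs (a read's D operation is its maximal
deleted run). Supporting read indices are retained for non-reference bases
and for indel events so that callers can measure read-level co-occurrence.

Column invariant: depth = sum of base counts + deleted reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignedRead
from .refmodel import CODE_TO_BASE, AmpliconRef, encode_seq


@dataclass
class PileupColumn:
    """Counts at one reference offset (view into the pileup arrays)."""

    ref_offset: int
    ref_base: str
    base_counts: dict  # base -> count over A/C/G/T
    del_count: int
    ins_events: dict = field(default_factory=dict)  # inserted seq -> count
    depth: int = 0


class Pileup:
    """Vectorized pileup over the whole amplicon."""

    def __init__(self, ref: AmpliconRef, n_reads: int):
        L = len(ref)
        self.ref = ref
        self.ref_enc = ref.encoded
        self.n_reads = n_reads
        self.base_counts = np.zeros((L, 4), dtype=np.int64)
        self.del_count = np.zeros(L, dtype=np.int64)
        # anchor offset (column the insertion follows) -> seq -> read indices
        self.ins_events: dict[int, dict[str, list[int]]] = {}
        # (start offset, length) -> read indices
        self.del_events: dict[tuple[int, int], list[int]] = {}
        # (offset, base code) -> read indices, non-reference bases only
        self.alt_supporters: dict[tuple[int, int], list[int]] = {}

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=1) + self.del_count

    def consensus(self) -> np.ndarray:
        """Per-column consensus base code among A/C/G/T.

        Tie-break: highest count, then the reference base, then lexicographic
        (A<C<G<T). Zero-depth columns fall back to the reference base.
        """
        counts = self.base_counts
        best = counts.max(axis=1)
        cons = counts.argmax(axis=1)  # argmax returns lowest index on ties
        ref_ok = counts[np.arange(len(cons)), np.minimum(self.ref_enc, 3)] == best
        cons = np.where(ref_ok, np.minimum(self.ref_enc, 3), cons)
        cons = np.where(best == 0, np.minimum(self.ref_enc, 3), cons)
        return cons.astype(np.uint8)

    def column(self, offset: int) -> PileupColumn:
        counts = {CODE_TO_BASE[b]: int(self.base_counts[offset, b]) for b in range(4)}
        ins = {seq: len(reads) for seq, reads in self.ins_events.get(offset, {}).items()}
        return PileupColumn(
            ref_offset=offset,
            ref_base=self.ref.sequence[offset],
            base_counts=counts,
            del_count=int(self.del_count[offset]),
            ins_events=ins,
            depth=int(self.depth[offset]),
        )

    def __len__(self) -> int:
        return len(self.ref)


def build_pileup(alignments: list[AlignedRead], ref: AmpliconRef) -> Pileup:
    """Tally all alignments into a :class:`Pileup`."""
    pile = Pileup(ref, len(alignments))
    r_enc = pile.ref_enc
    for idx, a in enumerate(alignments):
        q = encode_seq(a.query_seq)
        qi, rj = 0, a.ref_start
        for op, ln in a.cigar:
            if op == "M":
                seg = q[qi:qi + ln]
                cols = np.arange(rj, rj + ln)
                valid = seg < 4
                np.add.at(pile.base_counts, (cols[valid], seg[valid]), 1)
                mism = np.flatnonzero((seg != r_enc[rj:rj + ln]) & valid)
                for p in mism:
                    pile.alt_supporters.setdefault((rj + int(p), int(seg[p])), []).append(idx)
                qi += ln
                rj += ln
            elif op == "D":
                pile.del_count[rj:rj + ln] += 1
                pile.del_events.setdefault((rj, ln), []).append(idx)
                rj += ln
            else:  # I: insertion sits between columns rj-1 and rj
                anchor = max(rj - 1, 0)
                seq = a.query_seq[qi:qi + ln]
                pile.ins_events.setdefault(anchor, {}).setdefault(seq, []).append(idx)
                qi += ln
    return pile
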