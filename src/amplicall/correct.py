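"""Pileup-consensus correction of random errors in long-amplicon reads.

Random nanopore errors are private to single reads, while true variants are
shared by a stable fraction of reads; columnwise allele frequencies separate
the two. Per column with depth >= ``min_depth_correct``:

* a read base whose column frequency is below ``protect_frac`` is replaced
  by the column consensus base;
* a read insertion whose (anchor, sequence) frequency is below
  ``protect_frac`` of the anchor depth is removed;
* a read deletion at a column where deleted reads are below ``protect_frac``
  of depth is filled with the consensus base.

Minority alleles at or above ``protect_frac`` are never touched, so any
variant near or above reporting limits survives unchanged. The correction is
computed against the pileup of the *input* alignments (not updated while
correcting), which makes it idempotent: every allele that survives one pass
keeps its exact column frequency and is out of correction range on a second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignedRead
from .errors import ValidationError
from .pileup import Pileup, PileupColumn, build_pileup  # noqa: F401  (module surface)
from .refmodel import AmpliconRef, decode_seq, encode_seq


@dataclass(frozen=True)
class CorrectionParams:
    """Thresholds for pileup-consensus correction.

    ``protect_frac`` (default 0.10) sits below the Sanger-style reporting
    limits (0.15 SNV / 0.20 indel) but above the raw per-allele noise floor,
    so no reportable variant can be erased while 4-7% random errors are.
    ``min_depth_correct`` (default 20) leaves shallow columns untouched,
    where the consensus itself is unreliable.
    """

    protect_frac: float = 0.10
    min_depth_correct: int = 20

    def __post_init__(self):
        if not 0 < self.protect_frac < 0.5:
            raise ValidationError("protect_frac must lie in (0, 0.5)")


def correct_reads(
    alignments: list[AlignedRead],
    pile: Pileup,
    params: CorrectionParams = CorrectionParams(),
) -> list[AlignedRead]:
    """Return corrected copies of the alignments (inputs untouched).

    The pileup must have been built from these alignments (read indices in
    the pileup refer to positions in this list).
    """
    ref_enc = pile.ref_enc
    depth = pile.depth
    ok = depth >= params.min_depth_correct
    safe_depth = np.maximum(depth, 1)
    freq = pile.base_counts / safe_depth[:, None]
    low_base = ok[:, None] & (freq < params.protect_frac)
    fill_del = ok & (pile.del_count / safe_depth < params.protect_frac)
    cons = pile.consensus()

    # insertion events to drop: (anchor, seq) below the protection threshold
    drop_ins: set[tuple[int, str]] = set()
    for anchor, seqs in pile.ins_events.items():
        if not ok[anchor]:
            continue
        for seq, readers in seqs.items():
            if len(readers) / depth[anchor] < params.protect_frac:
                drop_ins.add((anchor, seq))

    out: list[AlignedRead] = []
    for a in alignments:
        q = encode_seq(a.query_seq)
        qi, rj = 0, a.ref_start
        new_q: list[np.ndarray] = []
        ops: list[tuple[str, int]] = []

        def emit(op: str, ln: int):
            if ln == 0:
                return
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + ln)
            else:
                ops.append((op, ln))

        mism = 0
        for op, ln in a.cigar:
            if op == "M":
                seg = q[qi:qi + ln].copy()
                cols = np.arange(rj, rj + ln)
                replace = (seg < 4) & (seg != cons[cols]) & low_base[cols, np.minimum(seg, 3)]
                seg[replace] = cons[cols[replace]]
                mism += int(np.count_nonzero(seg != ref_enc[cols]))
                new_q.append(seg)
                emit("M", ln)
                qi += ln
                rj += ln
            elif op == "D":
                for j in range(rj, rj + ln):
                    if fill_del[j]:
                        new_q.append(np.array([cons[j]], dtype=np.uint8))
                        if cons[j] != ref_enc[j]:
                            mism += 1
                        emit("M", 1)
                    else:
                        emit("D", 1)
                rj += ln
            else:  # I
                anchor = max(rj - 1, 0)
                seq = a.query_seq[qi:qi + ln]
                if (anchor, seq) not in drop_ins:
                    new_q.append(q[qi:qi + ln])
                    emit("I", ln)
                qi += ln

        new_seq = decode_seq(np.concatenate(new_q)) if new_q else ""
        ins = sum(ln for op, ln in ops if op == "I")
        dels = sum(ln for op, ln in ops if op == "D")
        out.append(AlignedRead(
            read_id=a.read_id,
            sample_id=a.sample_id,
            ref_start=a.ref_start,
            cigar=ops,
            query_seq=new_seq,
            edit_distance=mism + ins + dels,
            n_mismatch=mism,
            score=a.score,
        ))
    return out


def write_corrected_fasta(alignments: list[AlignedRead], path) -> None:
    """Corrected read sequences as FASTA (for optional external realignment)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(a.query_seq), id=a.read_id, description="") for a in alignments]
    SeqIO.write(records, str(path), "fasta")
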