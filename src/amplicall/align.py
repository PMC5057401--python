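"""Banded affine-gap glocal alignment of amplicon reads, plus SAM interop.

Reads from a single long amplicon should map end-to-end, so the aligner is
*glocal* (semi-global): the query is aligned in full, while reference
overhang on either side is free. Local alignment would soft-clip genuine
deletions near read ends; global alignment would penalize fragments.

The dynamic program is the standard three-state Gotoh recursion
(match/mismatch M, insertion I consuming query, deletion D consuming
reference) with affine gap cost ``gap_open + k * gap_extend`` for a gap of
length k, evaluated inside a diagonal band. The band is centered on a guide
line through the approximate start/end of the read on the reference
(estimated with an edit-distance infix scan), which absorbs the net
coordinate drift that deletion-biased nanopore errors accumulate over a
multi-kilobase read; the band half-width then only needs to cover local
excursions around that line. Ties are broken deterministically, preferring
M over D over I.

Externally produced alignments (e.g. BWA-MEM) can be ingested through
``read_sam`` and are interchangeable with internal ones downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pysam
from numba import njit

from .errors import ValidationError
from .refmodel import AmpliconRef, encode_seq

logger = logging.getLogger(__name__)

MIN_QUERY_LEN = 30  #: shorter queries are rejected, not aligned
NEG = -(10 ** 9)


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()
DEFAULT_BAND = 256  # suits ~7-kb reads at ~15% error; tests use tighter bands


@dataclass
class AlignedRead:
    """A read placed on the amplicon with explicit M/I/D operations."""

    read_id: str
    sample_id: str
    ref_start: int  # 0-based amplicon offset
    cigar: list[tuple[str, int]]  # ops 'M' (match/mismatch), 'I', 'D'
    query_seq: str
    edit_distance: int  # mismatches + inserted bases + deleted bases
    n_mismatch: int = 0
    score: int = 0

    @property
    def query_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MI")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span

    def validate(self, ref: AmpliconRef) -> None:
        if self.query_span != len(self.query_seq):
            raise ValidationError("CIGAR M+I length does not match query length")
        if self.ref_start < 0 or self.ref_end > len(ref):
            raise ValidationError("alignment extends beyond the reference")
        ins = sum(n for op, n in self.cigar if op == "I")
        dels = sum(n for op, n in self.cigar if op == "D")
        if self.edit_distance != self.n_mismatch + ins + dels:
            raise ValidationError("edit_distance inconsistent with CIGAR/mismatches")

    def identity(self) -> float:
        """Matching columns over all alignment columns (M+I+D)."""
        cols = sum(n for _, n in self.cigar)
        matches = sum(n for op, n in self.cigar if op == "M") - self.n_mismatch
        return matches / cols if cols else 0.0


# ------------------------------------------------------------------- kernel

@njit(cache=True)
def _banded_dp(q, r, lo, W, match, mismatch, go, ge):  # pragma: no cover - jit
    m = q.shape[0]
    n = r.shape[0]
    tbM = np.zeros((m + 1, W), np.uint8)
    tbD = np.zeros((m + 1, W), np.uint8)
    tbI = np.zeros((m + 1, W), np.uint8)
    Mprev = np.full(W, NEG, np.int64)
    Dprev = np.full(W, NEG, np.int64)
    Iprev = np.full(W, NEG, np.int64)
    Mcur = np.full(W, NEG, np.int64)
    Dcur = np.full(W, NEG, np.int64)
    Icur = np.full(W, NEG, np.int64)
    for k in range(W):
        if lo[0] + k <= n:
            Mprev[k] = 0  # free reference prefix: start anywhere on row 0
    for i in range(1, m + 1):
        qc = q[i - 1]
        loi = lo[i]
        lop = lo[i - 1]
        for k in range(W):
            Mcur[k] = NEG
            Dcur[k] = NEG
            Icur[k] = NEG
        for k in range(W):
            j = loi + k
            if j > n:
                break
            kp = j - lop  # same column, previous row
            if 0 <= kp < W:
                mo = Mprev[kp] + go + ge
                ie = Iprev[kp] + ge
                if mo >= ie:
                    Icur[k] = mo
                    tbI[i, k] = 0
                else:
                    Icur[k] = ie
                    tbI[i, k] = 2
            if j >= 1:
                kd = j - 1 - lop  # diagonal predecessor
                if 0 <= kd < W:
                    best = Mprev[kd]
                    st = 0
                    if Dprev[kd] > best:
                        best = Dprev[kd]
                        st = 1
                    if Iprev[kd] > best:
                        best = Iprev[kd]
                        st = 2
                    if best > NEG // 2:
                        rc = r[j - 1]
                        s = match if (qc == rc and qc < 4) else mismatch
                        Mcur[k] = best + s
                        tbM[i, k] = st
                if k >= 1:
                    mo = Mcur[k - 1] + go + ge
                    de = Dcur[k - 1] + ge
                    if mo >= de:
                        Dcur[k] = mo
                        tbD[i, k] = 0
                    else:
                        Dcur[k] = de
                        tbD[i, k] = 1
        Mprev, Mcur = Mcur, Mprev
        Dprev, Dcur = Dcur, Dprev
        Iprev, Icur = Icur, Iprev
    # free reference suffix: best over the last row; prefer M over I on ties
    best = NEG
    best_j = -1
    best_state = 0
    for k in range(W):
        j = lo[m] + k
        if j > n:
            break
        if Mprev[k] > best:
            best = Mprev[k]
            best_j = j
            best_state = 0
        if Iprev[k] > best:
            best = Iprev[k]
            best_j = j
            best_state = 2
    return best, best_j, best_state, tbM, tbD, tbI


@njit(cache=True)
def _traceback(tbM, tbD, tbI, lo, i, j, state):  # pragma: no cover - jit
    maxlen = tbM.shape[0] + tbM.shape[1] + j + 5
    ops = np.empty(maxlen, np.uint8)
    pos = maxlen
    while i > 0:
        k = j - lo[i]
        pos -= 1
        if state == 0:
            ops[pos] = 0  # M
            state = tbM[i, k]
            i -= 1
            j -= 1
        elif state == 1:
            ops[pos] = 2  # D
            state = tbD[i, k]
            j -= 1
        else:
            ops[pos] = 1  # I
            state = tbI[i, k]
            i -= 1
    return ops[pos:], j


def _guide_line(query: str, ref_seq: str) -> tuple[int, int]:
    """Approximate (start, end) of the query on the reference (half-open)."""
    res = edlib.align(query, ref_seq, mode="HW", task="locations")
    locs = res.get("locations") or []
    if locs and locs[0][0] is not None and locs[0][1] is not None:
        return locs[0][0], locs[0][1] + 1
    return 0, len(ref_seq)


def align_read(
    query: str,
    ref: AmpliconRef,
    scoring: Scoring = DEFAULT_SCORING,
    band: int = DEFAULT_BAND,
    read_id: str = "",
    sample_id: str = "",
) -> AlignedRead | None:
    """Glocal banded affine-gap alignment of one read.

    Returns None (a rejected-read signal) for queries shorter than
    ``MIN_QUERY_LEN``; never raises for alignable input.
    """
    if band < 1:
        raise ValidationError("band must be >= 1")
    query = query.upper()
    if len(query) < MIN_QUERY_LEN:
        return None
    q = encode_seq(query)
    r = ref.encoded
    m, n = len(q), len(r)
    W = min(2 * band + 1, n + 1)
    start, end = _guide_line(query, ref.sequence)
    centers = np.round(start + np.arange(m + 1) * ((end - start) / max(m, 1)))
    lo = np.clip(centers.astype(np.int64) - band, 0, max(0, n + 1 - W))
    score, end_j, end_state, tbM, tbD, tbI = _banded_dp(
        q, r, lo, W, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if score <= NEG // 2:  # band never reached the last row; realign unbanded
        lo = np.zeros(m + 1, dtype=np.int64)
        score, end_j, end_state, tbM, tbD, tbI = _banded_dp(
            q, r, lo, n + 1, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
        )
    ops, ref_start = _traceback(tbM, tbD, tbI, lo, m, end_j, end_state)
    cigar: list[tuple[str, int]] = []
    for op in ops:
        name = "MID"[op]
        if cigar and cigar[-1][0] == name:
            cigar[-1] = (name, cigar[-1][1] + 1)
        else:
            cigar.append((name, 1))
    # count mismatches along M runs
    mism = 0
    qi, rj = 0, ref_start
    for op, ln in cigar:
        if op == "M":
            mism += int(np.count_nonzero(q[qi:qi + ln] != r[rj:rj + ln]))
            qi += ln
            rj += ln
        elif op == "I":
            qi += ln
        else:
            rj += ln
    ins = sum(ln for op, ln in cigar if op == "I")
    dels = sum(ln for op, ln in cigar if op == "D")
    return AlignedRead(
        read_id=read_id,
        sample_id=sample_id,
        ref_start=int(ref_start),
        cigar=cigar,
        query_seq=query,
        edit_distance=mism + ins + dels,
        n_mismatch=mism,
        score=int(score),
    )


def align_reads(
    reads,
    ref: AmpliconRef,
    scoring: Scoring = DEFAULT_SCORING,
    band: int = DEFAULT_BAND,
    sample_id: str = "",
    min_identity: float = 0.6,
) -> tuple[list[AlignedRead], dict]:
    """Align a batch of (read_id, sequence) pairs; drop junk.

    Reads shorter than ``MIN_QUERY_LEN`` or with alignment identity below
    ``min_identity`` are dropped and counted in the returned stats dict.
    """
    alignments: list[AlignedRead] = []
    stats = {"input": 0, "aligned": 0, "too_short": 0, "low_identity": 0}
    for read_id, seq in reads:
        stats["input"] += 1
        aln = align_read(seq, ref, scoring=scoring, band=band,
                         read_id=read_id, sample_id=sample_id)
        if aln is None:
            stats["too_short"] += 1
            continue
        if aln.identity() < min_identity:
            stats["low_identity"] += 1
            continue
        stats["aligned"] += 1
        alignments.append(aln)
    return alignments, stats


# ------------------------------------------------------------------- SAM IO

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2}


def write_sam(alignments: list[AlignedRead], ref: AmpliconRef, path) -> None:
    """Write a minimal SAM (plain text): @HD, @SQ, @RG per sample, NM tags."""
    samples = sorted({a.sample_id for a in alignments if a.sample_id})
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": len(ref)}],
        "RG": [{"ID": s, "SM": s} for s in samples],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = a.ref_start
            seg.mapping_quality = 60
            seg.cigartuples = [(_CIGAR_CODE[op], ln) for op, ln in a.cigar]
            seg.query_sequence = a.query_seq
            tags = [("NM", a.edit_distance)]
            if a.sample_id:
                tags.append(("RG", a.sample_id))
            seg.tags = tags
            out.write(seg)


def _iter_sam_records(sam):
    """Yield records, swallowing htslib parse aborts on malformed lines."""
    it = sam.fetch(until_eof=True)
    while True:
        try:
            yield next(it)
        except StopIteration:
            return
        except (OSError, ValueError) as exc:
            logger.warning("SAM parse error, remaining records skipped: %s", exc)
            return


def read_sam(path, ref: AmpliconRef) -> list[AlignedRead]:
    """Read a SAM file into AlignedReads.

    Unmapped/secondary/supplementary records are skipped. Soft clips are
    trimmed out of the query, ``=``/``X`` collapse to M, hard clips are
    ignored. Records whose CIGAR and sequence lengths disagree are skipped
    with a logged warning.
    """
    out: list[AlignedRead] = []
    skipped = 0
    r_enc = ref.encoded
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        rg_to_sample = {rg.get("ID"): rg.get("SM", rg.get("ID", ""))
                        for rg in sam.header.to_dict().get("RG", [])}
        records = _iter_sam_records(sam)
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != ref.name:
                continue
            cigar: list[tuple[str, int]] = []
            for code, ln in rec.cigartuples or []:
                if code in (0, 7, 8):  # M, =, X
                    name = "M"
                elif code == 1:
                    name = "I"
                elif code == 2:
                    name = "D"
                elif code in (4, 5):  # S/H: trimmed / ignored
                    continue
                else:
                    name = None
                if name is None:
                    cigar = []
                    break
                if cigar and cigar[-1][0] == name:
                    cigar[-1] = (name, cigar[-1][1] + 1)
                else:
                    cigar.append((name, ln))
            seq = (rec.query_alignment_sequence or "").upper()
            q_len = sum(ln for op, ln in cigar if op in "MI")
            if not cigar or q_len != len(seq):
                skipped += 1
                logger.warning("skipping SAM record %s: CIGAR/sequence mismatch", rec.query_name)
                continue
            q = encode_seq(seq)
            mism = 0
            qi, rj = 0, rec.reference_start
            for op, ln in cigar:
                if op == "M":
                    mism += int(np.count_nonzero(q[qi:qi + ln] != r_enc[rj:rj + ln]))
                    qi += ln
                    rj += ln
                elif op == "I":
                    qi += ln
                else:
                    rj += ln
            ins = sum(ln for op, ln in cigar if op == "I")
            dels = sum(ln for op, ln in cigar if op == "D")
            sample = ""
            if rec.has_tag("RG"):
                rg = rec.get_tag("RG")
                sample = rg_to_sample.get(rg, rg)
            edit = rec.get_tag("NM") if rec.has_tag("NM") else mism + ins + dels
            out.append(AlignedRead(
                read_id=rec.query_name,
                sample_id=sample,
                ref_start=rec.reference_start,
                cigar=cigar,
                query_seq=seq,
                edit_distance=int(edit),
                n_mismatch=mism,
            ))
    if skipped:
        logger.warning("read_sam: skipped %d malformed records", skipped)
    return out
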