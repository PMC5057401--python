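"""Read-set summaries, alignment error assessment, coverage profiles.

Error accounting convention: for each read, errors = mismatches + inserted
bases + deleted bases (a 2-nt deletion counts as 2 errors); the denominator
is the reference-aligned span (M+D columns); per-100 figures are unweighted
means over reads. A base-pooled figure (total errors over total span) is
also computed as a secondary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignedRead
from .refmodel import AmpliconRef


@dataclass(frozen=True)
class LengthSummary:
    n_reads: int
    min_len: int | None
    max_len: int | None
    mean_len: float | None


def length_summary(lengths) -> LengthSummary:
    """Summary statistics of read lengths (reads, strings, or ints)."""
    ls = [len(x) if not isinstance(x, (int, np.integer)) else int(x) for x in lengths]
    if not ls:
        return LengthSummary(0, None, None, None)
    return LengthSummary(len(ls), int(min(ls)), int(max(ls)), float(np.mean(ls)))


def length_histogram(lengths, n_bins: int = 50) -> pd.DataFrame:
    """Binned read-length histogram, suitable for TSV export / plotting."""
    ls = np.array([len(x) if not isinstance(x, (int, np.integer)) else int(x) for x in lengths])
    if ls.size == 0:
        return pd.DataFrame({"bin_start": [], "bin_end": [], "count": []})
    counts, edges = np.histogram(ls, bins=n_bins)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})


@dataclass(frozen=True)
class ErrorReport:
    subs_per100: float
    ins_per100: float
    del_per100: float
    total_per100: float
    mean_indel_event_len: float
    n_reads_assessed: int
    pooled_total_per100: float = 0.0  # secondary: totals pooled over bases


def per_read_errors(alignments: list[AlignedRead]) -> pd.DataFrame:
    """Per-read error components; substrate for :func:`assess_errors`."""
    rows = []
    for a in alignments:
        ins = sum(ln for op, ln in a.cigar if op == "I")
        dels = sum(ln for op, ln in a.cigar if op == "D")
        span = a.ref_span
        events = [ln for op, ln in a.cigar if op in "ID"]
        rows.append({
            "read_id": a.read_id,
            "sample_id": a.sample_id,
            "span": span,
            "mismatches": a.n_mismatch,
            "ins_bases": ins,
            "del_bases": dels,
            "indel_events": len(events),
            "indel_event_bases": sum(events),
        })
    return pd.DataFrame(rows)


def assess_errors(alignments: list[AlignedRead], ref: AmpliconRef | None = None) -> ErrorReport:
    """Mean errors per 100 aligned reference bases, by class, over reads."""
    if not alignments:
        return ErrorReport(0.0, 0.0, 0.0, 0.0, 0.0, 0)
    df = per_read_errors(alignments)
    span = df["span"].to_numpy(dtype=float)
    subs = float(np.mean(df["mismatches"] / span * 100))
    ins = float(np.mean(df["ins_bases"] / span * 100))
    dels = float(np.mean(df["del_bases"] / span * 100))
    n_events = int(df["indel_events"].sum())
    mean_event = float(df["indel_event_bases"].sum() / n_events) if n_events else 0.0
    pooled = float(
        (df["mismatches"] + df["ins_bases"] + df["del_bases"]).sum() / span.sum() * 100
    )
    return ErrorReport(
        subs_per100=subs,
        ins_per100=ins,
        del_per100=dels,
        total_per100=subs + ins + dels,
        mean_indel_event_len=mean_event,
        n_reads_assessed=len(alignments),
        pooled_total_per100=pooled,
    )


def coverage_profile(alignments: list[AlignedRead], ref: AmpliconRef) -> np.ndarray:
    """Depth per reference position; a position is covered by M or D columns."""
    depth = np.zeros(len(ref), dtype=np.int64)
    for a in alignments:
        rj = a.ref_start
        for op, ln in a.cigar:
            if op in "MD":
                depth[rj:rj + ln] += 1
                rj += ln
    return depth


def coverage_to_tsv(depth: np.ndarray, ref: AmpliconRef, path) -> None:
    pd.DataFrame({
        "genomic_pos": np.arange(len(depth)) + ref.genomic_anchor,
        "depth": depth,
    }).to_csv(path, sep="\t", index=False)


def error_report_to_tsv(report: ErrorReport, path) -> None:
    pd.DataFrame([report.__dict__]).to_csv(path, sep="\t", index=False)


def plot_coverage(depth: np.ndarray, ref: AmpliconRef, path) -> None:
    """Coverage plot (optional; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(np.arange(len(depth)) + ref.genomic_anchor, depth, step="mid", alpha=0.6)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("depth")
    ax.set_title(f"coverage: {ref.name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_length_hist(lengths, path, n_bins: int = 50) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ls = [len(x) if not isinstance(x, (int, np.integer)) else int(x) for x in lengths]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.hist(ls, bins=n_bins)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
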