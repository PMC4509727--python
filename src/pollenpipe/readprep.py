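"""Paired-end merging and quality filtering.

Merging reverse-complements the reverse read and scans every candidate
overlap length L ≥ ``min_overlap`` between the forward read's suffix and
the reverse-complemented read's prefix.  The candidate minimising the
mismatch fraction wins (ties go to the longer overlap) and is accepted iff
its mismatch fraction is at most ``max_mismatch_frac``.  In the consensus,
agreeing positions keep the higher of the two qualities; disagreeing
positions keep the higher-quality base with quality ``|q1 - q2|`` (floored
at 2); merged qualities are capped at Q41 so they stay printable in
Phred+33.

Quality filtering drops merged reads shorter than ``min_len``, with mean
Phred below ``min_mean_q``, or with more than ``max_ambiguous`` non-ACGT
bases — the first failing rule is the reported reason.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import MAX_PHRED, ascii_to_phred, phred_to_ascii, revcomp, seq_to_array

logger = logging.getLogger(__name__)

__all__ = [
    "MergeParams",
    "FilterParams",
    "MergedRead",
    "MergeFailure",
    "merge_pair",
    "merge_sample",
    "quality_filter",
    "filter_reads",
    "prep_report",
    "iter_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class MergeParams:
    """Overlap-merge tuning; defaults follow the common joining-tool defaults."""

    min_overlap: int = 6
    max_mismatch_frac: float = 0.08

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_frac <= 1.0:
            raise ValueError("max_mismatch_frac must be in [0, 1]")


@dataclass(frozen=True)
class FilterParams:
    min_len: int = 150
    min_mean_q: float = 20.0
    max_ambiguous: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_len: int
    overlap_mismatches: int


@dataclass(frozen=True)
class MergeFailure:
    id: str
    reason: str  # "no_overlap" | "too_many_mismatches"


def _overlap_mismatches(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Mismatch count for every overlap length L = 1..min(n1,n2).

    Overlap L aligns the last L bases of read 1 with the first L bases of
    (reverse-complemented) read 2, i.e. one anti-diagonal band of the
    pairwise equality matrix; match counts per diagonal come from a single
    bincount over the equal cells.
    """
    n1, n2 = len(a1), len(a2)
    eq = a1[:, None] == a2[None, :]
    # cell (i, j) compares r1[i] vs rc2[j]; it belongs to overlap L = n1 - i + j
    # (valid while j < L and i >= n1 - L, i.e. j - i + n1 in 1..min(n1, n2))
    i_idx, j_idx = np.nonzero(eq)
    L_of_cell = j_idx - i_idx + n1
    lmax = min(n1, n2)
    valid = (L_of_cell >= 1) & (L_of_cell <= lmax)
    matches = np.bincount(L_of_cell[valid], minlength=lmax + 1)[1:]
    lengths = np.arange(1, lmax + 1)
    return lengths - matches


def merge_pair(
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    params: MergeParams = MergeParams(),
    read_id: str = "read",
) -> MergedRead | MergeFailure:
    """Merge one read pair by overlap, or report why it could not be merged."""
    if not r1_seq or not r2_seq:
        raise ValueError(f"read {read_id}: empty sequence")
    if len(r1_seq) != len(r1_qual) or len(r2_seq) != len(r2_qual):
        raise ValueError(f"read {read_id}: sequence/quality length mismatch")

    rc2_seq = revcomp(r2_seq)
    rc2_qual = r2_qual[::-1]
    n1, n2 = len(r1_seq), len(rc2_seq)
    lmax = min(n1, n2)
    if params.min_overlap > lmax:
        return MergeFailure(read_id, "no_overlap")

    a1 = seq_to_array(r1_seq)
    a2 = seq_to_array(rc2_seq)
    mism = _overlap_mismatches(a1, a2)  # index L-1 -> mismatches at overlap L
    lengths = np.arange(1, lmax + 1)
    ok = lengths >= params.min_overlap
    frac = mism[ok] / lengths[ok]
    cand_lengths = lengths[ok]
    # min mismatch fraction, ties -> larger L (scan from the end)
    best_frac = frac.min()
    best_pos = np.nonzero(frac == best_frac)[0][-1]
    L = int(cand_lengths[best_pos])
    n_mm = int(mism[L - 1])
    if best_frac > params.max_mismatch_frac:
        return MergeFailure(read_id, "too_many_mismatches")

    q1 = ascii_to_phred(r1_qual)
    q2 = ascii_to_phred(rc2_qual)
    ov1_seq, ov1_q = a1[n1 - L :], q1[n1 - L :]
    ov2_seq, ov2_q = a2[:L], q2[:L]
    agree = ov1_seq == ov2_seq
    cons_seq = np.where(agree | (ov1_q >= ov2_q), ov1_seq, ov2_seq)
    cons_q = np.where(agree, np.maximum(ov1_q, ov2_q), np.maximum(np.abs(ov1_q - ov2_q), 2))
    cons_q = np.minimum(cons_q, MAX_PHRED)
    seq = r1_seq[: n1 - L] + cons_seq.astype(np.uint8).tobytes().decode("ascii") + rc2_seq[L:]
    qual = (
        phred_to_ascii(q1[: n1 - L])
        + phred_to_ascii(cons_q)
        + phred_to_ascii(q2[L:])
    )
    return MergedRead(read_id, seq, qual, overlap_len=L, overlap_mismatches=n_mm)


def merge_sample(
    pairs: Iterable[tuple[str, str, str, str, str]],
    params: MergeParams = MergeParams(),
) -> tuple[list[MergedRead], list[MergeFailure]]:
    """Merge a stream of (id, r1_seq, r1_qual, r2_seq, r2_qual) tuples."""
    merged: list[MergedRead] = []
    failed: list[MergeFailure] = []
    for rid, s1, q1, s2, q2 in pairs:
        out = merge_pair(s1, q1, s2, q2, params, read_id=rid)
        (merged if isinstance(out, MergedRead) else failed).append(out)
    return merged, failed


def quality_filter(seq: str, qual: str, params: FilterParams = FilterParams()) -> str | None:
    """Return None to keep the read, else the discard reason.

    Rules are checked in order: short, low_quality, ambiguous.
    """
    if len(seq) < params.min_len:
        return "short"
    if float(ascii_to_phred(qual).mean()) < params.min_mean_q:
        return "low_quality"
    n_ambig = sum(1 for c in seq if c not in "ACGT")
    if n_ambig > params.max_ambiguous:
        return "ambiguous"
    return None


def filter_reads(
    reads: Iterable[MergedRead], params: FilterParams = FilterParams()
) -> tuple[list[MergedRead], dict[str, int]]:
    """Apply :func:`quality_filter` to a read list; returns kept reads and
    per-reason discard counts."""
    kept: list[MergedRead] = []
    reasons: dict[str, int] = {"short": 0, "low_quality": 0, "ambiguous": 0}
    for r in reads:
        reason = quality_filter(r.seq, r.qual, params)
        if reason is None:
            kept.append(r)
        else:
            reasons[reason] += 1
    return kept, reasons


def prep_report(raw_count: int, merged_count: int, kept_count: int, sample_id: str = "sample") -> pd.DataFrame:
    """One-row per-sample report with merge and keep rates."""
    if min(raw_count, merged_count, kept_count) < 0:
        raise ValueError("counts must be >= 0")
    if kept_count > merged_count or merged_count > raw_count:
        raise ValueError(
            f"counts must satisfy kept <= merged <= raw, got {kept_count} <= {merged_count} <= {raw_count}"
        )
    if raw_count == 0:
        logger.warning("sample %s: zero raw reads", sample_id)
    merge_rate = merged_count / raw_count if raw_count else 0.0
    keep_rate = kept_count / merged_count if merged_count else 0.0
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "raw": raw_count,
                "merged": merged_count,
                "kept": kept_count,
                "merge_rate": merge_rate,
                "keep_rate": keep_rate,
            }
        ]
    )


def _open_maybe_gz(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual) from a FASTQ file (optionally gzipped)."""
    with _open_maybe_gz(Path(path), "r") as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (id, seq, qual) records as Phred+33 FASTQ; returns record count."""
    n = 0
    with _open_maybe_gz(Path(path), "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
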