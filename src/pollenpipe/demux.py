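"""Dual-index demultiplexing.

Each read pair carries two 8-nt index reads (i1 from the forward oligo, i2
from the reverse).  A pair is assigned to the unique sample whose index
pair it matches — by default with *perfect* matches only, mirroring the
on-instrument demultiplexer's policy.  A relaxed mode accepts up to
``max_mismatch`` Hamming mismatches per index, but any ambiguity (two
samples both within tolerance) sends the pair to "undetermined"; N bases
in index reads count as mismatches.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._util import revcomp, validate_dna

__all__ = [
    "SampleSheet",
    "IndexedReadPair",
    "DemuxResult",
    "parse_samplesheet",
    "demultiplex",
    "read_indexed_pairs",
    "write_demultiplexed",
]

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class SampleSheet:
    """Maps (fwd_index, rev_index) pairs to sample ids.

    sample_ids are unique, index pairs are unique, all indices 8 nt.
    """

    rows: tuple[tuple[str, str, str], ...]  # (sample_id, fwd_index, rev_index)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dup}")
        pairs = [(r[1], r[2]) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (fwd_index, rev_index) pair in sample sheet")
        for sid, f, r in self.rows:
            validate_dna(f, f"fwd_index of {sid}", length=8)
            validate_dna(r, f"rev_index of {sid}", length=8)

    @property
    def sample_ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def pair_lookup(self) -> dict[tuple[str, str], str]:
        return {(f, r): sid for sid, f, r in self.rows}


@dataclass(frozen=True)
class IndexedReadPair:
    id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    i1_seq: str
    i2_seq: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class DemuxResult:
    """Per-sample read counts; sum(per-sample) + undetermined == total."""

    per_sample: dict[str, int]
    undetermined: int
    total: int

    def check(self) -> None:
        if sum(self.per_sample.values()) + self.undetermined != self.total:
            raise AssertionError("demux count conservation violated")


def parse_samplesheet(path: str | Path) -> SampleSheet:
    """Read a CSV sample sheet with columns sample_id, fwd_index, rev_index.

    Sheets written by :func:`pollenpipe.oligos.enumerate_combinations`
    (combo_id/fwd_seq/rev_seq columns) are accepted too.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty sample sheet")
        cols = {c.strip().lower(): c for c in reader.fieldnames}
        id_col = cols.get("sample_id") or cols.get("combo_id")
        f_col = cols.get("fwd_index") or cols.get("fwd_seq")
        r_col = cols.get("rev_index") or cols.get("rev_seq")
        if not (id_col and f_col and r_col):
            raise ValueError(
                f"{path}: need sample_id/fwd_index/rev_index (or combo_id/fwd_seq/rev_seq) columns"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    (
                        row[id_col].strip(),
                        validate_dna(row[f_col].strip(), "fwd_index", length=8),
                        validate_dna(row[r_col].strip(), "rev_index", length=8),
                    )
                )
            except (ValueError, AttributeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: sample sheet has no data rows")
    try:
        return SampleSheet(rows=tuple(rows))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _hamming_or_more(a: str, b: str, cap: int) -> int:
    """Hamming distance, short-circuiting once it exceeds *cap*; N is a mismatch."""
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
            if d > cap:
                return d
    return d


def demultiplex(
    reads: Iterable[IndexedReadPair],
    sheet: SampleSheet,
    max_mismatch: int = 0,
    rc_i2: bool = False,
) -> tuple[DemuxResult, dict[str, list[IndexedReadPair]]]:
    """Assign read pairs to samples by dual-index match.

    A pair goes to sample *s* iff both indices are within ``max_mismatch``
    of *s*'s pair and no other sample also qualifies; everything else —
    no match, or ambiguous match — is "undetermined".  ``rc_i2`` applies a
    reverse complement to the i2 read first, for instruments whose i5
    index is delivered in the opposite orientation.

    Returns the count summary and the per-destination read lists
    (undetermined reads under key "undetermined").
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    exact = sheet.pair_lookup()
    index_len = 8
    buckets: dict[str, list[IndexedReadPair]] = {sid: [] for sid in sheet.sample_ids}
    buckets[UNDETERMINED] = []
    counts = {sid: 0 for sid in sheet.sample_ids}
    undet = 0
    total = 0
    rows = sheet.rows
    for pair in reads:
        total += 1
        i1, i2 = pair.i1_seq, pair.i2_seq
        if rc_i2:
            i2 = revcomp(i2)
        if len(i1) != index_len or len(i2) != index_len:
            raise ValueError(
                f"read {pair.id}: index length {len(i1)}/{len(i2)} differs from sheet ({index_len} nt)"
            )
        dest = UNDETERMINED
        if max_mismatch == 0:
            if "N" not in i1 and "N" not in i2:
                dest = exact.get((i1, i2), UNDETERMINED)
        else:
            hits = []
            for sid, f, r in rows:
                if (
                    _hamming_or_more(i1, f, max_mismatch) <= max_mismatch
                    and _hamming_or_more(i2, r, max_mismatch) <= max_mismatch
                ):
                    hits.append(sid)
                    if len(hits) > 1:
                        break
            if len(hits) == 1:
                dest = hits[0]
        if dest == UNDETERMINED:
            undet += 1
        else:
            counts[dest] += 1
        buckets[dest].append(pair)
    result = DemuxResult(per_sample=counts, undetermined=undet, total=total)
    result.check()
    return result, buckets


def read_indexed_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    i1_path: str | Path | None = None,
    i2_path: str | Path | None = None,
) -> Iterator[IndexedReadPair]:
    """Stream read pairs from FASTQ files.

    With separate I1/I2 files the index reads come from there; without
    them, a Casava-style ``<i1>+<i2>`` token is expected at the end of the
    R1 header comment.
    """
    from .readprep import iter_fastq  # local import, avoids cycle

    r1_iter = iter_fastq(r1_path)
    r2_iter = iter_fastq(r2_path)
    if i1_path is not None and i2_path is not None:
        i1_iter = iter_fastq(i1_path)
        i2_iter = iter_fastq(i2_path)
        for (id1, s1, q1), (id2, s2, q2), (_, i1, _qi1), (_, i2, _qi2) in zip(
            r1_iter, r2_iter, i1_iter, i2_iter
        ):
            yield IndexedReadPair(id1.split()[0], s1, q1, s2, q2, i1, i2)
    else:
        for (id1, s1, q1), (_id2, s2, q2) in zip(r1_iter, r2_iter):
            token = id1.split(":")[-1] if ":" in id1 else ""
            if "+" not in token:
                raise ValueError(
                    f"read {id1}: no I1/I2 files given and no '<i1>+<i2>' header token found"
                )
            i1, i2 = token.split("+", 1)
            yield IndexedReadPair(id1.split()[0], s1, q1, s2, q2, i1, i2)


def write_demultiplexed(
    buckets: dict[str, list[IndexedReadPair]], outdir: str | Path
) -> dict[str, tuple[Path, Path]]:
    """Write per-sample <sample>_R1.fastq / _R2.fastq files."""
    from .readprep import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid, pairs in buckets.items():
        p1 = outdir / f"{sid}_R1.fastq"
        p2 = outdir / f"{sid}_R2.fastq"
        write_fastq(p1, ((p.id, p.r1_seq, p.r1_qual) for p in pairs))
        write_fastq(p2, ((p.id, p.r2_seq, p.r2_qual) for p in pairs))
        paths[sid] = (p1, p2)
    return paths


def demux_stats_frame(result: DemuxResult) -> "pd.DataFrame":
    """Demux counts as a tidy table (one row per sample + undetermined)."""
    import pandas as pd

    rows = [
        {"sample_id": sid, "reads": n, "fraction": n / result.total if result.total else 0.0}
        for sid, n in result.per_sample.items()
    ]
    rows.append(
        {
            "sample_id": UNDETERMINED,
            "reads": result.undetermined,
            "fraction": result.undetermined / result.total if result.total else 0.0,
        }
    )
    return pd.DataFrame(rows)
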