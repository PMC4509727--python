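"""End-to-end convenience: demux → merge → filter → classify → aggregate.

Thin glue over the stage modules, used by the CLI's ``pipeline`` command
and by end-to-end simulation checks.  Each stage keeps its own module as
the authoritative interface; nothing here adds behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .aggregate import AggregateParams, CommunityMatrix, aggregate, drop_low_depth_samples, filter_rare
from .classify import ClassifierParams, KmerModel, classify_sample, train
from .demux import DemuxResult, IndexedReadPair, SampleSheet, demultiplex
from .readprep import FilterParams, MergeParams, filter_reads, merge_sample, prep_report
from .refdb import ReferenceDB

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    demux: DemuxResult
    prep: pd.DataFrame  # per-sample raw/merged/kept counts
    assignments: dict[str, pd.DataFrame]
    matrix: CommunityMatrix  # raw aggregated counts
    filtered: CommunityMatrix  # rare-filtered, low-depth samples dropped
    dropped_samples: list[str]


def run_pipeline(
    pairs: Iterable[IndexedReadPair],
    sheet: SampleSheet,
    db: ReferenceDB,
    classifier_params: ClassifierParams = ClassifierParams(),
    merge_params: MergeParams = MergeParams(),
    filter_params: FilterParams = FilterParams(),
    agg_params: AggregateParams = AggregateParams(),
    max_mismatch: int = 0,
    model: KmerModel | None = None,
    with_cutoff: bool = True,
) -> PipelineResult:
    """Run the full per-sample pipeline on an in-memory read stream."""
    if model is None:
        model = train(db, classifier_params)
    demux_result, buckets = demultiplex(pairs, sheet, max_mismatch=max_mismatch)

    prep_frames = []
    assignments: dict[str, pd.DataFrame] = {}
    for sample_id in sheet.sample_ids:
        sample_pairs = buckets[sample_id]
        merged, _failed = merge_sample(
            ((p.id, p.r1_seq, p.r1_qual, p.r2_seq, p.r2_qual) for p in sample_pairs),
            merge_params,
        )
        kept, _reasons = filter_reads(merged, filter_params)
        prep_frames.append(
            prep_report(len(sample_pairs), len(merged), len(kept), sample_id=sample_id)
        )
        assignments[sample_id] = classify_sample(
            [(r.id, r.seq) for r in kept], model, classifier_params, with_cutoff=with_cutoff
        )

    matrix = aggregate(assignments)
    filtered = filter_rare(matrix, agg_params)
    filtered, dropped = drop_low_depth_samples(filtered, agg_params)
    return PipelineResult(
        demux=demux_result,
        prep=pd.concat(prep_frames, ignore_index=True),
        assignments=assignments,
        matrix=matrix,
        filtered=filtered,
        dropped_samples=dropped,
    )
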