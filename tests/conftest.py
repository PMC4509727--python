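"""Shared fixtures: toy reference databases and a seeded simulated run."""

from __future__ import annotations

import pytest

from pollenpipe.classify import ClassifierParams
from pollenpipe.demux import SampleSheet
from pollenpipe.oligos import synthetic_index_set
from pollenpipe.refdb import Lineage, ReferenceDB
from pollenpipe.simulate import SimParams, simulate_community, simulate_refdb, simulate_run


def make_lineage(order="o1", family="f1", genus="g1", species="s1") -> Lineage:
    return Lineage(("Plantae", "Tracheophyta", "Magnoliopsida", order, family, genus, species))


@pytest.fixture
def toy_db() -> ReferenceDB:
    """Four species in two genera, short hand-written sequences."""
    return ReferenceDB(
        [
            ("seq1", "ACGTACGTACGTACGTACGT", make_lineage(genus="g1", species="s1")),
            ("seq2", "ACGTACGTACGTACGTTTTT", make_lineage(genus="g1", species="s2")),
            ("seq3", "GGGGCCCCGGGGCCCCGGGG", make_lineage(genus="g2", species="s3")),
            ("seq4", "GGGGCCCCGGGGCCCCAAAA", make_lineage(genus="g2", species="s4")),
        ]
    )


@pytest.fixture(scope="session")
def sim_db():
    """Hierarchical simulated reference: 5 orders x 2 x 2 x 2 = 40 species."""
    return simulate_refdb(SimParams(rng_seed=7))


@pytest.fixture(scope="session")
def small_run(sim_db):
    """A 2-sample, 300-reads-per-sample seeded run with 1% error."""
    params = SimParams(rng_seed=7, reads_per_sample=300)
    comms = {
        f"s{i + 1:02d}": simulate_community(
            sim_db, n_taxa=10, sigma=1.0, seed=70 + i, reads_per_sample=300
        )
        for i in range(2)
    }
    fwd = synthetic_index_set(16, "forward", seed=7)
    rev = synthetic_index_set(24, "reverse", seed=7)
    return simulate_run(sim_db, comms, fwd, rev, params)


@pytest.fixture(scope="session")
def small_sheet(small_run) -> SampleSheet:
    return SampleSheet(
        rows=tuple(
            (r.sample_id, r.fwd_index, r.rev_index) for r in small_run.samplesheet.itertuples()
        )
    )
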