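from __future__ import annotations

import pytest

from vamir import annotate, conserved, sequence_io
from vamir.simulate import SimConfig, simulate


SMALL_SIM = SimConfig(
    seed=7,
    n_mirnas=10,
    expression_meanlog=3.2,
    expression_sdlog=1.2,
    n_decoys=5,
    low_quality_fraction=0.0,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fully deterministic synthetic bundle shared by unit tests."""
    return simulate(SMALL_SIM)


@pytest.fixture(scope="session")
def small_pipeline_state(small_bundle):
    """Cleaned, collapsed, mapped and conserved-matched state of the small
    bundle, computed once per session."""
    b = small_bundle
    reads = [sequence_io.RawRead(rid, seq, qual) for rid, seq, qual in b.reads]
    reads = sequence_io.trim_adapters(reads, b.config.adapter3)
    reads = sequence_io.quality_filter(reads)
    reads = sequence_io.length_filter(reads, 15, 30)
    tags = sequence_io.polya_filter(sequence_io.collapse_reads(reads))
    annotate.map_to_genome(tags, b.genome)
    known = [
        conserved.KnownMature.from_header(r.mirna_id, r.mature_seq)
        for _, r in b.truth.mirnas.iterrows()
    ]
    assignments = conserved.match_known(tags, known)
    return {"bundle": b, "tags": tags, "known": known, "assignments": assignments}
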