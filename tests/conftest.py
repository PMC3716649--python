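from __future__ import annotations

import numpy as np
import pytest

from amphap.align import align_read, build_pileup
from amphap.calls import accepted_event_set, call_pileup, combine_reports
from amphap.scenarios import build_demo_scenario
from amphap.seqio import QualRead, ReferenceRegion
from amphap.simulate import (
    ErrorModel,
    ReadLengthModel,
    plant_variants,
    sample_reads,
)


def make_read(seq: str, q: int = 40, rid: str = "r") -> QualRead:
    return QualRead(rid, seq, tuple([q] * len(seq)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def demo_scenario():
    return build_demo_scenario(1)


@pytest.fixture(scope="session")
def demo_pool(demo_scenario):
    haps, truth = plant_variants(demo_scenario.panel, demo_scenario.specs)
    return haps, truth


@pytest.fixture(scope="session")
def demo_run(demo_scenario, demo_pool):
    """One zero-error library at depth 400 (full-length reads), fully
    analysed: shared by haplotype/consequence/intron tests."""
    haps, truth = demo_pool
    region = demo_scenario.region
    reads, sources = sample_reads(
        haps, 400, ErrorModel(),
        ReadLengthModel(mean=2 * len(region), sd=30), seed=9)
    alignments = [a for a in (align_read(r, region) for r in reads) if a]
    pileup = build_pileup(alignments)
    calls = call_pileup(pileup, region)
    combined, summary = combine_reports(
        {"L1": calls, "L2": calls, "L3": calls})
    return {
        "region": region,
        "haps": haps,
        "truth": truth,
        "reads": reads,
        "sources": sources,
        "alignments": alignments,
        "pileup": pileup,
        "calls": calls,
        "combined": combined,
        "summary": summary,
        "accepted": accepted_event_set(combined),
    }
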