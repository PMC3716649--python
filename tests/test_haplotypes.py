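"""Haplotype grouping, allele assignment and frequency-table tests."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from amphap.align import align_read, build_pileup
from amphap.calls import accepted_event_set, call_pileup, combine_reports
from amphap.haplotypes import (
    AmpliconVariant,
    GroupConfig,
    assign_allele,
    consensus_from_events,
    frequency_table,
    group_reads,
    variant_from_sequence,
)
from amphap.seqio import AllelePanelEntry, ReferenceRegion
from amphap.simulate import (
    ErrorModel,
    PlantedVariant,
    ReadLengthModel,
    apply_events,
    make_panel,
    plant_variants,
    reference_region,
    sample_reads,
)

from conftest import make_read


def hap_truth_keys(hap):
    keys = []
    for p, r, a in hap.events_vs_reference:
        if r and a:
            keys.append((p, a))
        elif r == "":
            keys.append((p, "+" + a))
        else:
            keys.extend((p + i, "-" + r[i]) for i in range(len(r)))
    return tuple(sorted(keys))


class TestGroupReads:
    def test_reference_only_pool(self):
        region = ReferenceRegion("r", "ACGTACGTACGT" * 10)
        alns = [align_read(make_read(region.sequence, rid=f"r{i}"), region)
                for i in range(20)]
        variants = group_reads(alns, region, region.rp_interval, set())
        assert len(variants) == 1
        v = variants[0]
        assert v.events == ()
        assert v.frequency_pct == 100.0
        assert v.consensus == region.sequence
        assert v.variant_id.endswith(".type")

    def test_recovery_exact_at_zero_error(self, demo_run):
        """Recovered event strings equal planted event lists and frequencies
        equal realised source fractions exactly."""
        variants = group_reads(demo_run["alignments"], demo_run["region"],
                               demo_run["region"].rp_interval,
                               demo_run["accepted"])
        counts = Counter(demo_run["sources"])
        n = sum(counts.values())
        expected = {hap_truth_keys(h): counts[h.label]
                    for h in demo_run["haps"]}
        got = {v.events: v.read_count for v in variants}
        assert got == expected
        for v in variants:
            assert v.frequency_pct == pytest.approx(100 * got[v.events] / n)

    def test_recovery_within_3se_of_planted(self, demo_run):
        variants = group_reads(demo_run["alignments"], demo_run["region"],
                               demo_run["region"].rp_interval,
                               demo_run["accepted"])
        n = len(demo_run["sources"])
        planted = {hap_truth_keys(h): h.frequency for h in demo_run["haps"]}
        for v in variants:
            p = planted[v.events]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(v.frequency_pct / 100 - p) <= 3 * se + 1e-12

    def test_consensus_regenerable(self, demo_run):
        region = demo_run["region"]
        variants = group_reads(demo_run["alignments"], region,
                               region.rp_interval, demo_run["accepted"])
        haps = {hap_truth_keys(h): h for h in demo_run["haps"]}
        for v in variants:
            assert v.consensus == haps[v.events].sequence

    def test_sum_to_100(self, demo_run):
        variants = group_reads(demo_run["alignments"], demo_run["region"],
                               demo_run["region"].rp_interval,
                               demo_run["accepted"])
        assert sum(v.frequency_pct for v in variants) == pytest.approx(100.0)

    def test_no_full_span_reads(self):
        region = ReferenceRegion("r", "ACGTACGTACGT" * 20)
        short = align_read(make_read(region.sequence[:60]), region)
        assert group_reads([short], region, region.rp_interval, set()) == []

    def test_min_support_merge_and_floor(self):
        """Singletons merge into the nearest larger group; a 0.1% variant
        with 2 supporting reads survives."""
        region = ReferenceRegion("r", "ACGTACGTACGT" * 10)
        seq = region.sequence
        alt15 = "A" if seq[14] != "A" else "C"
        variant_seq = seq[:14] + alt15 + seq[15:]
        accepted = {(15, alt15)}
        alns = []
        for i in range(1996):
            alns.append(align_read(make_read(seq, rid=f"w{i}"), region))
        for i in range(2):
            alns.append(align_read(make_read(variant_seq, rid=f"v{i}"),
                                   region))
        # two singleton sequencing errors at a non-accepted position
        err = seq[:29] + ("G" if seq[29] != "G" else "T") + seq[30:]
        alns.append(align_read(make_read(err, rid="e1"), region))
        variants = group_reads(alns, region, region.rp_interval, accepted)
        by_events = {v.events: v for v in variants}
        assert set(by_events) == {(), ((15, alt15),)}
        assert by_events[((15, alt15),)].read_count == 2
        assert by_events[((15, alt15),)].frequency_pct == pytest.approx(0.1,
                                                                        abs=0.01)
        # the error read was absorbed by the type group
        assert by_events[()].read_count == 1997

    def test_structural_three_utr_lengths(self):
        """Three co-amplified region variants of 124, 103 and 94 nt at equal
        thirds are recovered as three variants of those lengths."""
        rng = np.random.default_rng(8)
        seq124 = "".join(rng.choice(list("ACGT"), size=124))
        # avoid shiftable deletions: delete blocks whose flanks differ
        region = ReferenceRegion("utr", seq124)
        v103 = seq124[:40] + seq124[61:]   # 21-nt deletion
        v94 = seq124[:70] + seq124[100:]   # 30-nt deletion
        pools = [seq124, v103, v94]
        # large deletions push identity below the homeolog default; relax it
        from amphap.align import AlignConfig

        cfg = AlignConfig(min_identity=0.60)
        alns = []
        for i in range(150):
            alns.append(align_read(make_read(pools[i % 3], rid=f"r{i}"),
                                   region, cfg))
        assert all(a is not None for a in alns)
        calls = call_pileup(build_pileup(alns), region)
        combined, _ = combine_reports({"only": calls})
        accepted = accepted_event_set(combined)
        variants = group_reads(alns, region, region.rp_interval, accepted)
        lengths = sorted(len(v.consensus) for v in variants)
        assert lengths == [94, 103, 124]
        for v in variants:
            assert v.frequency_pct == pytest.approx(100 / 3, abs=1.0)


class TestAssignAllele:
    panel = [
        AllelePanelEntry("allele-A1a", "A", "ACGTACGTACGTACGTACGTGGCCAAGG"),
        AllelePanelEntry("allele-B1a", "B", "ACGTACGTACTTACGTACGTGGCCAAGG"),
        AllelePanelEntry("allele-D1a", "D", "AGGTACGAACGTACGAACGTGGCCTAGG"),
    ]

    def mk(self, consensus):
        return AmpliconVariant("amp", (), 10, 100.0, consensus)

    def test_identical_consensus(self):
        v = assign_allele(self.mk(self.panel[1].sequence), self.panel)
        assert v.allele_name == "allele-B1a"
        assert v.genome_label == "B"
        assert v.identity_pct == 100.0
        assert not v.ambiguous

    def test_tie_is_ambiguous_lexicographic(self):
        two = [AllelePanelEntry("x-allele", "A", "ACGTACGTACGT"),
               AllelePanelEntry("a-allele", "B", "ACGTACGTACGT")]
        v = assign_allele(self.mk("ACGTACGTACGT"), two)
        assert v.ambiguous
        assert v.allele_name == "a-allele"

    def test_divergence_separation(self, rng):
        """~3% from the true source, >=8% from the others -> correct genome."""
        base = "".join(rng.choice(list("ACGT"), size=200))
        def mutate(s, k, seed):
            r = np.random.default_rng(seed)
            s = list(s)
            for pos in r.choice(len(s), size=k, replace=False):
                s[pos] = str(r.choice([b for b in "ACGT" if b != s[pos]]))
            return "".join(s)
        panel = [
            AllelePanelEntry("true-src", "A", base),
            AllelePanelEntry("far-1", "B", mutate(base, 20, 1)),
            AllelePanelEntry("far-2", "D", mutate(base, 22, 2)),
        ]
        consensus = mutate(base, 6, 3)
        v = assign_allele(self.mk(consensus), panel)
        assert v.allele_name == "true-src"
        assert v.genome_label == "A"
        assert v.identity_pct >= 96.0
        assert not v.ambiguous

    def test_empty_panel(self):
        with pytest.raises(ValueError):
            assign_allele(self.mk("ACGT"), [])


class TestFrequencyTable:
    def mk(self, events, freq, vid):
        return AmpliconVariant("amp", events, 10, freq, "ACGT",
                               variant_id=vid)

    def test_single_cell(self):
        df = frequency_table({"lib1": [self.mk((), 100.0, "t")]})
        assert df.loc["t", "lib1"] == 100.0

    def test_absent_variant_zero(self):
        v = self.mk(((5, "T"),), 40.0, "v1")
        t = self.mk((), 60.0, "t")
        df = frequency_table({
            "lib1": [t, v], "lib2": [t, v],
            "lib3": [self.mk((), 100.0, "t")],
        })
        assert df.loc["v1", "lib3"] == 0.0
        assert df.loc["v1", "lib1"] == 40.0

    def test_columns_sum_to_100(self, demo_run):
        variants = group_reads(demo_run["alignments"], demo_run["region"],
                               demo_run["region"].rp_interval,
                               demo_run["accepted"])
        df = frequency_table({"L1": variants})
        assert df["L1"].sum() == pytest.approx(100.0)


def test_compensation_property(demo_scenario):
    """Raising one planted variant's share lowers the type variant's
    recovered share correspondingly."""
    region = demo_scenario.region
    panel = demo_scenario.panel
    base_ev = demo_scenario.planted["snps"][1]

    def recovered_type_freq(f_variant, seed):
        specs = (
            PlantedVariant("B", (base_ev,), f_variant, "v"),
            PlantedVariant("B", (), 1 - f_variant, "t"),
        )
        haps, _ = plant_variants(panel, specs)
        reads, _ = sample_reads(haps, 250, ErrorModel(),
                                ReadLengthModel(mean=2 * len(region), sd=20),
                                seed=seed)
        alns = [a for a in (align_read(r, region) for r in reads) if a]
        calls = call_pileup(build_pileup(alns), region)
        combined, _ = combine_reports({"x": calls})
        variants = group_reads(alns, region, region.rp_interval,
                               accepted_event_set(combined))
        return next(v.frequency_pct for v in variants if v.events == ())

    low = recovered_type_freq(0.3, seed=4)
    high = recovered_type_freq(0.6, seed=4)
    assert high < low
    assert low - high == pytest.approx(30.0, abs=10.0)


def test_variant_from_sequence_round_trip(demo_run):
    region = demo_run["region"]
    hap = next(h for h in demo_run["haps"] if h.label == "hap-main")
    out = variant_from_sequence(hap.sequence, region)
    assert out is not None
    variant, interval = out
    assert variant.consensus == hap.sequence
    assert variant.events == hap_truth_keys(hap)
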