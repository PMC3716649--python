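"""Simulator tests: panel generation, planting, truth, and read sampling."""

from __future__ import annotations

import io

import numpy as np
import pytest
from Bio import Align

from amphap.consequence import translate
from amphap.haplotypes import variant_from_sequence
from amphap.seqio import revcomp, write_fastq
from amphap.simulate import (
    ErrorModel,
    PlantedVariant,
    ReadLengthModel,
    TruthError,
    apply_events,
    make_panel,
    merge_events,
    plant_variants,
    reference_region,
    sample_reads,
    validate_events,
)


def pairwise_identity(a: str, b: str) -> float:
    """Oracle: global alignment identity (match/mismatch only scoring)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    t, q = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(t, q) if x == y and x != "-")
    return matches / len(t)


class TestEvents:
    def test_apply_substitution_deletion_insertion(self):
        seq = "ACGTACGT"
        assert apply_events(seq, [(2, "C", "G")]) == "AGGTACGT"
        assert apply_events(seq, [(3, "GTA", "")]) == "ACCGT"
        assert apply_events(seq, [(4, "", "TTT")]) == "ACGTTTTACGT"

    def test_ref_mismatch_raises(self):
        with pytest.raises(TruthError):
            apply_events("ACGT", [(2, "G", "T")])

    def test_overlap_raises(self):
        with pytest.raises(TruthError):
            validate_events([(2, "CG", ""), (3, "G", "A")])

    def test_positions_strictly_increasing(self):
        with pytest.raises(TruthError):
            validate_events([(5, "A", "C"), (5, "A", "G")])

    def test_merge_sorted(self):
        merged = merge_events([(10, "A", "C")], [(2, "", "TT")])
        assert merged == ((2, "", "TT"), (10, "A", "C"))


class TestMakePanel:
    def test_zero_divergence_identical_backbones(self):
        panel = make_panel(seed=5, length=400, divergence=0.0)
        seqs = {h.backbone_seq for h in panel}
        assert len(seqs) == 1
        assert all(not h.divergence_events for h in panel)

    def test_determinism(self):
        a = make_panel(seed=9, length=500, divergence=0.05)
        b = make_panel(seed=9, length=500, divergence=0.05)
        assert [h.backbone_seq for h in a] == [h.backbone_seq for h in b]
        assert [h.divergence_events for h in a] == [h.divergence_events for h in b]

    def test_mean_pairwise_identity_at_0p05(self):
        panel = make_panel(seed=2, length=1902, divergence=0.05)
        idents = []
        for i in range(3):
            for j in range(i + 1, 3):
                idents.append(pairwise_identity(panel[i].backbone_seq,
                                                panel[j].backbone_seq))
        assert np.mean(idents) == pytest.approx(0.95, abs=0.01)

    def test_lengths_within_band(self):
        panel = make_panel(seed=3, length=800, divergence=0.06)
        lengths = [len(h.backbone_seq) for h in panel]
        assert max(lengths) - min(lengths) <= 30

    def test_atg_at_cds_start(self):
        for seed in (1, 2, 3):
            for h in make_panel(seed=seed, length=400, divergence=0.08):
                s = h.backbone_seq
                assert s[h.cds_start - 1:h.cds_start + 2] == "ATG"

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_panel(seed=1, length=100, divergence=0.05)
        with pytest.raises(ValueError):
            make_panel(seed=1, length=400, divergence=0.5)


class TestPlantVariants:
    def test_empty_specs_gives_backbones_at_thirds(self):
        panel = make_panel(seed=4, length=400, divergence=0.04)
        haps, truth = plant_variants(panel, ())
        assert len(haps) == 3
        assert all(h.frequency == pytest.approx(1 / 3) for h in haps)
        backbones = {h.genome_label: h.backbone_seq for h in panel}
        for h in haps:
            assert h.sequence == backbones[h.genome_label]

    def test_stop_creating_snp_truncates_truth_protein(self):
        panel = make_panel(seed=6, length=400, divergence=0.0)
        region = reference_region(panel)
        seq = region.sequence
        cds = region.cds_start_rp
        # find a codon whose single-base change gives TAG
        target = None
        for ci in range(2, 40):
            p = cds + 3 * ci
            codon = seq[p - 1:p + 2]
            for k, want in enumerate("TAG"):
                cand = codon[:k] + want + codon[k + 1:]
                if cand == "TAG" and codon != "TAG":
                    target = (p + k, codon[k], want, ci)
                    break
            if target:
                break
        rp, ref, alt, ci = target
        specs = (PlantedVariant("B", ((rp, ref, alt),), 1.0, "null"),)
        haps, truth = plant_variants(panel, specs)
        prot = translate(haps[0].sequence[cds - 1:])
        assert prot[ci] == "*"
        assert "*" not in prot[:ci]

    def test_72nt_gt_ag_insertion_truth_interval(self):
        panel = make_panel(seed=7, length=400, divergence=0.0)
        region = reference_region(panel)
        ins = "GT" + "AC" * 34 + "AG"
        assert len(ins) == 72
        anchor = 150
        while region.sequence[anchor - 1] == "G":
            anchor += 1
        specs = (PlantedVariant("B", ((anchor, "", ins),), 0.5, "intron"),
                 PlantedVariant("B", (), 0.5, "type"))
        haps, truth = plant_variants(panel, specs)
        by_label = {h.label: h for h in haps}
        assert len(by_label["intron"].sequence) == len(region) + 72
        assert truth.intron_intervals == ((anchor, 72, "canonical"),)

    def test_frequencies_must_sum_to_one(self):
        panel = make_panel(seed=8, length=400, divergence=0.0)
        with pytest.raises(TruthError):
            plant_variants(panel, (PlantedVariant("B", (), 0.6, "a"),
                                   PlantedVariant("B", (), 0.3, "b")))

    def test_planted_ref_mismatch_raises(self):
        panel = make_panel(seed=8, length=400, divergence=0.0)
        seq = panel[1].backbone_seq
        wrong = "A" if seq[99] != "A" else "C"
        with pytest.raises(TruthError):
            plant_variants(panel, (PlantedVariant(
                "B", ((100, wrong, "G" if wrong != "G" else "T"),), 1.0,
                "bad"),))

    def test_round_trip_alignment_recovers_planted_events(self, demo_pool,
                                                          demo_scenario):
        """Planting then aligning with zero error reproduces the planted
        event list for every haplotype."""
        haps, truth = demo_pool
        region = demo_scenario.region
        for hap in haps:
            out = variant_from_sequence(hap.sequence, region)
            assert out is not None
            variant, _ = out
            expected = []
            for p, r, a in hap.events_vs_reference:
                if r and a:
                    expected.append((p, a))
                elif r == "":
                    expected.append((p, "+" + a))
                else:
                    expected.extend((p + i, "-" + r[i])
                                    for i in range(len(r)))
            assert variant.events == tuple(sorted(expected)), hap.label


class TestSampleReads:
    def _pool(self, freqs=(1.0,), seed=3):
        panel = make_panel(seed=seed, length=400, divergence=0.0)
        region = reference_region(panel)
        seq = region.sequence
        specs = []
        for i, f in enumerate(freqs):
            if i == 0:
                specs.append(PlantedVariant("B", (), f, "h0"))
            else:
                pos = 50 + 17 * i
                alt = "A" if seq[pos - 1] != "A" else "C"
                specs.append(PlantedVariant(
                    "B", ((pos, seq[pos - 1], alt),), f, f"h{i}"))
        return plant_variants(panel, tuple(specs))

    def test_zero_error_reads_are_substrings(self):
        haps, _ = self._pool()
        reads, sources = sample_reads(haps, 50, ErrorModel(),
                                      ReadLengthModel(200, 30, 100), seed=1)
        hap = haps[0].sequence
        for r in reads:
            assert r.seq in hap or revcomp(r.seq) in hap

    def test_depth_zero(self):
        haps, _ = self._pool()
        reads, sources = sample_reads(haps, 0, seed=1)
        assert reads == [] and sources == []

    def test_multinomial_within_3se_at_depth_10000(self):
        haps, _ = self._pool(freqs=(0.6, 0.3, 0.1), seed=5)
        reads, sources = sample_reads(haps, 10000, ErrorModel(),
                                      ReadLengthModel(300, 40, 100), seed=11)
        n = len(sources)
        for hap in haps:
            p = hap.frequency
            se = np.sqrt(p * (1 - p) / n)
            observed = sources.count(hap.label) / n
            assert abs(observed - p) <= 3 * se

    def test_determinism_byte_identical_fastq(self):
        haps, _ = self._pool(freqs=(0.7, 0.3), seed=6)
        outs = []
        for _ in range(2):
            reads, _ = sample_reads(haps, 100,
                                    ErrorModel(substitution_rate=0.01,
                                               homopolymer_indel_rate=0.01),
                                    ReadLengthModel(250, 40, 100), seed=21)
            buf = io.StringIO()
            write_fastq(reads, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_qualities_clipped_and_lengths_match(self):
        haps, _ = self._pool()
        reads, _ = sample_reads(haps, 60,
                                ErrorModel(substitution_rate=0.02,
                                           homopolymer_indel_rate=0.02),
                                ReadLengthModel(200, 50, 100), seed=2)
        for r in reads:
            assert len(r.seq) == len(r.quals)
            assert all(2 <= q <= 40 for q in r.quals)

    def test_error_model_validation_and_cap(self):
        with pytest.raises(ValueError):
            ErrorModel(substitution_rate=1.5)
        m = ErrorModel(homopolymer_indel_rate=0.3, homopolymer_multiplier=3.0)
        assert m.indel_prob(1) == pytest.approx(0.3)
        assert m.indel_prob(5) == 0.5  # capped

    def test_negative_depth_rejected(self):
        haps, _ = self._pool()
        with pytest.raises(ValueError):
            sample_reads(haps, -1)


def test_truth_event_freqs_consistent(demo_pool):
    haps, truth = demo_pool
    # recompute from the haplotype table: frequencies per (rp, alt) key
    recomputed = {}
    for h in haps:
        for p, r, a in h.events_vs_reference:
            if r and a:
                keys = [(p, a)]
            elif r == "":
                keys = [(p, "+" + a)]
            else:
                keys = [(p + i, "-" + r[i]) for i in range(len(r))]
            for k in keys:
                recomputed[k] = recomputed.get(k, 0.0) + h.frequency
    assert recomputed.keys() == truth.event_freqs.keys()
    for k in recomputed:
        assert truth.event_freqs[k] == pytest.approx(recomputed[k])
    # non-reference fractions never exceed the total planted fraction
    assert all(0 < f <= 1 for f in truth.nonref_fraction.values())
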