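"""Deterministic validation scenario: a hexaploid pool carrying one of every
variant class the pipeline must recover.

The builder selects planting sites on a generated homeolog panel so that

* every planted event is clear of divergence events and of other planted
  events (no representational ambiguity after indel left-alignment),
* the nonsense SNP sits inside the configured DELLA-style protein interval,
* the 72-nt GT..AG insertion carries an in-frame internal stop (so the frame
  check flags the variant even though 72 is a multiple of three),
* the AC..AT retained-segment case is planted in aligner-normal form
  (single-base deletion plus substitutions) chosen so that the planted
  representation is the unique optimal alignment.

Every choice is a pure function of the seed, so fixtures regenerate
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import ReferenceRegion
from .simulate import (
    Event,
    HomeologPanel,
    PlantedVariant,
    _left_aligned_ok,
    make_panel,
    reference_region,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

POOL_FREQUENCIES = {
    "main": 0.44,       # B backbone + 2 SNPs + in-frame codon deletion
    "null": 0.25,       # A backbone + nonsense SNP (DELLA) + missense SNP
    "wild_d": 0.15,     # unmodified D backbone
    "intron72": 0.10,   # B backbone + 72-nt GT..AG insertion + missense SNP
    "acat": 0.06,       # B backbone + AC..AT retained-segment case
}


@dataclass(frozen=True)
class DemoScenario:
    seed: int
    panel: list[HomeologPanel]
    region: ReferenceRegion
    specs: tuple[PlantedVariant, ...]
    della_interval: tuple[int, int]
    planted: dict

    def specs_by_library(self, n_libraries: int = 3) -> dict:
        return {f"lib{i + 1}": self.specs for i in range(n_libraries)}


class _SitePicker:
    """Scans reference codons for plantable sites, keeping planted loci and
    divergence loci apart."""

    def __init__(self, panel: Sequence[HomeologPanel],
                 region: ReferenceRegion):
        self.seq = region.sequence
        self.cds = region.cds_start_rp
        taken: set[int] = set()
        for h in panel:
            for p, r, _a in h.divergence_events:
                hi = p + max(len(r), 1) - 1
                taken.update(range(p - 5, hi + 6))
        self.taken = taken

    def clear(self, lo: int, hi: int) -> bool:
        return not any(q in self.taken for q in range(lo, hi + 1))

    def reserve(self, lo: int, hi: int) -> None:
        self.taken.update(range(lo - 7, hi + 8))

    def codon(self, ci: int) -> tuple[int, str]:
        """1-based codon index -> (RP of first base, codon string)."""
        p = self.cds + 3 * (ci - 1)
        return p, self.seq[p - 1:p + 2]

    @property
    def n_codons(self) -> int:
        return (len(self.seq) - self.cds + 1) // 3

    def find_nonsense(self) -> tuple[int, str, str]:
        """(RP, ref base, alt base) of a stop-creating substitution."""
        for ci in range(3, self.n_codons - 2):
            p, codon = self.codon(ci)
            if codon in _STOPS or not self.clear(p, p + 2):
                continue
            for k in range(3):
                for alt in _BASES:
                    if alt == codon[k]:
                        continue
                    if codon[:k] + alt + codon[k + 1:] in _STOPS:
                        self.reserve(p, p + 2)
                        return p + k, codon[k], alt
        raise RuntimeError("no nonsense site available")

    def find_snp(self, synonymous: bool) -> tuple[int, str, str]:
        from .consequence import translate

        for ci in range(3, self.n_codons - 2):
            p, codon = self.codon(ci)
            if codon in _STOPS or not self.clear(p, p + 2):
                continue
            for k in range(3):
                for alt in _BASES:
                    if alt == codon[k]:
                        continue
                    mutated = codon[:k] + alt + codon[k + 1:]
                    if mutated in _STOPS:
                        continue
                    same = translate(mutated) == translate(codon)
                    if same == synonymous:
                        self.reserve(p, p + 2)
                        return p + k, codon[k], alt
        raise RuntimeError("no SNP site available")

    def find_inframe_del(self) -> Event:
        """Deletion of one whole codon, left-aligned by construction."""
        for ci in range(3, self.n_codons - 2):
            p, codon = self.codon(ci)
            if not self.clear(p - 1, p + 3):
                continue
            ev: Event = (p, codon, "")
            if _left_aligned_ok(self.seq, ev):
                self.reserve(p, p + 2)
                return ev
        raise RuntimeError("no in-frame deletion site available")

    def find_insertion_anchor(self, last_base: str) -> int:
        """A codon-end anchor whose base differs from the insertion's last
        base (keeps the insertion left-aligned)."""
        for ci in range(3, self.n_codons - 2):
            p, _codon = self.codon(ci)
            anchor = p + 2  # end of codon ci
            if not self.clear(anchor - 1, anchor + 3):
                continue
            if self.seq[anchor - 1] != last_base:
                self.reserve(anchor, anchor + 1)
                return anchor
        raise RuntimeError("no insertion anchor available")

    def find_acat_site(self) -> tuple[Event, ...] | None:
        """Plant, in aligner-normal form, a single-base deletion plus
        substitutions that leave an AC..AT 5-mer replacing a reference 6-mer.

        Returns the events, or None when no site admits a uniquely optimal
        representation.
        """
        seq = self.seq
        for ci in range(3, self.n_codons - 3):
            p, _codon = self.codon(ci)
            anchor = p + 2          # codon boundary: 6-mer = anchor+1..anchor+6
            a = anchor
            if not self.clear(a, a + 7):
                continue
            six = seq[a:a + 6]      # 0-based slice = RP a+1..a+6
            target = "AC" + six[3] + "AT"   # var[2] pairs with ref 6-mer[3]
            # deletion of 6-mer position 1, remaining five pair with target
            pair1 = six[1:]
            m1 = sum(1 for x, y in zip(pair1, target) if x != y)
            unique = True
            for j in range(1, 6):   # delete 6-mer position j+1 instead
                pairing = six[:j] + six[j + 1:]
                mj = sum(1 for x, y in zip(pairing, target) if x != y)
                if mj <= m1:
                    unique = False
                    break
            ev_del: Event = (a + 1, six[0], "")
            if not unique or m1 > 3 or not _left_aligned_ok(seq, ev_del):
                continue
            events = [ev_del]
            for i in range(5):
                if pair1[i] != target[i]:
                    events.append((a + 2 + i, pair1[i], target[i]))
            self.reserve(a, a + 7)
            return tuple(events)
        return None


def build_demo_scenario(seed: int, length: int = 420,
                        divergence: float = 0.05) -> DemoScenario:
    """Panel + planted specs for the four-haplotype validation pool.

    Retries internally (deterministically) when a drawn panel does not admit
    all planting sites, so any seed yields a scenario.
    """
    for attempt in range(40):
        panel_seed = seed + 1000003 * attempt
        panel = make_panel(panel_seed, length, divergence)
        region = reference_region(panel)
        picker = _SitePicker(panel, region)
        try:
            scenario = _plant(seed, panel, region, picker)
        except RuntimeError:
            continue
        if scenario is not None:
            return scenario
    raise RuntimeError(f"no usable scenario for seed {seed}")


def _plant(seed: int, panel: list[HomeologPanel], region: ReferenceRegion,
           picker: _SitePicker) -> DemoScenario | None:
    rng = np.random.default_rng(seed + 17)
    nonsense_rp, nonsense_ref, nonsense_alt = picker.find_nonsense()
    snp_a = picker.find_snp(synonymous=False)
    snp_b_syn = picker.find_snp(synonymous=True)
    snp_b_mis = picker.find_snp(synonymous=False)
    snp_i = picker.find_snp(synonymous=False)
    del3 = picker.find_inframe_del()
    mid = "".join(rng.choice(list(_BASES), size=64))
    ins_seq = "GTCTAG" + mid + "AG"
    assert len(ins_seq) == 72
    ins_anchor = picker.find_insertion_anchor(ins_seq[-1])
    acat_events = picker.find_acat_site()
    if acat_events is None:
        return None

    def sub(site: tuple[int, str, str]) -> Event:
        return (site[0], site[1], site[2])

    f = POOL_FREQUENCIES
    # the intron-bearing haplotypes sit on the reference genome so that the
    # spliced translation is compared against a divergence-free baseline
    specs = (
        PlantedVariant("B", tuple(sorted(
            [sub(snp_b_syn), sub(snp_b_mis), del3])), f["main"], "hap-main"),
        PlantedVariant("A", tuple(sorted(
            [(nonsense_rp, nonsense_ref, nonsense_alt), sub(snp_a)])),
            f["null"], "hap-null"),
        PlantedVariant("D", (), f["wild_d"], "hap-wildD"),
        PlantedVariant("B", tuple(sorted(
            [(ins_anchor, "", ins_seq), sub(snp_i)])),
            f["intron72"], "hap-intron72"),
        PlantedVariant("B", acat_events, f["acat"], "hap-acat"),
    )
    nonsense_codon = (nonsense_rp - region.cds_start_rp) // 3 + 1
    della = (max(1, nonsense_codon - 4), nonsense_codon + 4)
    planted = {
        "nonsense": {"rp": nonsense_rp, "ref": nonsense_ref,
                     "alt": nonsense_alt, "codon": nonsense_codon},
        "snps": [sub(snp_a), sub(snp_b_syn), sub(snp_b_mis), sub(snp_i),
                 (nonsense_rp, nonsense_ref, nonsense_alt)],
        "del3": del3,
        "ins72": {"anchor": ins_anchor, "seq": ins_seq},
        "acat": {"events": acat_events,
                 "del_rp": acat_events[0][0]},
        "frequencies": dict(f),
    }
    return DemoScenario(seed, panel, region, specs, della, planted)
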