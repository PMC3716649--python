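"""Putative spliceosomal-intron detection in amplicon variant sequences.

A variant whose coding length change is not a multiple of three, or which
gains a premature stop, is frame-disrupted.  Candidate intron intervals on
the variant consensus are those whose in-silico removal restores the frame
(net length change back to 0 mod 3) and removes every premature stop.
GT..AG-bounded candidates are canonical; all others are non-canonical and
rank below them.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Sequence

from .consequence import _cds_frame_offset, translate
from .haplotypes import AmpliconVariant, consensus_position_to_rp
from .seqio import ReferenceRegion


class ConflictError(ValueError):
    """Overlapping intron calls handed to the splicer."""


@dataclass(frozen=True)
class DisruptionReport:
    variant_id: str
    net_change_nt: int
    mod3: int
    premature_stop_codon: int | None  # 1-based codon index in the variant frame
    frame_disrupted: bool             # net change not a multiple of 3

    @property
    def disrupted(self) -> bool:
        return self.frame_disrupted or self.premature_stop_codon is not None


@dataclass(frozen=True)
class IntronCall:
    variant_id: str
    start: int            # 1-based on the variant consensus, inclusive
    length: int
    rp_start: int | None
    rp_end: int | None
    donor: str            # 5' boundary dinucleotide
    acceptor: str         # 3' boundary dinucleotide
    klass: str            # "canonical" | "non_canonical"
    frame_restored: bool
    stops_removed: bool
    residues_deleted: int
    similarity: float     # spliced-translation similarity to the reference
    rank: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def _segment_setup(variant: AmpliconVariant, region: ReferenceRegion,
                   amplicon_interval: tuple[int, int] | None):
    if amplicon_interval is None:
        rp_start, rp_end = region.rp_interval
    else:
        rp_start, rp_end = amplicon_interval
    offset, _first = _cds_frame_offset(region, rp_start)
    shift = 0
    for rp, alt in variant.events:
        if rp_start <= rp < rp_start + offset:
            if alt.startswith("-"):
                shift -= 1
            elif alt.startswith("+"):
                shift += len(alt) - 1
    i0 = region.to_internal(rp_start) - 1
    i1 = region.to_internal(rp_end)
    ref_cds = region.sequence[i0 + offset:i1]
    var_cds = variant.consensus[offset + shift:]
    return rp_start, offset + shift, ref_cds, var_cds


def detect_frame_disruption(variant: AmpliconVariant, region: ReferenceRegion,
                            amplicon_interval: tuple[int, int] | None = None,
                            ) -> DisruptionReport:
    """Net coding-length change mod 3 and first premature stop."""
    _rp0, _off, ref_cds, var_cds = _segment_setup(variant, region,
                                                  amplicon_interval)
    net = len(var_cds) - len(ref_cds)
    ref_prot = translate(ref_cds)
    var_prot = translate(var_cds)
    ref_stop = ref_prot.find("*")
    stop_idx = var_prot.find("*")
    expected_stop = ref_stop + (net // 3 if net % 3 == 0 else 0)
    premature = None
    if stop_idx >= 0 and (ref_stop < 0 or stop_idx < expected_stop):
        premature = stop_idx + 1
    return DisruptionReport(variant.variant_id, net, net % 3, premature,
                            net % 3 != 0)


def _no_premature_stop(prot: str, ref_stop: int, net: int) -> bool:
    """No stop before the (net-shifted) natural stop position."""
    idx = prot.find("*")
    if idx < 0:
        return True
    return ref_stop >= 0 and idx >= ref_stop + net // 3


def scan_introns(variant: AmpliconVariant, region: ReferenceRegion,
                 amplicon_interval: tuple[int, int] | None = None,
                 max_len: int = 200, min_len: int = 4) -> list[IntronCall]:
    """Candidate intron intervals whose removal restores frame and removes
    all premature stops.

    Candidates are ordered by how closely the spliced translation matches
    the reference protein; among equally good candidates canonical GT..AG
    boundaries rank above non-canonical ones, then leftmost-first.
    """
    rp0, cds_off, ref_cds, var_cds = _segment_setup(variant, region,
                                                    amplicon_interval)
    net = len(var_cds) - len(ref_cds)
    ref_prot = translate(ref_cds)
    ref_stop = ref_prot.find("*")
    n = len(var_cds)
    calls: list[IntronCall] = []
    for length in range(min_len, min(max_len, n) + 1):
        if (net - length) % 3 != 0:
            continue
        for start in range(0, n - length + 1):
            spliced = var_cds[:start] + var_cds[start + length:]
            prot = translate(spliced)
            if not _no_premature_stop(prot, ref_stop,
                                      len(spliced) - len(ref_cds)):
                continue
            donor = var_cds[start:start + 2]
            acceptor = var_cds[start + length - 2:start + length]
            klass = "canonical" if (donor == "GT" and acceptor == "AG") \
                else "non_canonical"
            deficit = len(ref_cds) - len(spliced)
            residues_deleted = max(0, deficit // 3)
            sim = difflib.SequenceMatcher(a=ref_prot, b=prot,
                                          autojunk=False).ratio()
            cons_start = cds_off + start + 1  # 1-based on the full consensus
            rp_a = consensus_position_to_rp(variant.events, rp0, cons_start)
            rp_b = consensus_position_to_rp(variant.events, rp0,
                                            cons_start + length - 1)
            calls.append(IntronCall(
                variant.variant_id, cons_start, length, rp_a, rp_b, donor,
                acceptor, klass, True, True, residues_deleted, sim))
    # best frame restoration first (the true intron splices back to the
    # reference); ties prefer known splice boundaries (GT..AG, then the
    # known non-canonical AC..AT), then leftmost/shortest
    def boundary_rank(c: IntronCall) -> int:
        if (c.donor, c.acceptor) == ("GT", "AG"):
            return 0
        if (c.donor, c.acceptor) == ("AC", "AT"):
            return 1
        return 2

    calls.sort(key=lambda c: (-round(c.similarity, 9), boundary_rank(c),
                              c.start, c.length))
    return [IntronCall(**{**c.__dict__, "rank": i + 1})
            for i, c in enumerate(calls)]


def splice_and_translate(variant: AmpliconVariant, calls: Sequence[IntronCall],
                         region: ReferenceRegion,
                         amplicon_interval: tuple[int, int] | None = None,
                         ) -> str:
    """Remove non-overlapping intron intervals and translate the result."""
    _rp0, cds_off, _ref_cds, var_cds = _segment_setup(variant, region,
                                                      amplicon_interval)
    ivs = sorted((c.start - cds_off - 1, c.start - cds_off - 1 + c.length)
                 for c in calls)
    for (a0, a1), (b0, _b1) in zip(ivs, ivs[1:]):
        if b0 < a1:
            raise ConflictError("overlapping intron calls")
    out = []
    prev = 0
    for a0, a1 in ivs:
        out.append(var_cds[prev:a0])
        prev = a1
    out.append(var_cds[prev:])
    return translate("".join(out))


def write_intron_tsv(calls: Sequence[IntronCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant\trank\tstart\tlength\tRP_start\tRP_end\tdonor\t"
                 "acceptor\tclass\tframe_restored\tstops_removed\t"
                 "residues_deleted\tsimilarity\n")
        for c in calls:
            fh.write(f"{c.variant_id}\t{c.rank}\t{c.start}\t{c.length}\t"
                     f"{c.rp_start}\t{c.rp_end}\t{c.donor}\t{c.acceptor}\t"
                     f"{c.klass}\t{int(c.frame_restored)}\t"
                     f"{int(c.stops_removed)}\t{c.residues_deleted}\t"
                     f"{c.similarity:.3f}\n")
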