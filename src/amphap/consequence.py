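"""Protein-level annotation: codon arithmetic, stop detection, motif hits,
and class tallies.

Frame is anchored at the region's ``cds_start_rp``; no splice-aware
translation happens here (putative introns are handled separately and the
spliced sequence can be re-annotated).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .haplotypes import AmpliconVariant
from .seqio import ReferenceRegion

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
INFRAME_INDEL = "inframe_indel"
FRAMESHIFT = "frameshift"
UTR5 = "5'UTR"

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def translate(nt: str) -> str:
    """Translate complete codons only (trailing partial codon ignored)."""
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate())


@dataclass(frozen=True)
class MotifSet:
    """Named amino-acid motifs, located either by literal sequence search in
    the reference protein or by a fixed 1-based residue interval."""

    sequences: Mapping[str, str] = field(default_factory=dict)
    intervals: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.sequences.items():
            if not s or not s.isupper():
                raise ValueError(f"motif {name!r} must be uppercase amino acids")

    def locate(self, protein: str) -> dict[str, tuple[int, int]]:
        """Motif name -> 1-based residue interval within ``protein``."""
        hits: dict[str, tuple[int, int]] = {}
        for name, s in self.sequences.items():
            idx = protein.find(s)
            if idx >= 0:
                hits[name] = (idx + 1, idx + len(s))
        for name, (a, b) in self.intervals.items():
            hits[name] = (a, b)
        return hits


def default_motifs(della_interval: tuple[int, int] | None = None) -> MotifSet:
    """TVHYNP located by search; the DELLA region by configured interval."""
    intervals = {"DELLA": della_interval} if della_interval else {}
    return MotifSet(sequences={"TVHYNP": "TVHYNP"}, intervals=intervals)


@dataclass(frozen=True)
class ConsequenceRecord:
    variant_id: str
    rp: int
    region: str                    # "CDS" | "5'UTR"
    cds_nt: int | None = None
    codon_index: int | None = None
    codon_position: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    consequence: str | None = None
    motif: str | None = None


def _reference_protein(region: ReferenceRegion) -> str:
    i0 = region.to_internal(region.cds_start_rp) - 1
    return translate(region.sequence[i0:])


def annotate_snp(rp: int, alt_base: str, region: ReferenceRegion,
                 motifs: MotifSet | None = None,
                 variant_id: str = ".") -> ConsequenceRecord:
    """Annotate a single-base substitution at an RP."""
    if region.cds_start_rp is None:
        raise ValueError("region has no CDS anchor")
    if rp < region.cds_start_rp:
        return ConsequenceRecord(variant_id, rp, UTR5)
    cds_nt = rp - region.cds_start_rp + 1
    codon_index = (cds_nt - 1) // 3 + 1
    codon_position = (cds_nt - 1) % 3 + 1
    i0 = region.to_internal(region.cds_start_rp) - 1
    c0 = i0 + (codon_index - 1) * 3
    ref_codon = region.sequence[c0:c0 + 3]
    if len(ref_codon) < 3:
        return ConsequenceRecord(variant_id, rp, "CDS", cds_nt, codon_index,
                                 codon_position)
    ref_base = ref_codon[codon_position - 1]
    if alt_base == ref_base:
        raise ValueError(f"alt equals reference base at RP {rp}")
    alt_codon = (ref_codon[:codon_position - 1] + alt_base
                 + ref_codon[codon_position:])
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    if alt_codon in _STOP_CODONS and ref_codon not in _STOP_CODONS:
        cls = NONSENSE
    elif ref_aa == alt_aa:
        cls = SYNONYMOUS
    else:
        cls = MISSENSE
    motif = None
    if motifs is not None:
        for name, (a, b) in motifs.locate(_reference_protein(region)).items():
            if a <= codon_index <= b:
                motif = name
                break
    return ConsequenceRecord(variant_id, rp, "CDS", cds_nt, codon_index,
                             codon_position, ref_codon, alt_codon, ref_aa,
                             alt_aa, cls, motif)


# ---------------------------------------------------------------------------
# whole-variant protein diff
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinDiff:
    variant_id: str
    net_indel_nt: int
    frameshift: bool
    premature_stop_codon: int | None   # 1-based codon index in the variant
    truncated_length: int | None       # residues retained before the stop
    substitutions: tuple[tuple[int, str, str], ...]  # (ref residue pos, ref, alt)
    inframe_indels: tuple[tuple[int, str, str], ...]  # (ref residue pos, op, residues)

    @property
    def is_empty(self) -> bool:
        return (not self.frameshift and self.premature_stop_codon is None
                and not self.substitutions and not self.inframe_indels)


def _cds_frame_offset(region: ReferenceRegion, rp_start: int) -> tuple[int, int]:
    """(consensus offset of the first complete codon, codon index of it)."""
    delta = rp_start - region.cds_start_rp
    if delta <= 0:
        return -delta, 1
    skip = (-delta) % 3
    return skip, (delta + skip) // 3 + 1


def annotate_variant_protein(variant: AmpliconVariant, region: ReferenceRegion,
                             amplicon_interval: tuple[int, int] | None = None,
                             ) -> ProteinDiff:
    """Protein-level diff of a variant consensus against the reference over
    the coding part of its amplicon."""
    if amplicon_interval is None:
        rp_start, rp_end = region.rp_interval
    else:
        rp_start, rp_end = amplicon_interval
    offset, first_codon = _cds_frame_offset(region, rp_start)
    i0 = region.to_internal(rp_start) - 1
    i1 = region.to_internal(rp_end)
    ref_cds = region.sequence[i0 + offset:i1]
    # indels upstream of the CDS anchor shift where the CDS begins within
    # the variant consensus
    shift = 0
    for rp, alt in variant.events:
        if rp_start <= rp < rp_start + offset:
            if alt.startswith("-"):
                shift -= 1
            elif alt.startswith("+"):
                shift += len(alt) - 1
    var_cds = variant.consensus[offset + shift:]
    net = len(var_cds) - len(ref_cds)
    ref_prot = translate(ref_cds)
    var_prot = translate(var_cds)
    stop_idx = var_prot.find("*")
    ref_stop = ref_prot.find("*")
    frameshift = net % 3 != 0
    # an in-frame indel legitimately shifts the natural stop by net/3 codons
    expected_stop = ref_stop + (net // 3 if not frameshift else 0)
    premature = None
    truncated = None
    if stop_idx >= 0 and (ref_stop < 0 or stop_idx < expected_stop):
        premature = stop_idx + 1
        truncated = stop_idx
    substitutions: list[tuple[int, str, str]] = []
    indels: list[tuple[int, str, str]] = []
    if not frameshift:
        # a premature stop truncates translation; diff only the prefix so the
        # lost tail is reported as truncation, not as a deletion
        if premature is not None:
            cmp_var = var_prot[:stop_idx]
            ref_cmp = ref_prot[:stop_idx]
        else:
            cmp_var = var_prot
            ref_cmp = ref_prot
        sm = difflib.SequenceMatcher(a=ref_cmp, b=cmp_var, autojunk=False)
        for tag, a0, a1, b0, b1 in sm.get_opcodes():
            if tag == "replace" and a1 - a0 == b1 - b0:
                for k in range(a1 - a0):
                    substitutions.append(
                        (first_codon + a0 + k, ref_cmp[a0 + k], cmp_var[b0 + k]))
            elif tag == "delete" or (tag == "replace" and a1 - a0 > b1 - b0):
                indels.append((first_codon + a0, "del", ref_cmp[a0:a1]))
                if tag == "replace":
                    for k in range(b1 - b0):
                        substitutions.append(
                            (first_codon + a0 + k, ref_cmp[a0 + k], cmp_var[b0 + k]))
            elif tag == "insert" or (tag == "replace" and b1 - b0 > a1 - a0):
                indels.append((first_codon + a0, "ins", cmp_var[b0:b1]))
    return ProteinDiff(variant.variant_id, net, frameshift, premature,
                       truncated, tuple(substitutions), tuple(indels))


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

def tally_consequences(records: Iterable[ConsequenceRecord]) -> dict:
    """Counts by class and, for substituting SNPs, by codon position."""
    by_class = {SYNONYMOUS: 0, MISSENSE: 0, NONSENSE: 0}
    by_codon_position = {1: 0, 2: 0, 3: 0}
    utr = 0
    for r in records:
        if r.region == UTR5:
            utr += 1
            continue
        if r.consequence in by_class:
            by_class[r.consequence] += 1
        if r.consequence in (MISSENSE, NONSENSE) and r.codon_position:
            by_codon_position[r.codon_position] += 1
    coding = sum(by_class.values())
    return {
        "coding_snps": coding,
        "synonymous": by_class[SYNONYMOUS],
        "non_synonymous": by_class[MISSENSE] + by_class[NONSENSE],
        "by_class": by_class,
        "substituting_by_codon_position": by_codon_position,
        "utr5_snps": utr,
    }


def write_consequence_tsv(records: Iterable[ConsequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tRP\tregion\tcds_nt\tcodon_index\tcodon_position\t"
                 "ref_codon\talt_codon\tref_aa\talt_aa\tconsequence\tmotif\n")
        for r in records:
            vals = [r.variant_id, r.rp, r.region, r.cds_nt, r.codon_index,
                    r.codon_position, r.ref_codon, r.alt_codon, r.ref_aa,
                    r.alt_aa, r.consequence, r.motif]
            fh.write("\t".join("." if v is None else str(v) for v in vals) + "\n")
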