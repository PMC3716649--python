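"""Linked-variant haplotype reconstruction and genome/allele assignment.

Reads spanning an amplicon are grouped by the exact string of accepted
variant events they carry; each group is an amplicon variant with a relative
frequency among full-span reads.  Non-accepted mismatches are treated as
sequencing error and absorbed by the reference/majority consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .align import AlignConfig, ReadAlignment
from .seqio import AllelePanelEntry, ReferenceRegion

EventKey = tuple[int, str]  # (RP, alt) with alt = base | +SEQ | -B


@dataclass
class AmpliconVariant:
    """A haplotype of one amplicon: ordered linked events plus bookkeeping."""

    pair_name: str
    events: tuple[EventKey, ...]
    read_count: int
    frequency_pct: float
    consensus: str
    variant_id: str = ""
    allele_name: str | None = None
    genome_label: str | None = None
    identity_pct: float | None = None
    ambiguous: bool = False


@dataclass(frozen=True)
class GroupConfig:
    min_support: int = 2
    merge_small: bool = True      # else drop sub-support groups
    min_span_fraction: float = 0.95


def read_events(aln: ReadAlignment, region: ReferenceRegion,
                accepted: set[EventKey] | None) -> tuple[EventKey, ...]:
    """The variant events carried by one aligned read, restricted to the
    ``accepted`` set (``None`` keeps every event)."""
    events: list[EventKey] = []
    rp = aln.rp_start
    for op, payload in aln.ops:
        if op == "M":
            for base in payload:
                if base != region.base_at_rp(rp):
                    key = (rp, base)
                    if accepted is None or key in accepted:
                        events.append(key)
                rp += 1
        elif op == "D":
            for _ in range(int(payload)):
                key = (rp, "-" + region.base_at_rp(rp))
                if accepted is None or key in accepted:
                    events.append(key)
                rp += 1
        else:
            key = (rp - 1, "+" + payload)
            if accepted is None or key in accepted:
                events.append(key)
    events.sort()
    return tuple(events)


def variant_from_sequence(seq: str, region: ReferenceRegion,
                          cfg: AlignConfig = AlignConfig(),
                          variant_id: str = "variant",
                          pair_name: str = "amplicon",
                          ) -> tuple[AmpliconVariant, tuple[int, int]] | None:
    """Align a variant sequence to the reference and express it as an
    amplicon variant over the aligned interval (all events kept).

    Returns (variant, aligned RP interval) or ``None`` when unalignable.
    """
    from .align import align_read  # local import to avoid cycle at module load

    aln = align_read(seq, region, cfg)
    if aln is None:
        return None
    events = read_events(aln, region, None)
    interval = (aln.rp_start, aln.rp_end)
    consensus = consensus_from_events(events, region, *interval)
    variant = AmpliconVariant(pair_name, events, 1, 100.0, consensus,
                              variant_id=variant_id)
    return variant, interval


def consensus_from_events(events: Sequence[EventKey], region: ReferenceRegion,
                          rp_start: int, rp_end: int) -> str:
    """Apply an event string to the reference interval (right to left)."""
    i0 = region.to_internal(rp_start) - 1
    i1 = region.to_internal(rp_end)
    seq = list(region.sequence[i0:i1])
    for rp, alt in sorted(events, reverse=True):
        idx = region.to_internal(rp) - 1 - i0
        if not 0 <= idx < len(seq) + 1:
            continue
        if alt.startswith("-"):
            del seq[idx]
        elif alt.startswith("+"):
            seq.insert(idx + 1, alt[1:])
        else:
            seq[idx] = alt
    return "".join(seq)


def consensus_position_to_rp(events: Sequence[EventKey], rp_start: int,
                             pos: int) -> int:
    """Map a 1-based consensus position back to an RP (insertion bases map to
    their anchor RP)."""
    rp = rp_start
    c = 0
    ev = sorted(events)
    k = 0
    while True:
        while k < len(ev) and ev[k][0] < rp:
            k += 1
        if k < len(ev) and ev[k][0] == rp:
            _rp, alt = ev[k]
            if alt.startswith("-"):
                rp += 1
                k += 1
                continue
            if alt.startswith("+"):
                c += 1  # the reference base at rp itself
                if c >= pos:
                    return rp
                c += len(alt) - 1
                if c >= pos:
                    return rp
                rp += 1
                k += 1
                continue
        c += 1
        if c >= pos:
            return rp
        rp += 1


def group_reads(alignments: Iterable[ReadAlignment], region: ReferenceRegion,
                amplicon_interval: tuple[int, int],
                accepted: set[EventKey],
                cfg: GroupConfig = GroupConfig(),
                pair_name: str = "amplicon") -> list[AmpliconVariant]:
    """Group full-span reads into amplicon variants.

    Groups with support below ``cfg.min_support`` are merged into the
    nearest larger group by event-string symmetric difference (or dropped
    when ``merge_small`` is off).  Frequencies are percentages of full-span
    reads and sum to 100 within rounding.
    """
    rp_start, rp_end = amplicon_interval
    span = rp_end - rp_start + 1
    need = cfg.min_span_fraction * span
    groups: dict[tuple[EventKey, ...], int] = {}
    for aln in alignments:
        cover = (min(aln.rp_end, rp_end) - max(aln.rp_start, rp_start) + 1)
        if cover < need:
            continue
        key = tuple(e for e in read_events(aln, region, accepted)
                    if rp_start <= e[0] <= rp_end)
        groups[key] = groups.get(key, 0) + 1

    if not groups:
        return []

    big = {k: n for k, n in groups.items() if n >= cfg.min_support}
    small = {k: n for k, n in groups.items() if n < cfg.min_support}
    if big:
        if cfg.merge_small:
            for k, n in small.items():
                target = min(
                    big,
                    key=lambda b: (len(set(b) ^ set(k)), -big[b], b))
                big[target] += n
        groups = big
    # else: nothing reaches min_support; keep groups as they are rather than
    # emit an empty table

    total = sum(groups.values())
    variants = []
    for key, n in sorted(groups.items(), key=lambda kv: (-kv[1], kv[0])):
        consensus = consensus_from_events(key, region, rp_start, rp_end)
        variants.append(AmpliconVariant(
            pair_name=pair_name, events=key, read_count=n,
            frequency_pct=100.0 * n / total, consensus=consensus))
    for i, v in enumerate(variants):
        v.variant_id = f"{pair_name}.v{i + 1}" if v.events else f"{pair_name}.type"
    return variants


# ---------------------------------------------------------------------------
# allele assignment
# ---------------------------------------------------------------------------

def _identity_to(consensus: str, target: str,
                 cfg: AlignConfig) -> tuple[float, float]:
    """(identity, score) of the consensus aligned inside the target."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = cfg.match
    a.mismatch_score = cfg.mismatch
    a.open_gap_score = cfg.gap_open
    a.extend_gap_score = cfg.gap_extend
    try:
        a.end_deletion_score = 0.0
    except AttributeError:
        a.query_end_gap_score = 0.0
    aln = a.align(target, consensus)[0]
    t, q = str(aln[0]), str(aln[1])
    lead = len(q) - len(q.lstrip("-"))
    tail = len(q) - len(q.rstrip("-"))
    t = t[lead:len(t) - tail or None]
    q = q[lead:len(q) - tail or None]
    matches = sum(1 for x, y in zip(t, q) if x == y and x != "-")
    ident = matches / len(t) if t else 0.0
    return ident, float(aln.score)


def assign_allele(variant: AmpliconVariant,
                  panel: Sequence[AllelePanelEntry],
                  cfg: AlignConfig = AlignConfig(),
                  ambiguity_margin_pct: float = 1.0) -> AmpliconVariant:
    """Assign the maximum-identity panel entry to a variant.

    Ties break by higher alignment score, then lexicographic allele name;
    results separated from the runner-up by less than
    ``ambiguity_margin_pct`` identity points are flagged ambiguous.
    """
    if not panel:
        raise ValueError("allele panel must be non-empty")
    scored = []
    for entry in panel:
        ident, score = _identity_to(variant.consensus, entry.sequence, cfg)
        scored.append((ident, score, entry))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2].allele_name))
    best_ident, _score, best = scored[0]
    ambiguous = False
    if len(scored) > 1:
        runner_ident = scored[1][0]
        if (best_ident - runner_ident) * 100.0 < ambiguity_margin_pct:
            ambiguous = True
    return replace(variant, allele_name=best.allele_name,
                   genome_label=best.genome_label,
                   identity_pct=100.0 * best_ident, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# cross-library table
# ---------------------------------------------------------------------------

def frequency_table(variants_by_library: Mapping[str, Sequence[AmpliconVariant]]
                    ) -> pd.DataFrame:
    """Variant x library matrix of relative frequencies (%), matched across
    libraries by identical event string; absent variants are 0."""
    keys: dict[tuple[EventKey, ...], str] = {}
    for lib in sorted(variants_by_library):
        for v in variants_by_library[lib]:
            keys.setdefault(v.events, v.variant_id)
    rows = []
    for events, vid in sorted(keys.items(), key=lambda kv: (len(kv[0]), kv[0])):
        row: dict[str, object] = {
            "variant": vid,
            "events": ";".join(f"{rp}:{alt}" for rp, alt in events) or ".",
        }
        for lib in sorted(variants_by_library):
            freq = 0.0
            for v in variants_by_library[lib]:
                if v.events == events:
                    freq = v.frequency_pct
                    break
            row[lib] = freq
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def write_haplotype_table(variants_by_library: Mapping[str, Sequence[AmpliconVariant]],
                          path) -> None:
    with open(path, "w") as fh:
        fh.write("library\tvariant\tpair\tevents\treads\tfrequency_pct\t"
                 "allele\tgenome\tidentity_pct\tambiguous\n")
        for lib in sorted(variants_by_library):
            for v in variants_by_library[lib]:
                ev = ";".join(f"{rp}:{alt}" for rp, alt in v.events) or "."
                ident = "." if v.identity_pct is None else f"{v.identity_pct:.1f}"
                fh.write(f"{lib}\t{v.variant_id}\t{v.pair_name}\t{ev}\t"
                         f"{v.read_count}\t{v.frequency_pct:.1f}\t"
                         f"{v.allele_name or '.'}\t{v.genome_label or '.'}\t"
                         f"{ident}\t{int(v.ambiguous)}\n")
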