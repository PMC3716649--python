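"""Per-position SNP/indel calling with count-based thresholds and the
cross-library rare-variant confirmation rule.

An event is *called* outright when depth >= ``min_depth`` and its frequency
>= ``min_freq_pct`` (both inclusive).  Events below either bar are
*candidates*; a candidate survives only when the same (RP, alt) event is
present (> 0%) in at least ``rare_min_other_libraries`` other libraries and
reaches ``rare_min_pct_in_one`` percent in at least one of them.

Alt-allele encoding: a bare base for a SNP, ``+SEQ`` for an insertion
anchored after the RP, ``-B`` for deletion of base B at the RP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .align import PileupColumn
from .seqio import ReferenceRegion

CALLED = "called"
CANDIDATE = "candidate"
CROSS_CONFIRMED = "cross_confirmed"
REJECTED = "rejected"


class ConfigurationError(ValueError):
    """The cross-library rule is undefined for the supplied libraries."""


@dataclass(frozen=True)
class CallConfig:
    min_depth: int = 40
    min_freq_pct: float = 20.0
    rare_min_other_libraries: int = 2
    rare_min_pct_in_one: float = 5.0

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_freq_pct,
               self.rare_min_other_libraries, self.rare_min_pct_in_one) <= 0:
            raise ValueError("all call thresholds must be positive")


@dataclass(frozen=True)
class VariantCall:
    """One event in one library."""

    rp: int
    event_type: str           # "snp" | "indel"
    ref: str
    alt: str                  # base | +SEQ | -B
    count: int
    depth: int
    status: str

    @property
    def frequency_pct(self) -> float:
        return 100.0 * self.count / self.depth if self.depth else 0.0


@dataclass
class CombinedVariant:
    """One event across all libraries (a combined-report row)."""

    rp: int
    event_type: str
    ref: str
    alt: str
    status: str
    per_library: dict[str, tuple[float | None, int | None]] = field(
        default_factory=dict)


def event_type_of(alt: str) -> str:
    return "indel" if alt.startswith(("+", "-")) else "snp"


def call_column(col: PileupColumn, ref_base: str,
                cfg: CallConfig = CallConfig()) -> list[VariantCall]:
    """All non-reference events at one pileup column.

    Every observed event yields a record; the status separates ``called``
    from ``candidate``.  ``N`` never forms an alt allele.
    """
    if ref_base not in "ACGT":
        raise ValueError(f"ref_base must be one of ACGT, got {ref_base!r}")
    depth = col.depth
    calls: list[VariantCall] = []

    def status_for(count: int) -> str:
        freq = 100.0 * count / depth if depth else 0.0
        ok = depth >= cfg.min_depth and freq >= cfg.min_freq_pct
        return CALLED if ok else CANDIDATE

    for base in "ACGT":
        n = col.base_counts.get(base, 0)
        if base != ref_base and n > 0:
            calls.append(VariantCall(col.rp, "snp", ref_base, base, n, depth,
                                     status_for(n)))
    if col.del_count > 0:
        calls.append(VariantCall(col.rp, "indel", ref_base, "-" + ref_base,
                                 col.del_count, depth,
                                 status_for(col.del_count)))
    for seq, n in sorted(col.insertions.items()):
        calls.append(VariantCall(col.rp, "indel", ref_base, "+" + seq, n,
                                 depth, status_for(n)))
    return calls


def call_pileup(columns: Mapping[int, PileupColumn], region: ReferenceRegion,
                cfg: CallConfig = CallConfig()) -> list[VariantCall]:
    calls: list[VariantCall] = []
    for rp in sorted(columns):
        ref_base = region.base_at_rp(rp)
        if ref_base not in "ACGT":
            continue
        calls.extend(call_column(columns[rp], ref_base, cfg))
    return calls


def confirm_rare(candidate: VariantCall,
                 all_libraries: Mapping[str, Iterable[VariantCall]],
                 candidate_library: str,
                 cfg: CallConfig = CallConfig()) -> str:
    """Resolve a candidate against the other libraries.

    ``cross_confirmed`` iff the event is present (frequency > 0) in at least
    ``rare_min_other_libraries`` other libraries AND at least one of those
    reaches ``rare_min_pct_in_one`` percent; otherwise ``rejected``.
    """
    others = {lib: calls for lib, calls in all_libraries.items()
              if lib != candidate_library}
    if len(others) < cfg.rare_min_other_libraries:
        raise ConfigurationError(
            f"cross-library rule needs >= {cfg.rare_min_other_libraries} "
            f"other libraries, got {len(others)}")
    present_freqs = []
    for calls in others.values():
        for c in calls:
            if (c.rp, c.alt) == (candidate.rp, candidate.alt) and c.count > 0:
                present_freqs.append(c.frequency_pct)
                break
    if (len(present_freqs) >= cfg.rare_min_other_libraries
            and max(present_freqs, default=0.0) >= cfg.rare_min_pct_in_one):
        return CROSS_CONFIRMED
    return REJECTED


def combine_reports(per_library_calls: Mapping[str, list[VariantCall]],
                    cfg: CallConfig = CallConfig(),
                    include_rejected: bool = False,
                    ) -> tuple[list[CombinedVariant], dict[str, int]]:
    """Merge per-library call lists into one table plus summary counts.

    Candidates are put through the cross-library rule when at least
    ``rare_min_other_libraries + 1`` libraries are available; with fewer
    libraries the rule is undefined and unconfirmed candidates are rejected.

    Summary positions are distinct RPs carrying accepted events:
    ``snp_positions``/``indel_positions`` count positions with only that
    event class, ``both_positions`` positions with both, and
    ``positions_total`` their sum.
    """
    if not per_library_calls:
        raise ValueError("at least one library required")
    libraries = sorted(per_library_calls)
    by_event: dict[tuple[int, str], dict[str, VariantCall]] = {}
    for lib, calls in per_library_calls.items():
        for c in calls:
            by_event.setdefault((c.rp, c.alt), {})[lib] = c

    can_cross = len(libraries) >= cfg.rare_min_other_libraries + 1
    combined: list[CombinedVariant] = []
    for (rp, alt), lib_calls in sorted(by_event.items()):
        any_call = next(iter(lib_calls.values()))
        if any(c.status == CALLED for c in lib_calls.values()):
            status = CALLED
        else:
            status = REJECTED
            if can_cross:
                for lib, c in lib_calls.items():
                    if confirm_rare(c, per_library_calls, lib,
                                    cfg) == CROSS_CONFIRMED:
                        status = CROSS_CONFIRMED
                        break
        if status == REJECTED and not include_rejected:
            continue
        per_lib: dict[str, tuple[float | None, int | None]] = {}
        for lib in libraries:
            c = lib_calls.get(lib)
            per_lib[lib] = (c.frequency_pct, c.depth) if c else (None, None)
        combined.append(CombinedVariant(rp, any_call.event_type, any_call.ref,
                                        alt, status, per_lib))

    accepted = [c for c in combined if c.status in (CALLED, CROSS_CONFIRMED)]
    snp_rps = {c.rp for c in accepted if c.event_type == "snp"}
    indel_rps = {c.rp for c in accepted if c.event_type == "indel"}
    both = snp_rps & indel_rps
    summary = {
        "positions_total": len(snp_rps | indel_rps),
        "snp_positions": len(snp_rps - both),
        "indel_positions": len(indel_rps - both),
        "both_positions": len(both),
    }
    return combined, summary


def accepted_event_set(combined: Iterable[CombinedVariant]) -> set[tuple[int, str]]:
    """(RP, alt) keys of called/cross-confirmed events, for haplotype grouping."""
    return {(c.rp, c.alt) for c in combined
            if c.status in (CALLED, CROSS_CONFIRMED)}
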