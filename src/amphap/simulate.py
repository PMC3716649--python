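"""Synthetic hexaploid amplicon-pool generator with exact planted truth.

Three homeolog backbones are derived from a common ancestor sequence.  The
genome designated as the pipeline reference (default ``B``) receives
substitution-only divergence, so its coordinate frame equals the ancestor's
and every haplotype's difference list against the reference is computable in
closed form — the :class:`TruthSet` is therefore exact and independent of
any aligner.

Events are ``(pos, ref, alt)`` triples in the reference coordinate frame
(1-based):

* substitution: ``ref`` and ``alt`` both length 1;
* deletion: ``ref`` the deleted bases starting at ``pos``, ``alt`` empty;
* insertion: ``ref`` empty, ``alt`` inserted *after* ``pos``.

Generated indels are left-aligned by construction (never shiftable into the
preceding context), matching the normalisation the aligner applies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import QualRead, ReferenceRegion, revcomp, write_fastq

Event = tuple[int, str, str]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

GENOMES = ("A", "B", "D")


class TruthError(ValueError):
    """A planted event contradicts the backbone it is planted on."""


# ---------------------------------------------------------------------------
# event algebra
# ---------------------------------------------------------------------------

def _event_span(ev: Event) -> tuple[int, int]:
    """Closed interval of reference positions consumed (anchor for insertions)."""
    pos, ref, _alt = ev
    if ref == "":
        return pos, pos
    return pos, pos + len(ref) - 1


def validate_events(events: Sequence[Event], seq: str | None = None) -> None:
    """Events sorted, non-overlapping, and (when ``seq`` given) ref-consistent."""
    last_end = 0
    last_pos = -1
    for ev in events:
        pos, ref, alt = ev
        if pos <= last_pos:
            raise TruthError(f"event positions not strictly increasing at {pos}")
        last_pos = pos
        if ref == "" and alt == "":
            raise TruthError(f"empty event at {pos}")
        if ref and alt and (len(ref) != 1 or len(alt) != 1):
            raise TruthError(f"substitutions must be 1:1 at {pos}")
        if ref and alt and ref == alt:
            raise TruthError(f"substitution with ref == alt at {pos}")
        s, e = _event_span(ev)
        if ref and s <= last_end:
            raise TruthError(f"overlapping events at {pos}")
        if ref:
            last_end = e
        if seq is not None:
            if ref == "":
                if not 1 <= pos <= len(seq):
                    raise TruthError(f"insertion anchor {pos} outside sequence")
            else:
                if e > len(seq):
                    raise TruthError(f"event at {pos} runs past sequence end")
                actual = seq[pos - 1:pos - 1 + len(ref)]
                if actual != ref:
                    raise TruthError(
                        f"ref mismatch at {pos}: event says {ref!r}, "
                        f"sequence has {actual!r}")


def apply_events(seq: str, events: Sequence[Event]) -> str:
    """Apply sorted, non-overlapping events left to right."""
    validate_events(events, seq)
    out: list[str] = []
    i = 0  # 0-based cursor into seq
    for pos, ref, alt in events:
        if ref == "":  # insertion after pos
            out.append(seq[i:pos])
            out.append(alt)
            i = pos
        else:
            out.append(seq[i:pos - 1])
            out.append(alt)
            i = pos - 1 + len(ref)
    out.append(seq[i:])
    return "".join(out)


def merge_events(a: Sequence[Event], b: Sequence[Event]) -> tuple[Event, ...]:
    """Merge two event lists over disjoint loci into one sorted list."""
    merged = sorted([*a, *b], key=lambda ev: (ev[0], ev[1] != ""))
    validate_events(merged)
    return tuple(merged)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomeologPanel:
    """One genome's backbone: label, sequence and its divergence from the
    common ancestor (events in ancestor coordinates)."""

    genome_label: str
    backbone_seq: str
    cds_start: int
    divergence_events: tuple[Event, ...]

    def __post_init__(self) -> None:
        if self.genome_label not in GENOMES:
            raise ValueError(f"genome label must be one of {GENOMES}")
        atg = self.backbone_seq[self.cds_start - 1:self.cds_start + 2]
        if atg != "ATG":
            raise ValueError(f"no ATG at cds_start (found {atg!r})")


@dataclass(frozen=True)
class PlantedVariant:
    """A haplotype to plant: genome, events on that genome's backbone
    (reference-frame coordinates), and its share of the whole pool."""

    genome_label: str
    events: tuple[Event, ...]
    relative_frequency: float
    label: str
    intron_intervals: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.relative_frequency <= 1:
            raise ValueError("relative_frequency must be in [0, 1]")


@dataclass(frozen=True)
class Haplotype:
    """A materialised pool member."""

    label: str
    genome_label: str
    sequence: str
    frequency: float
    events_vs_reference: tuple[Event, ...]


@dataclass(frozen=True)
class ErrorModel:
    """454-flavoured error model: iid substitutions plus homopolymer-biased
    indels whose probability grows with run length, capped at 0.5."""

    substitution_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    homopolymer_multiplier: float = 1.5
    quality_profile: tuple[tuple[float, float, float], ...] = (
        (0.0, 34.0, 3.0), (0.5, 32.0, 3.0), (1.0, 26.0, 4.0))

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0 <= r <= 1:
                raise ValueError("error rates must be in [0, 1]")

    def indel_prob(self, run_length: int) -> float:
        p = self.homopolymer_indel_rate * self.homopolymer_multiplier ** (run_length - 1)
        return min(p, 0.5)


@dataclass(frozen=True)
class ReadLengthModel:
    """Truncated normal read lengths, capped at the template length."""

    mean: float = 420.0
    sd: float = 60.0
    min_len: int = 100


@dataclass(frozen=True)
class TruthSet:
    """Exact expected outcomes, recomputable from the planted variant list."""

    reference_name: str
    reference_genome: str
    haplotypes: tuple[Haplotype, ...]
    event_freqs: dict[tuple[int, str], float]
    nonref_fraction: dict[int, float]
    intron_intervals: tuple[tuple[int, int, str], ...]

    def to_json(self) -> str:
        payload = {
            "reference_name": self.reference_name,
            "reference_genome": self.reference_genome,
            "haplotypes": [
                {"label": h.label, "genome": h.genome_label,
                 "frequency": h.frequency,
                 "events": [list(e) for e in h.events_vs_reference]}
                for h in self.haplotypes
            ],
            "event_freqs": {f"{rp}:{alt}": f
                            for (rp, alt), f in sorted(self.event_freqs.items())},
            "nonref_fraction": {str(k): v
                                for k, v in sorted(self.nonref_fraction.items())},
            "intron_intervals": [list(t) for t in self.intron_intervals],
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

def _random_orf_sequence(rng: np.random.Generator, length: int,
                         cds_start: int) -> str:
    """Random DNA with ATG at cds_start and no in-frame stop downstream."""
    utr = "".join(rng.choice(list(_BASES), size=cds_start - 1))
    seq = [utr, "ATG"]
    pos = cds_start + 2
    while pos + 3 <= length:
        codon = "".join(rng.choice(list(_BASES), size=3))
        while codon in _STOPS:
            codon = "".join(rng.choice(list(_BASES), size=3))
        seq.append(codon)
        pos += 3
    seq.append("".join(rng.choice(list(_BASES), size=length - pos)))
    return "".join(seq)


def _left_aligned_ok(seq: str, ev: Event) -> bool:
    """True when the event cannot be shifted left (canonical placement)."""
    pos, ref, alt = ev
    if ref and alt:
        return True
    if ref == "":  # insertion after pos: shiftable if last inserted == seq[pos-1]
        return pos < 1 or alt[-1] != seq[pos - 1]
    # deletion at pos..pos+k-1: shiftable if seq[pos-2] == seq[pos+k-2]
    return pos < 2 or seq[pos - 2] != seq[pos - 1 + len(ref) - 1]


def _draw_divergence_events(rng: np.random.Generator, seq: str, rate: float,
                            taken: set[int], indel_frac: float,
                            subs_only: bool, cds_start: int,
                            ) -> tuple[Event, ...]:
    """Draw events whose +-5 neighbourhoods avoid ``taken`` (updated in
    place, so sharing it across genomes keeps events of different genomes
    apart — a nearby foreign event changes the reference context and can
    make the planted representation non-canonical under left-alignment)."""
    length = len(seq)
    n = rng.binomial(length, rate)
    events: list[Event] = []
    tries = 0
    while len(events) < n and tries < 60 * (n + 1):
        tries += 1
        pos = int(rng.integers(1, length + 1))
        if any(p in taken for p in range(pos - 5, pos + 6)):
            continue
        base = seq[pos - 1]
        if subs_only or rng.random() > indel_frac:
            alt = _BASES[int(rng.integers(4))]
            while alt == base:
                alt = _BASES[int(rng.integers(4))]
            ev: Event = (pos, base, alt)
        else:
            # homeologs keep frame: coding indels are whole codons
            k = 3 if pos >= cds_start else int(rng.integers(1, 4))
            if rng.random() < 0.5 and pos + k - 1 <= length:
                ev = (pos, seq[pos - 1:pos - 1 + k], "")
            else:
                ins = "".join(rng.choice(list(_BASES), size=k))
                ev = (pos, "", ins)
            if not _left_aligned_ok(seq, ev):
                continue
        events.append(ev)
        taken.update(range(pos - 5, pos + 6))
    events.sort(key=lambda e: e[0])
    return tuple(events)


def make_panel(seed: int, length: int, divergence: float,
               cds_start: int = 61, indel_frac: float = 0.08,
               reference_genome: str = "B") -> list[HomeologPanel]:
    """Three homeolog backbones derived from one ancestor.

    Each genome carries independent events at per-base rate ``divergence/2``
    so that every backbone pair differs by ``divergence`` in expectation.
    The reference genome receives substitutions only, keeping its coordinate
    frame identical to the ancestor's.
    """
    if length < 300:
        raise ValueError("length must be >= 300")
    if not 0 <= divergence < 0.2:
        raise ValueError("divergence must be in [0, 0.2)")
    rng = np.random.default_rng(seed)
    ancestor = _random_orf_sequence(rng, length, cds_start)
    # keep primer landing zones and the start codon invariant across genomes
    forbidden = set(range(1, 26)) | set(range(length - 24, length + 1))
    forbidden |= set(range(cds_start, cds_start + 3))
    panel = []
    taken = set(forbidden)
    for genome in GENOMES:
        for _attempt in range(50):
            trial = set(taken)
            events = _draw_divergence_events(
                rng, ancestor, divergence / 2.0, trial, indel_frac,
                subs_only=(genome == reference_genome), cds_start=cds_start)
            backbone = apply_events(ancestor, events)
            shift = sum(len(a) - len(r) for p, r, a in events
                        if p < cds_start)
            cds = cds_start + shift
            if not _has_premature_stop(backbone, cds):
                taken = trial
                break
        else:
            raise RuntimeError("could not draw a stop-free backbone")
        panel.append(HomeologPanel(genome, backbone, cds, events))
    return panel


def _has_premature_stop(seq: str, cds_start: int) -> bool:
    cds = seq[cds_start - 1:]
    for i in range(0, len(cds) - len(cds) % 3 - 3, 3):
        if cds[i:i + 3] in _STOPS:
            return True
    return False


def reference_region(panel: Sequence[HomeologPanel], name: str = "ref",
                     rp_offset: int = 0,
                     reference_genome: str = "B") -> ReferenceRegion:
    ref = next(h for h in panel if h.genome_label == reference_genome)
    return ReferenceRegion(name, ref.backbone_seq, rp_offset,
                           cds_start_rp=ref.cds_start + rp_offset)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _backbone_base(ancestor_base: str, genome_events: dict[int, Event],
                   pos: int) -> str | None:
    """Backbone base at a reference-frame position (None when deleted)."""
    for p, ref, alt in genome_events.values():
        if ref and p <= pos <= p + len(ref) - 1:
            if alt:  # substitution
                return alt if p == pos else None
            return None  # deleted
    return ancestor_base


def _compose_vs_reference(hap_events: Sequence[Event],
                          ref_subs: Sequence[Event]) -> tuple[Event, ...]:
    """Rewrite ancestor-frame events as differences against the reference
    backbone (= ancestor + substitution-only ``ref_subs``)."""
    sub_at = {p: alt for p, _r, alt in ref_subs}
    out: list[Event] = []
    covered: set[int] = set()
    for pos, ref, alt in hap_events:
        if ref and alt:  # substitution
            covered.add(pos)
            ref_base = sub_at.get(pos, ref)
            if alt != ref_base:
                out.append((pos, ref_base, alt))
        elif ref == "":  # insertion
            out.append((pos, "", alt))
        else:  # deletion: rewrite ref string onto the reference backbone
            covered.update(range(pos, pos + len(ref)))
            new_ref = "".join(
                sub_at.get(pos + i, ref[i]) for i in range(len(ref)))
            out.append((pos, new_ref, ""))
    # reference substitutions at loci the haplotype left ancestral
    for p, anc_base, b_alt in ref_subs:
        if p not in covered:
            out.append((p, b_alt, anc_base))
    out.sort(key=lambda e: (e[0], e[1] != ""))
    return tuple(out)


def plant_variants(panel: Sequence[HomeologPanel],
                   specs: Sequence[PlantedVariant],
                   reference_genome: str = "B",
                   reference_name: str = "ref",
                   ) -> tuple[list[Haplotype], TruthSet]:
    """Materialise haplotypes and the exact truth they imply.

    With empty ``specs`` the pool is the three unmodified backbones at one
    third each.  Otherwise ``specs`` is the complete pool (frequencies sum
    to 1); a spec with no events is an unmodified backbone.
    """
    by_genome = {h.genome_label: h for h in panel}
    ref_panel = by_genome[reference_genome]
    ref_seq = ref_panel.backbone_seq
    ref_subs = ref_panel.divergence_events  # substitution-only by construction
    if any(r == "" or a == "" for _p, r, a in ref_subs):
        raise TruthError("reference backbone must carry substitutions only")

    if not specs:
        specs = tuple(
            PlantedVariant(g, (), 1.0 / 3.0, f"{g}-backbone") for g in GENOMES)
    total = sum(s.relative_frequency for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise TruthError(f"pool frequencies sum to {total}, expected 1")
    if len({s.label for s in specs}) != len(specs):
        raise TruthError("duplicate haplotype labels")

    # ancestor = reference with its own substitutions undone
    ancestor = apply_events(ref_seq, tuple(
        (p, alt, ref) for p, ref, alt in ref_subs))

    haplotypes: list[Haplotype] = []
    intron_intervals: list[tuple[int, int, str]] = []
    for spec in specs:
        genome = by_genome[spec.genome_label]
        gen_events = {ev[0]: ev for ev in genome.divergence_events}
        for pos, ref, alt in spec.events:
            lo, hi = _event_span((pos, ref, alt))
            for gp, gref, _ga in genome.divergence_events:
                gs, ge = _event_span((gp, gref, _ga))
                if gref and ref and not (hi < gs or ge < lo):
                    raise TruthError(
                        f"planted event at {pos} overlaps a divergence event "
                        f"of genome {spec.genome_label}")
            if ref:
                for i, b in enumerate(ref):
                    actual = _backbone_base(ancestor[pos - 1 + i], gen_events,
                                            pos + i)
                    if actual != b:
                        raise TruthError(
                            f"planted ref mismatch at {pos + i}: event says "
                            f"{b!r}, backbone has {actual!r}")
        merged = merge_events(genome.divergence_events, spec.events)
        sequence = apply_events(ancestor, merged)
        vs_ref = _compose_vs_reference(merged, ref_subs)
        assert apply_events(ref_seq, vs_ref) == sequence
        haplotypes.append(Haplotype(spec.label, spec.genome_label, sequence,
                                    spec.relative_frequency, vs_ref))
        intron_intervals.extend(spec.intron_intervals)
        # auto-detect intron-like planted insertions
        for pos, ref, alt in spec.events:
            if ref == "" and len(alt) >= 4:
                if alt[:2] == "GT" and alt[-2:] == "AG":
                    iv = (pos, len(alt), "canonical")
                elif alt[:2] == "AC" and alt[-2:] == "AT":
                    iv = (pos, len(alt), "non_canonical")
                else:
                    continue
                if iv not in intron_intervals:
                    intron_intervals.append(iv)

    event_freqs: dict[tuple[int, str], float] = {}
    nonref: dict[int, float] = {}
    for hap in haplotypes:
        seen_pos: set[int] = set()
        for pos, ref, alt in hap.events_vs_reference:
            if ref and alt:
                key = [(pos, alt)]
                seen_pos.add(pos)
            elif ref == "":
                key = [(pos, "+" + alt)]
            else:
                key = [(pos + i, "-" + ref[i]) for i in range(len(ref))]
                seen_pos.update(pos + i for i in range(len(ref)))
            for k in key:
                event_freqs[k] = event_freqs.get(k, 0.0) + hap.frequency
        for p in seen_pos:
            nonref[p] = nonref.get(p, 0.0) + hap.frequency

    truth = TruthSet(reference_name, reference_genome, tuple(haplotypes),
                     event_freqs, nonref, tuple(intron_intervals))
    return haplotypes, truth


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def _inject_errors(rng: np.random.Generator, seq: str,
                   model: ErrorModel) -> str:
    if model.substitution_rate == 0 and model.homopolymer_indel_rate == 0:
        return seq
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if model.homopolymer_indel_rate > 0 and rng.random() < model.indel_prob(j - i):
            if rng.random() < 0.5:
                run = run + run[0]      # over-call
            else:
                run = run[:-1]          # under-call
        out.append(run)
        i = j
    seq2 = list("".join(out))
    if model.substitution_rate > 0:
        hits = np.flatnonzero(rng.random(len(seq2)) < model.substitution_rate)
        for h in hits:
            alt = _BASES[int(rng.integers(4))]
            while alt == seq2[h]:
                alt = _BASES[int(rng.integers(4))]
            seq2[h] = alt
    return "".join(seq2)


def _qualities(rng: np.random.Generator, length: int,
               model: ErrorModel) -> tuple[int, ...]:
    xs = np.array([p for p, _m, _s in model.quality_profile])
    means = np.array([m for _p, m, _s in model.quality_profile])
    sds = np.array([s for _p, _m, s in model.quality_profile])
    frac = np.linspace(0.0, 1.0, num=max(length, 1))
    mu = np.interp(frac, xs, means)
    sd = np.interp(frac, xs, sds)
    q = np.clip(np.rint(rng.normal(mu, sd)), 2, 40).astype(int)
    return tuple(int(v) for v in q[:length])


def sample_reads(haplotypes: Sequence[Haplotype], depth: int,
                 error_model: ErrorModel = ErrorModel(),
                 read_length: ReadLengthModel = ReadLengthModel(),
                 seed: int = 0,
                 id_prefix: str = "read",
                 ) -> tuple[list[QualRead], list[str]]:
    """Draw ``depth`` reads multinomially from the pool.

    Returns the reads and, separately, the source haplotype label per read
    (truth only — never encoded in the FASTQ).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    freqs = np.array([h.frequency for h in haplotypes], dtype=float)
    freqs = freqs / freqs.sum()
    reads: list[QualRead] = []
    sources: list[str] = []
    for i in range(depth):
        hap = haplotypes[int(rng.choice(len(haplotypes), p=freqs))]
        template = hap.sequence
        tlen = len(template)
        lo = min(read_length.min_len, tlen)
        length = int(np.rint(rng.normal(read_length.mean, read_length.sd)))
        length = max(lo, min(length, tlen))
        if rng.random() < 0.5:
            sub = template[:length]
        else:
            sub = revcomp(template[tlen - length:])
        sub = _inject_errors(rng, sub, error_model)
        quals = _qualities(rng, len(sub), error_model)
        reads.append(QualRead(f"{id_prefix}{i:06d}", sub, quals))
        sources.append(hap.label)
    return reads, sources


# ---------------------------------------------------------------------------
# library bundles
# ---------------------------------------------------------------------------

def write_truth_bundle(truth: TruthSet, sources_by_library: dict[str, list[str]],
                       outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    with open(outdir / "haplotypes_truth.tsv", "w") as fh:
        fh.write("label\tgenome\tfrequency\tevents\n")
        for h in truth.haplotypes:
            ev = ";".join(f"{p}:{r or '-'}>{a or '-'}"
                          for p, r, a in h.events_vs_reference)
            fh.write(f"{h.label}\t{h.genome_label}\t{h.frequency:.6f}\t{ev or '.'}\n")
    for lib, sources in sources_by_library.items():
        with open(outdir / f"{lib}.sources.tsv", "w") as fh:
            fh.write("read\tsource\n")
            for i, s in enumerate(sources):
                fh.write(f"read{i:06d}\t{s}\n")


def simulate_libraries(panel: Sequence[HomeologPanel],
                       specs_by_library: dict[str, Sequence[PlantedVariant]],
                       depth: int, seed: int,
                       error_model: ErrorModel = ErrorModel(),
                       read_length: ReadLengthModel = ReadLengthModel(),
                       outdir: str | Path | None = None,
                       reference_genome: str = "B",
                       ) -> dict[str, dict]:
    """Per-library FASTQ + truth; per-stage seeds derived from ``seed``."""
    out: dict[str, dict] = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(specs_by_library))
    for (lib, specs), child in zip(sorted(specs_by_library.items()), child_seeds):
        haps, truth = plant_variants(panel, specs,
                                     reference_genome=reference_genome)
        lib_seed = int(child.generate_state(1)[0])
        reads, sources = sample_reads(haps, depth, error_model, read_length,
                                      seed=lib_seed)
        entry = {"reads": reads, "sources": sources, "truth": truth}
        if outdir is not None:
            libdir = Path(outdir)
            libdir.mkdir(parents=True, exist_ok=True)
            write_fastq(reads, libdir / f"{lib}.fastq")
            (libdir / f"{lib}.truth.json").write_text(truth.to_json() + "\n")
            entry["fastq"] = str(libdir / f"{lib}.fastq")
        out[lib] = entry
    return out
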