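"""Reference-guided semi-global alignment of pooled reads and pileup building.

Reads are aligned end-to-end against one reference region with free reference
overhangs (affine gap scoring), the better of the two orientations is kept,
and indels are left-aligned within homopolymer runs so that frequency
aggregation at a single reference position is well defined.

The dynamic programming itself is delegated to Biopython's C
``PairwiseAligner``; op-string extraction, gap normalisation and pileup
accounting are implemented here and checked against brute-force oracles in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .seqio import ConsistencyError, QualRead, ReferenceRegion, revcomp

Op = tuple[str, object]  # ("M", read_seq) | ("I", inserted_seq) | ("D", length)


@dataclass(frozen=True)
class AlignConfig:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0     # score of the first gapped base
    gap_extend: float = -1.0   # score of each further gapped base
    min_identity: float = 0.80


@dataclass(frozen=True)
class ReadAlignment:
    """One read aligned to a reference region.

    ``ops`` reconstruct both sequences exactly: ``M`` ops carry the read
    segment aligned to reference bases, ``I`` the inserted read sequence
    (anchored after the preceding reference position), ``D`` the number of
    deleted reference bases.  ``rp_start`` is the RP of the first aligned
    reference base.
    """

    read_id: str
    region_name: str
    strand: str               # '+' or '-'
    rp_start: int
    ops: tuple[Op, ...]
    score: float
    identity: float

    @property
    def rp_end(self) -> int:
        """RP of the last reference base consumed (inclusive)."""
        span = sum(
            len(p) if op == "M" else (p if op == "D" else 0)
            for op, p in self.ops
        )
        return self.rp_start + span - 1

    def read_sequence(self) -> str:
        """The aligned (strand-corrected) read sequence."""
        return "".join(p for op, p in self.ops if op in ("M", "I"))

    def op_string(self) -> str:
        """Textual form, e.g. ``M:ACGT...;I:ACG;M:TT;D2`` (M carries the read
        segment so the TSV export round-trips exactly)."""
        parts = []
        for op, p in self.ops:
            if op == "M":
                parts.append(f"M:{p}")
            elif op == "I":
                parts.append(f"I:{p}")
            else:
                parts.append(f"D{p}")
        return ";".join(parts)


@dataclass
class PileupColumn:
    """Per-reference-position tally of bases, deletions, and anchored insertions."""

    rp: int
    base_counts: dict[str, int] = field(
        default_factory=lambda: {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0})
    del_count: int = 0
    insertions: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.del_count


def _aligner(cfg: AlignConfig) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = cfg.match
    a.mismatch_score = cfg.mismatch
    a.open_gap_score = cfg.gap_open
    a.extend_gap_score = cfg.gap_extend
    # free reference overhangs: gaps in the read (deletions) at alignment ends
    try:
        a.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        a.query_end_gap_score = 0.0
    return a


def _left_normalize(ref_row: list[str], read_row: list[str]) -> None:
    """Shift every gap run as far left as its homopolymer context allows.

    Operates in place on the two gapped alignment rows; score-preserving by
    construction (a base only trades places with an equal character).
    """
    changed = True
    while changed:
        changed = False
        for row, other in ((read_row, ref_row), (ref_row, read_row)):
            c = 0
            n = len(row)
            while c < n:
                if row[c] != "-":
                    c += 1
                    continue
                a = c
                while c < n and row[c] == "-":
                    c += 1
                b = c - 1  # gap run [a, b] in `row`
                while (
                    a > 0
                    and row[a - 1] != "-"
                    and other[a - 1] != "-"
                    and other[a - 1] == other[b]
                ):
                    row[b] = row[a - 1]
                    row[a - 1] = "-"
                    a -= 1
                    b -= 1
                    changed = True


def _rows_to_ops(ref_row: Sequence[str], read_row: Sequence[str]) -> tuple[Op, ...]:
    ops: list[Op] = []
    for r, q in zip(ref_row, read_row):
        if r != "-" and q != "-":
            if ops and ops[-1][0] == "M":
                ops[-1] = ("M", ops[-1][1] + q)
            else:
                ops.append(("M", q))
        elif r == "-":
            if ops and ops[-1][0] == "I":
                ops[-1] = ("I", ops[-1][1] + q)
            else:
                ops.append(("I", q))
        else:
            if ops and ops[-1][0] == "D":
                ops[-1] = ("D", ops[-1][1] + 1)
            else:
                ops.append(("D", 1))
    return tuple(ops)


def _align_oriented(seq: str, region: ReferenceRegion,
                    aligner: Align.PairwiseAligner):
    aln = aligner.align(region.sequence, seq)[0]
    return aln.score, aln


def align_read(read: QualRead | str, region: ReferenceRegion,
               cfg: AlignConfig = AlignConfig()) -> ReadAlignment | None:
    """Best semi-global alignment of a read; ``None`` when identity falls
    below ``cfg.min_identity`` (unaligned is a return state, not an error)."""
    read_id = read.id if isinstance(read, QualRead) else "read"
    seq = (read.seq if isinstance(read, QualRead) else read).upper()
    if not seq:
        return None
    aligner = _aligner(cfg)
    fwd_score, fwd = _align_oriented(seq, region, aligner)
    rc = revcomp(seq)
    rev_score, rev = _align_oriented(rc, region, aligner)
    if rev_score > fwd_score:
        strand, aln, score = "-", rev, rev_score
    else:
        strand, aln, score = "+", fwd, fwd_score

    ref_row = list(str(aln[0]))
    read_row = list(str(aln[1]))
    # strip the free end-deletion columns (reference overhangs)
    lead = 0
    while lead < len(read_row) and read_row[lead] == "-":
        lead += 1
    tail = len(read_row)
    while tail > lead and read_row[tail - 1] == "-":
        tail -= 1
    ref_row = ref_row[lead:tail]
    read_row = read_row[lead:tail]
    _left_normalize(ref_row, read_row)

    matches = sum(1 for r, q in zip(ref_row, read_row) if r == q and r != "-")
    columns = len(ref_row)
    identity = matches / columns if columns else 0.0
    if identity < cfg.min_identity:
        return None
    ops = _rows_to_ops(ref_row, read_row)
    return ReadAlignment(
        read_id=read_id,
        region_name=region.name,
        strand=strand,
        rp_start=region.to_rp(lead + 1),
        ops=ops,
        score=float(score),
        identity=identity,
    )


def reconstruct_read(aln: ReadAlignment) -> str:
    """Round-trip helper: the original read as sequenced (strand applied)."""
    seq = aln.read_sequence()
    return revcomp(seq) if aln.strand == "-" else seq


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def _mask_ranges_for_read(aln: ReadAlignment,
                          primer_intervals: Iterable[tuple[int, int]]
                          ) -> list[tuple[int, int]]:
    """RP ranges of this read that fall on primer-synthesised bases.

    A read end lying inside a primer interval means those terminal bases were
    copied from the primer, not the template, so they must not vote.
    """
    masked = []
    for s, e in primer_intervals:
        if s <= aln.rp_start <= e:
            masked.append((aln.rp_start, e))
        if s <= aln.rp_end <= e:
            masked.append((s, aln.rp_end))
    return masked


def build_pileup(alignments: Iterable[ReadAlignment],
                 primer_intervals: Iterable[tuple[int, int]] = (),
                 ) -> dict[int, PileupColumn]:
    """Per-RP pileup columns from alignments against one region.

    Positions never covered are omitted.  ``primer_intervals`` are RP
    intervals whose primer-derived read-end bases are excluded from counts.
    """
    primer_intervals = tuple(primer_intervals)
    columns: dict[int, PileupColumn] = {}
    region_names = set()

    def col(rp: int) -> PileupColumn:
        c = columns.get(rp)
        if c is None:
            c = columns[rp] = PileupColumn(rp)
        return c

    for aln in alignments:
        region_names.add(aln.region_name)
        if len(region_names) > 1:
            raise ConsistencyError(
                f"pileup over mixed references: {sorted(region_names)}")
        masked = _mask_ranges_for_read(aln, primer_intervals)

        def is_masked(rp: int) -> bool:
            return any(s <= rp <= e for s, e in masked)

        rp = aln.rp_start
        for op, payload in aln.ops:
            if op == "M":
                for base in payload:
                    if not is_masked(rp):
                        c = col(rp)
                        c.base_counts[base if base in c.base_counts else "N"] += 1
                    rp += 1
            elif op == "D":
                for _ in range(int(payload)):
                    if not is_masked(rp):
                        col(rp).del_count += 1
                    rp += 1
            else:  # insertion anchored after the previous reference base
                anchor = rp - 1
                if not is_masked(anchor):
                    c = col(anchor)
                    c.insertions[payload] = c.insertions.get(payload, 0) + 1
    return columns


def write_alignment_tsv(alignments: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tregion\tstrand\trp_start\trp_end\tidentity\tscore\tops\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.region_name}\t{a.strand}\t{a.rp_start}\t"
                     f"{a.rp_end}\t{a.identity:.4f}\t{a.score:g}\t{a.op_string()}\n")


def read_alignment_tsv(path) -> list[ReadAlignment]:
    """Round-trip reader for :func:`write_alignment_tsv` output."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ops: list[Op] = []
            rp = int(f[idx["rp_start"]])
            for part in f[idx["ops"]].split(";"):
                if part.startswith("I:"):
                    ops.append(("I", part[2:]))
                elif part.startswith("M:"):
                    ops.append(("M", part[2:]))
                elif part.startswith("D"):
                    ops.append(("D", int(part[1:])))
                else:
                    raise ValueError(f"bad op {part!r}")
            out.append(ReadAlignment(
                f[idx["read"]], f[idx["region"]], f[idx["strand"]], rp,
                tuple(ops), float(f[idx["score"]]),
                float(f[idx["identity"]])))
    return out


def read_pileup_tsv(path) -> dict[int, PileupColumn]:
    """Round-trip reader for :func:`write_pileup_tsv` output."""
    columns: dict[int, PileupColumn] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rp = int(f[0])
            col = PileupColumn(rp)
            for base, v in zip("ACGTN", f[2:7]):
                col.base_counts[base] = int(v)
            col.del_count = int(f[7])
            if f[8] != ".":
                for item in f[8].split(","):
                    seq, n = item.rsplit(":", 1)
                    col.insertions[seq] = int(n)
            columns[rp] = col
    return columns


def write_pileup_tsv(columns: dict[int, PileupColumn], path) -> None:
    with open(path, "w") as fh:
        fh.write("RP\tdepth\tA\tC\tG\tT\tN\tdel\tinsertions\n")
        for rp in sorted(columns):
            c = columns[rp]
            ins = ",".join(f"{s}:{n}" for s, n in sorted(c.insertions.items()))
            b = c.base_counts
            fh.write(f"{rp}\t{c.depth}\t{b['A']}\t{b['C']}\t{b['G']}\t{b['T']}\t"
                     f"{b['N']}\t{c.del_count}\t{ins or '.'}\n")
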