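"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention
---------------------
Internally every position is 1-based inclusive on the supplied region.
User-facing positions are *Reference Positions* (RP): the internal 1-based
position plus the region's ``rp_offset``.  With ``rp_offset=0`` internal and
reported coordinates coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: IUPAC degenerate base -> set of concrete bases (used for primer matching
#: only; degenerate codes are never written into consensus output).
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input record."""


class ConsistencyError(ValueError):
    """Internally inconsistent data handed to a writer."""


@dataclass(frozen=True)
class QualRead:
    """A read: identifier, IUPAC base string, per-base Phred scores."""

    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ParseError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReferenceRegion:
    """A reference sequence plus the offset mapping internal coordinates to RPs.

    Parameters
    ----------
    name:
        Region identifier (FASTA header word).
    sequence:
        Uppercase IUPAC DNA.
    rp_offset:
        Added to internal 1-based positions to obtain reported RPs.
    cds_start_rp:
        RP of the first base of the start codon, or ``None`` when the region
        is non-coding.
    """

    name: str
    sequence: str
    rp_offset: int = 0
    cds_start_rp: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(f"non-IUPAC characters in reference: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if self.cds_start_rp is not None:
            internal = self.to_internal(self.cds_start_rp)
            if not 1 <= internal <= len(seq):
                raise ValueError("cds_start_rp outside the region")

    def __len__(self) -> int:
        return len(self.sequence)

    def to_rp(self, internal_pos: int) -> int:
        return internal_pos + self.rp_offset

    def to_internal(self, rp: int) -> int:
        return rp - self.rp_offset

    def base_at_rp(self, rp: int) -> str:
        return self.sequence[self.to_internal(rp) - 1]

    @property
    def rp_interval(self) -> tuple[int, int]:
        return self.to_rp(1), self.to_rp(len(self.sequence))


@dataclass(frozen=True)
class AmpliconDef:
    """A primer pair and the reference interval it amplifies."""

    pair_name: str
    fwd_primer: str
    rev_primer: str
    rp_start: int
    rp_end: int

    def __post_init__(self) -> None:
        for p in (self.fwd_primer, self.rev_primer):
            if not 17 <= len(p) <= 25:
                raise ValueError(f"primer length {len(p)} outside 17-25 nt: {p}")
            if set(p.upper()) - IUPAC_DNA:
                raise ValueError(f"non-IUPAC primer: {p}")
        if not self.rp_start < self.rp_end:
            raise ValueError("amplicon interval start must be < end")

    @property
    def primer_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """RP intervals covered by the forward and reverse primers."""
        f = (self.rp_start, self.rp_start + len(self.fwd_primer) - 1)
        r = (self.rp_end - len(self.rev_primer) + 1, self.rp_end)
        return f, r


@dataclass(frozen=True)
class AllelePanelEntry:
    """A named reference allele with its genome assignment."""

    allele_name: str
    genome_label: str  # one of A, B, D, unassigned
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.genome_label not in {"A", "B", "D", "unassigned"}:
            raise ValueError(f"bad genome label {self.genome_label!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(stream: TextIO | str | Path) -> list[QualRead]:
    """Parse a Phred+33 FASTQ stream into :class:`QualRead` records."""
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return read_fastq(fh)
    reads: list[QualRead] = []
    lines = (ln.rstrip("\n") for ln in stream)
    idx = 0
    while True:
        try:
            header = next(lines)
        except StopIteration:
            return reads
        if header == "":
            continue
        try:
            seq = next(lines)
            plus = next(lines)
            qual = next(lines)
        except StopIteration:
            raise ParseError(f"record {idx}: truncated FASTQ record") from None
        if not header.startswith("@") or not plus.startswith("+"):
            raise ParseError(f"record {idx}: malformed FASTQ record")
        if len(seq) != len(qual):
            raise ParseError(
                f"record {idx}: quality length {len(qual)} != base length {len(seq)}"
            )
        quals = tuple(ord(c) - 33 for c in qual)
        if any(q < 0 for q in quals):
            raise ParseError(f"record {idx}: quality character below '!'")
        reads.append(QualRead(header[1:].split()[0], seq.upper(), quals))
        idx += 1


def write_fastq(reads: Iterable[QualRead], path: str | Path | TextIO) -> None:
    if not hasattr(path, "write"):
        with open(path, "w") as fh:
            write_fastq(reads, fh)
            return
    for r in reads:
        qual = "".join(chr(q + 33) for q in r.quals)
        path.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_fasta(path: str | Path | TextIO) -> dict[str, str]:
    """Name -> uppercase sequence, order-preserving."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(entries: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    items = entries.items() if isinstance(entries, dict) else entries
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_allele_panel(path: str | Path) -> list[AllelePanelEntry]:
    """FASTA whose headers are ``name genome=<A|B|D|unassigned> [source]``."""
    entries = []
    from Bio import SeqIO

    for rec in SeqIO.parse(path, "fasta"):
        genome = "unassigned"
        source = ""
        for tok in rec.description.split()[1:]:
            if tok.startswith("genome="):
                genome = tok.split("=", 1)[1]
            elif tok.startswith("source="):
                source = tok.split("=", 1)[1]
        entries.append(AllelePanelEntry(rec.id, genome, str(rec.seq), source))
    if len({e.allele_name for e in entries}) != len(entries):
        raise ConsistencyError("duplicate allele names in panel")
    return entries


# ---------------------------------------------------------------------------
# Variant report TSV
# ---------------------------------------------------------------------------

MISSING = "."


def write_variant_report(calls, libraries: list[str],
                         path: str | Path) -> pd.DataFrame:
    """Write the combined per-position variant report.

    One row per (RP, event); columns ``RP, type, ref, alt, status`` then
    ``<lib>_freq`` (percent, 1 decimal) and ``<lib>_depth`` per library.
    Rows sorted ascending by RP, then alt.  Absent values are ``.``.

    ``calls`` is an iterable of objects exposing ``rp, event_type, ref, alt,
    status, per_library`` where ``per_library`` maps library name ->
    ``(frequency_pct, depth)``.
    """
    rows = []
    seen = set()
    for c in calls:
        key = (c.rp, c.alt, c.event_type)
        if key in seen:
            raise ConsistencyError(f"duplicate report row for {key}")
        seen.add(key)
        row: dict[str, object] = {
            "RP": c.rp, "type": c.event_type, "ref": c.ref,
            "alt": c.alt, "status": c.status,
        }
        for lib in libraries:
            freq, depth = c.per_library.get(lib, (None, None))
            row[f"{lib}_freq"] = MISSING if freq is None else f"{freq:.1f}"
            row[f"{lib}_depth"] = MISSING if depth is None else int(depth)
        rows.append(row)
    cols = ["RP", "type", "ref", "alt", "status"]
    for lib in libraries:
        cols += [f"{lib}_freq", f"{lib}_depth"]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["RP", "alt"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_variant_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["RP"] = df["RP"].astype(int)
    return df


def write_vcf(calls, region: ReferenceRegion, path: str | Path) -> None:
    """Secondary VCF 4.2 export: one ALT per line, AF in INFO (fractions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={region.name},length={len(region)}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Maximum per-library alternate frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="Maximum per-library depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.rp, c.alt)):
            pos = region.to_internal(c.rp)
            if c.alt.startswith("+"):  # insertion after rp
                ref = region.sequence[pos - 1]
                alt = ref + c.alt[1:]
            elif c.alt.startswith("-"):  # deletion of bases at rp
                deleted = c.alt[1:]
                if pos == 1:
                    continue  # cannot left-anchor a deletion at position 1
                ref = region.sequence[pos - 2] + deleted
                alt = region.sequence[pos - 2]
                pos -= 1
            else:
                ref, alt = c.ref, c.alt
            freqs = [f for f, _ in c.per_library.values() if f is not None]
            depths = [d for _, d in c.per_library.values() if d is not None]
            af = max(freqs) / 100.0 if freqs else 0.0
            dp = max(depths) if depths else 0
            fh.write(f"{region.name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"AF={af:.4f};DP={dp}\n")


# ---------------------------------------------------------------------------
# JSON manifest
# ---------------------------------------------------------------------------

def write_manifest(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
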