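"""End-to-end orchestration: trim -> align -> call -> haplotype -> annotate
-> introns, with a reproducible run manifest.

Every stage is deterministic, so re-running an identical config produces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .align import AlignConfig, align_read, build_pileup, write_alignment_tsv, \
    write_pileup_tsv
from .calls import CallConfig, accepted_event_set, call_pileup, combine_reports
from .consequence import ConsequenceRecord, annotate_snp, default_motifs, \
    annotate_variant_protein, tally_consequences, write_consequence_tsv
from .haplotypes import GroupConfig, assign_allele, frequency_table, \
    group_reads, write_haplotype_table
from .introns import detect_frame_disruption, scan_introns, write_intron_tsv
from .qc import TrimConfig, trim_library
from .seqio import AllelePanelEntry, ReferenceRegion, read_fastq, write_fasta, \
    write_manifest, write_variant_report, write_vcf

logger = logging.getLogger("amphap")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    region: ReferenceRegion
    libraries: Mapping[str, str | Path]        # name -> FASTQ path
    outdir: str | Path
    amplicon_interval: tuple[int, int] | None = None
    primer_intervals: Sequence[tuple[int, int]] = ()
    panel: Sequence[AllelePanelEntry] = ()
    trim: TrimConfig = field(default_factory=TrimConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    call: CallConfig = field(default_factory=CallConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    della_interval: tuple[int, int] | None = None
    intron_max_len: int = 200
    seed: int = 0
    vcf_export: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the summary dict also written to summary.json."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region = cfg.region
    interval = cfg.amplicon_interval or region.rp_interval
    logger.info("thresholds: trim=%s call=%s align=%s group=%s",
                cfg.trim, cfg.call, cfg.align, cfg.group)

    per_lib_calls = {}
    per_lib_alignments = {}
    trim_rows = []
    for lib in sorted(cfg.libraries):
        path = cfg.libraries[lib]
        try:
            reads = read_fastq(path)
        except Exception as exc:
            raise StageError("read_fastq", f"library {lib}: {exc}") from exc
        kept, ts = trim_library(reads, cfg.trim)
        trim_rows.append((lib, ts))
        alignments = []
        for r in kept:
            try:
                a = align_read(r, region, cfg.align)
            except Exception as exc:
                raise StageError("align", f"library {lib}, read {r.id}: {exc}") \
                    from exc
            if a is not None:
                alignments.append(a)
        per_lib_alignments[lib] = alignments
        pileup = build_pileup(alignments, cfg.primer_intervals)
        per_lib_calls[lib] = call_pileup(pileup, region, cfg.call)
        write_alignment_tsv(alignments, outdir / f"{lib}.alignments.tsv")
        write_pileup_tsv(pileup, outdir / f"{lib}.pileup.tsv")
        logger.info("library %s: %d reads, %d kept, %d aligned, %d raw events",
                    lib, len(reads), len(kept), len(alignments),
                    len(per_lib_calls[lib]))

    with open(outdir / "trim_summary.tsv", "w") as fh:
        fh.write("library\treads_in\treads_kept\tmean_len_in\tmean_len_kept\n")
        for lib, ts in trim_rows:
            fh.write(f"{lib}\t{ts.n_in}\t{ts.n_kept}\t{ts.mean_len_in:.1f}\t"
                     f"{ts.mean_len_kept:.1f}\n")

    combined, variant_summary = combine_reports(per_lib_calls, cfg.call)
    libraries = sorted(cfg.libraries)
    write_variant_report(combined, libraries, outdir / "combined_variants.tsv")
    if cfg.vcf_export:
        write_vcf(combined, region, outdir / "combined_variants.vcf")
    accepted = accepted_event_set(combined)

    variants_by_library = {}
    for lib in libraries:
        variants = group_reads(per_lib_alignments[lib], region, interval,
                               accepted, cfg.group)
        if cfg.panel:
            variants = [assign_allele(v, cfg.panel, cfg.align) for v in variants]
        variants_by_library[lib] = variants
    write_haplotype_table(variants_by_library, outdir / "haplotypes.tsv")
    freq_df = frequency_table(variants_by_library)
    freq_df.to_csv(outdir / "frequency_table.tsv", sep="\t",
                   float_format="%.2f")

    # one representative per distinct event string (maximal support)
    distinct = {}
    for lib in libraries:
        for v in variants_by_library[lib]:
            old = distinct.get(v.events)
            if old is None or v.read_count > old.read_count:
                distinct[v.events] = v
    write_fasta([(v.variant_id, v.consensus)
                 for _e, v in sorted(distinct.items())],
                outdir / "consensus.fasta")

    motifs = default_motifs(cfg.della_interval)
    records: list[ConsequenceRecord] = []
    if region.cds_start_rp is not None:
        for c in combined:
            if c.status in ("called", "cross_confirmed") and c.event_type == "snp":
                records.append(annotate_snp(c.rp, c.alt, region, motifs,
                                            variant_id=f"RP{c.rp}{c.alt}"))
    write_consequence_tsv(records, outdir / "consequences.tsv")
    tally = tally_consequences(records)

    intron_calls = []
    protein_diffs = []
    if region.cds_start_rp is not None:
        for _events, v in sorted(distinct.items()):
            diff = annotate_variant_protein(v, region, interval)
            protein_diffs.append(diff)
            disruption = detect_frame_disruption(v, region, interval)
            if disruption.disrupted:
                calls = scan_introns(v, region, interval,
                                     max_len=cfg.intron_max_len)
                intron_calls.extend(calls[:10])
    write_intron_tsv(intron_calls, outdir / "introns.tsv")

    summary = {
        "variant_summary": variant_summary,
        "consequence_summary": tally,
        "n_haplotype_variants": {lib: len(v)
                                 for lib, v in variants_by_library.items()},
        "n_intron_calls": len(intron_calls),
        "trim": {lib: ts.__dict__ for lib, ts in trim_rows},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "region": {"name": region.name, "length": len(region),
                   "rp_offset": region.rp_offset,
                   "cds_start_rp": region.cds_start_rp},
        "libraries": {lib: str(cfg.libraries[lib]) for lib in libraries},
        "thresholds": {
            "trim": cfg.trim.__dict__,
            "call": cfg.call.__dict__,
            "align": cfg.align.__dict__,
            "group": cfg.group.__dict__,
            "intron_max_len": cfg.intron_max_len,
        },
        "outputs": {p.name: _sha256(p)
                    for p in sorted(outdir.glob("*.tsv"))},
    }
    write_manifest(manifest, outdir / "manifest.json")
    return summary
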