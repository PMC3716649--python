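# amphap

Deep amplicon-pool analysis for polyploid gene families: from pooled
(454-style) amplicon reads to per-position SNP/indel calls, linked-variant
haplotypes with relative frequencies, genome/allele assignment,
protein-consequence annotation, putative spliceosomal-intron detection, and
two-point linkage placement of a variant marker on a doubled-haploid map.
A synthetic hexaploid amplicon-pool generator with exact planted truth makes
every stage testable without external data.

## Pipeline stages

| module | role |
| --- | --- |
| `amphap.simulate` | homeolog panel + planted haplotypes + read sampling with exact `TruthSet` |
| `amphap.scenarios` | deterministic validation scenario with one of every variant class |
| `amphap.seqio` | FASTA/FASTQ/TSV/VCF readers & writers, RP coordinate convention |
| `amphap.qc` | modified-Mott quality trimming (limit 0.05) + terminal-ambiguity trimming |
| `amphap.align` | semi-global affine-gap alignment, indel left-alignment, pileups |
| `amphap.calls` | SNP/indel calling (depth ≥ 40, frequency ≥ 20 %) + cross-library rare-variant confirmation |
| `amphap.haplotypes` | linked-event haplotype grouping, allele assignment, frequency tables |
| `amphap.consequence` | codon arithmetic, nonsense/missense/synonymous classes, motif hits |
| `amphap.introns` | frame-disruption detection and GT..AG / AC..AT intron scanning |
| `amphap.linkmap` | two-point linkage (Kosambi/Haldane) and marker placement |
| `amphap.pipeline` | end-to-end orchestration with a reproducible manifest |

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (zero-error
end-to-end recovery at depth 2000×3 libraries, threshold boundary suite,
brute-force oracle equivalences, linkage recovery over 200 replicates); the
remaining files are per-module unit and property tests.

## CLI

```bash
# write a synthetic fixture (3 libraries + truth + reference + run.toml)
amphap simulate --out fixture/ --seed 1 --depth 500

# full pipeline from a TOML config
amphap run --config fixture/run.toml --out results/

# individual stages
amphap trim in.fastq out.fastq --limit 0.05 --max-ambig 4 --min-len 50 --summary trim.tsv
amphap align out.fastq reference.fasta --out aln.tsv --pileup pileup.tsv
amphap call reference.fasta lib1.pileup.tsv lib2.pileup.tsv --out combined.tsv
amphap annotate reference.fasta combined.tsv --cds-start-rp 104 --out consequences.tsv
amphap introns reference.fasta variants.fasta --cds-start-rp 104 --out introns.tsv
amphap map genotypes.csv map.csv my_marker --alpha 0.001
```

## Conventions

- Coordinates are 1-based inclusive; user-facing positions are Reference
  Positions (`RP = internal position + rp_offset`).
- Variant alt encoding: plain base for a SNP, `+SEQ` for an insertion
  anchored after the RP, `-B` for deletion of base B at the RP; indels are
  left-aligned within homopolymer runs.
- All randomness flows from a single seed; identical configs give
  byte-identical outputs.
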