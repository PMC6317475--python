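# splicepept

A proteogenomics toolkit for discovering novel protein-coding regions with
peptide-level mass-spectrometry evidence, modelled on large-scale
rice-genome reannotation workflows. It is written for computational
biologists who have (a) an assembled transcriptome and splice-junction
calls from RNA-Seq and (b) peptide-spectrum matches (PSMs) from searching
MS/MS data, and who want to turn those into a confidently filtered set of
novel peptides placed on the genome.

## What it does

1. **Novelty calling** — assembled transcripts are *known* when their full
   intron chain matches an official transcript (exon-end jitter ignored);
   observed junctions are *known* when the identical intron interval is
   annotated. Everything else becomes a novel transcript (NT) or novel
   junction (NJ); together, the novel events (NEs).
2. **Customized search database** — each NE's spliced DNA (exon chain, or
   ±96 nt around a novel intron) is translated in six reading frames; the
   single longest stop-free product of ≥ 5 aa joins the official proteome
   and a contaminant list as the search space, with full genomic
   provenance per entry.
3. **FDR control and partitioning** — target-decoy q-values per PSM
   (FDR at rank *i* = #decoys/#targets, q = running minimum); PSMs with
   q < 0.01 are grouped into peptides, each *known* (matches an official
   or contaminant protein) or a *putative novel peptide* (PNP).
4. **Exclusion cascade** — four independent filters turn PNPs into *final
   novel peptides* (FNPs): exact substring of a known protein (any
   termini); equal-length one-mismatch window match; explainability as a
   known peptide with a common modification (precursor mass-delta screen
   + external exclusion list); and a ≥ 2-spectra requirement. Flags are
   recorded per filter for Venn-style accounting.
5. **Genome mapping** — FNPs are placed back on the genome through entry
   provenance as nucleotide-exact blocks (splitting at junctions),
   classified unique/multi-mapping and intergenic/intragenic, and written
   as proBed for genome browsers.
6. **Event clustering** — NEs within 100 bp merge into clusters; a cluster
   with an NT is an NT cluster (an intergenic one is a novel gene
   candidate), otherwise an NJ cluster.
7. **Coding potential** — logistic model over ORF size, Fickett TESTCODE
   score and hexamer log-ratio score, trained on labeled transcripts,
   giving each NT a coding probability (CP).

A seeded synthetic-fixture generator (`splicepept.synthetic_fixtures`)
builds a miniature genome, annotation, transcriptome, proteome and PSM
table with planted truths, so the entire pipeline is testable offline.

## Worked example

```bash
splicepept fixtures --seed 17 --out fx/
splicepept run \
  --genome fx/genome.fa --reference-gtf fx/reference.gtf \
  --assembled-gtf fx/assembled.gtf --junction-bed fx/junctions.bed \
  --proteome fx/proteome.fa --contaminants fx/contaminants.fa \
  --psm-table fx/psms.tsv --exclusion fx/exclusion.tsv \
  --cp-coding fx/cp_coding.fa --cp-noncoding fx/cp_noncoding.fa \
  --outdir out/
```

The run prints a per-stage JSON summary; on the seed-17 fixture it reports

```
"events":         { "novel_transcripts": 18, "novel_junction_sites": 8, "novel_events": 26, ... }
"identification": { "psms_total": 335, "psms_accepted": 164, "known_peptides": 56, "pnps": 28, ... }
"filtration":     { "pnps_in": 28, "removed": 16, "fnps": 12, ... }
"mapping":        { "fnps": 12, "unique_mapping": 12, "intergenic": 9, "intragenic": 3 }
"clustering":     { "clusters_total": 26, "clusters_with_fnps": 9, "nt_clusters": 4, "nj_clusters": 5 }
```

meaning: 26 novel events were called, 28 identified peptides matched only
novel database entries, the cascade removed 16 of them (one-mismatch
variants of known peptides, modification-explainable spectra, and
single-spectrum identifications), and the 12 surviving FNPs — exactly the
genuinely novel multi-spectrum peptides planted by the generator — all map
uniquely, 9 to intergenic loci. Stage outputs (`fnps.probed`,
`cluster_report.tsv`, `cp_scores.tsv`, …) land in `out/`.

The same stages are available individually (`splicepept events`,
`builddb`, `fdr`, `filter`, `map`, `cluster`, `cpat-train`,
`cpat-score`), and as library functions.

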