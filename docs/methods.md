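# Methods

This note documents the models, conventions and numerical choices behind
`splicepept`, and what the synthetic fixtures do and do not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward genomic
strand; conversion to 1-based inclusive happens only in the GTF
reader/writer. A junction is always the intron interval (first intronic
base to one past the last), which is unambiguous across BED dialects: in
BED12 input the junction is the gap between the two blocks, in BED6 the
feature interval itself. Junctions from unstranded libraries carry strand
"." and match annotated introns on either strand.

The PSM table is a neutral TSV (columns: spectrum_id, dataset_id, peptide,
charge, precursor_mass, score, is_decoy, db_entries) rather than
mzIdentML: the pipeline's contract with upstream search engines is only a
ranked score per PSM, so a documented column set replaces a heavyweight
format. proBed output is the BED12 core plus peptide sequence,
uniqueness, PSM score, FDR class and modifications, with unknown optional
fields written as ".".

## Novelty calling

Multi-exon transcripts are compared by intron chain: identity of the
ordered intron tuple on the same chromosome and strand defines "known",
so exon-end differences never affect the call. Mono-exonic transcripts
are known when fully contained within one exon of a same-strand official
transcript — a conservative, deterministic stand-in for assembler class
codes, whose mono-exonic semantics are fuzzy. Merging of per-run
assemblies deduplicates multi-exon transcripts by intron chain (keeping
the widest span) and mono-exonic ones by containment; the merge is
idempotent. Observed junctions are deduplicated to sites on
(chrom, strand, start, end) before classification; occurrence-level and
site-level counts are both reported because summary statistics can be
quoted either way.

A novel junction identical to an intron of a retained novel transcript is
subsumed into that transcript's event (configurable off) to avoid double
counting in clusters. Event ids are deterministic
(`NT:<chrom>:<start>-<end>:<strand>:<chain hash>`), so database headers
and cluster memberships are reproducible across runs.

## Database construction

Novel-event fragments are translated in six frames and split at stop
codons; products are maximal stop-free stretches, not ATG-initiated ORFs,
because peptide evidence does not require an initiator codon within the
fragment. One product per event is kept: the longest with ≥ 5 aa, ties
broken by frame order (+0,+1,+2,−0,−1,−2) then smallest offset. The
novel-junction flank defaults to 96 nt (32 codons) per side, which exceeds
the arm length of any plausible tryptic peptide; it is configurable. A
separate ≥ 6 aa minimum applies to entries exported for searching,
mirroring typical search-engine minima — distinct from the 5-aa product
rule. Decoys, when requested, are full-sequence reversals with accession
prefix `XXX_`. Every novel entry records (event id, blocks, strand,
frame, codon offset), sufficient to map any substring to nucleotide-exact
genomic blocks; a codon crossing a block boundary contributes its
nucleotides to both blocks.

## FDR and partitioning

q-values use the standard target-decoy estimate: PSMs sorted by score,
FDR at a level = decoys/targets accumulated so far (targets-only
denominator; the +1-corrected variant is a documented alternative),
q = running minimum from the worst score upward, ties sharing a level.
Acceptance is strictly q < 0.01. Peptides group by exact sequence with
I/L distinct (as engines report them); a peptide matching any official or
contaminant entry is "known" (contaminant matches are flagged and can
never be novel), and a peptide matching only novel entries is a PNP.
Identification-summary rates are percentages rounded half-up to two
decimals; per-dataset spectra columns are additive but peptide columns
count distinct sequences, so column sums can exceed the distinct totals.

## The exclusion cascade

The four filters are evaluated independently on every PNP (no
short-circuiting), so overlap tables reproduce Venn-style accounting.
The one-mismatch filter is an exhaustive equal-length window scan
(≤ 1 substitution, no gaps), a strict superset of both a default and a
short-sequence-optimized BLASTp run with those acceptance rules, and of
the substring filter. The modification screen is deliberately *not* a
spectrum-level re-search: it flags a peptide when some PSM precursor mass
equals a known tryptic peptide mass (≤ 2 missed cleavages) plus a common
modification delta — oxidation +15.9949, phosphorylation +79.9663,
acetylation +42.0106, deamidation +0.9840, or no modification — within
0.02 Da (typical high-resolution precursor tolerance, configurable), or
when the peptide appears in an externally supplied exclusion list from a
dedicated PTM search tool. Optional I=L equivalence exists for the
sequence filters (default off, matching strict identity). The spectral
filter requires ≥ 2 PSMs.

## Mapping, locus classes and clustering

A peptide's placements are enumerated over every novel entry containing
it and deduplicated by (chrom, strand, blocks); "unique" means all
placements collapse to one locus. Locus classification uses official
*gene spans* (hull over a gene's transcripts) and ignores strand, so
intronic and antisense placements count as intragenic; exon-level
classification is available as an option. Clustering is single-linkage
per chromosome with a half-open gap rule: events merge when
`next.start − prev.end ≤ 100` (so a gap of exactly 100 merges, 101 does
not), strand-agnostic by default. Unique-mapping FNPs attach to the
clusters containing their source events; clusters with no attached FNP
are retained but excluded from the FNP-bearing cluster counts. In the
count table, the all-FNP row includes multi-mapping peptides only when
all their placements agree on one locus class.

## Coding potential

Three features per transcript: longest forward-strand ATG..stop ORF
length in nt (stop included); the Fickett TESTCODE statistic, computed
with the fixed published positional-bias and composition lookup tables
(external constants, not tunable); and a hexamer score — the mean
log-ratio of hexamer usage between coding and noncoding training corpora
over in-frame (step-3) hexamers of the longest ORF, falling back to the
whole sequence when no ORF exists. Both corpora are counted with the
same extraction rule and add-one smoothing, which makes the table exactly
antisymmetric under corpus swap and zero for identical corpora; this
differs from tools that count noncoding hexamers in all frames, trading a
little discrimination for exact symmetry properties. For CDS input the
longest ORF is the annotated frame.

The classifier is an unpenalized logistic regression on the three
features standardized by training means/SDs, fit with the deterministic
L-BFGS optimizer (max 100 iterations, tolerance 1e-8); coefficients are
capped at |30| with a warning under near-perfect separation. The decision
threshold maximizes balanced accuracy on the training data (smallest
maximizer under ties); a transcript is labeled coding when CP ≥ threshold.
CP is reported at full precision, never rounded to a saturated 100%.

## Synthetic fixtures

The generator emulates the study's inputs at desk scale: 2 chromosomes ×
100 kb, 40 multi-exon genes with GT..AG introns and complete ATG..stop
ORFs (proteome by translation), an assembled transcriptome containing
exact/end-jittered copies of every official transcript plus planted
novelty — exon-skipping transcripts, intergenic transcript chains,
single-substitution intergenic copies of official genes (the source of
variant-like peptides), shifted and intergenic novel junctions — and a
PSM table with planted truths: multi-spectrum genuinely novel peptides,
single-spectrum novels, one-mismatch mutants and non-tryptic substrings
of known peptides, modification-explainable precursors, externally
excluded peptides, and an exact count of decoy PSMs. Tryptic digestion
cleaves after K/R but not before P, with 0–2 missed cleavages; precursor
masses are monoisotopic (residues + water) with planted deltas where
intended.

Scores follow a two-normal model: decoys N(5,1), ordinary targets N(8,1)
(means 3 SD apart), planted truths N(12,0.5). Planted PSMs sit in the
confident upper tail by construction — their real-world counterparts are
the confidently identified spectra — which makes the 1% q-value cut
accept them at any seed, so truth-recovery checks are exact rather than
probabilistic. Peptides planted to *survive* the cascade are verified at
generation time against the same substring/one-mismatch/mass-screen
arithmetic the pipeline applies (at fixture scale, a random peptide's
mass collides with "known + modification" within 0.02 Da often enough
that unchecked planting would poison exact recovery).

What passing fixture tests show: the machinery — novelty calling,
translation and provenance round-trips, q-value accounting, filter logic,
splice-aware coordinate arithmetic, clustering — is correct on inputs
whose ground truth is known. What they do not show: behaviour under real
search-engine score distributions, homologous gene families (the random
proteome has far fewer near-duplicate sequences than a real one),
chimeric spectra, or annotation errors beyond the planted classes.

The coding/noncoding training corpora are likewise synthetic: coding
transcripts carry a 150–350-codon ORF with one fixed codon per amino acid
(a strong but simple usage bias) between short UTRs; noncoding
transcripts are uniform random DNA. These are linearly separable in the
three features — the held-out AUC ≥ 0.95 check validates the training and
thresholding machinery, not performance on real transcriptomes.

## Problem sizes and determinism

Default fixture scale (40 genes, ~26 novel events, ~335 PSMs) runs the
full pipeline in a few seconds; oracle suites use 500 randomized
one-mismatch cases, 1000 random six-frame sequences, 50×50 random
interval sets and 50 FDR simulations of 900 PSMs; coding-potential
training uses 500+500 sequences with a 150+150 held-out set. Every
random draw flows from a single seed (NumPy default_rng); the pipeline
itself is seedless and byte-deterministic given its inputs, and re-runs
with `resume` restore checkpointed stages only when the recorded
configuration/input checksum matches.

## Known limitations

Assembly and alignment are out of scope (the merge step only deduplicates
intron chains); multi-engine score combination and rescoring are upstream
concerns (one score column in, one out); the modification screen is a
mass-arithmetic stand-in, not spectral re-scoring; locus classification
by gene span is a choice, not the only defensible one (exon-level is
provided); mzIdentML and binary browser formats are not written.
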