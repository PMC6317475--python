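"""Seeded miniature proteogenomics study for end-to-end testing.

The generator builds a small genome with annotated multi-exon genes
(GT..AG introns, complete ATG..stop ORFs), an official proteome derived by
translation, an assembled transcriptome containing planted novel events,
a junction BED, and a PSM table with planted truths:

* exact copies of official transcripts (to be classified known),
* exon-skipping transcripts and intergenic transcript chains (novel NTs),
* single-base-substituted intergenic copies of official genes, whose
  peptides mimic single-amino-acid variants of known peptides,
* shifted and intergenic novel junctions (NJs),
* multi-spectrum genuinely novel peptides (must survive the cascade),
* single-spectrum novel peptides (to be dropped by the spectral filter),
* one-mismatch mutants and non-tryptic substrings of known peptides
  (to be caught by the homology filters),
* mass-shifted peptides explainable as modified known peptides, and
  externally excluded peptides (caught by the modification screen),
* decoy PSMs drawn from a null score distribution.

Every byte of output is a deterministic function of the seed.  Planted
"surviving" peptides are checked at construction time against the same
filter arithmetic the pipeline applies, so each planted item has exactly
one expected fate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation_events import (
    AnnotationSet,
    Junction,
    TranscriptModel,
    build_novel_event_set,
    classify_junctions,
    classify_transcripts,
    merge_assembled,
)
from .io_formats import GenomeSequence
from .novelty_filters import (
    DEFAULT_MODS,
    KnownPeptideMassIndex,
    one_mismatch_filter,
    substring_filter,
)
from .orf_database import (
    _CODON_TO_AA,
    DbEntry,
    build_search_database,
    translate_frame,
)
from .proteolysis import peptide_mono_mass, tryptic_digest
from .psm_processing import PsmRecord

_NONSTOP_CODONS = sorted(c for c, a in _CODON_TO_AA.items() if a != "*")
_AA_TO_CODON: dict[str, str] = {}
for _c in _NONSTOP_CODONS:
    _AA_TO_CODON.setdefault(_CODON_TO_AA[_c], _c)
_STOP_CODONS = sorted(c for c, a in _CODON_TO_AA.items() if a == "*")
_BASES = np.array(list("ACGT"))


@dataclass
class FixtureConfig:
    """Study conditions of the miniature fixture (all counts per study)."""

    seed: int = 17
    n_chroms: int = 2
    chrom_len: int = 100_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 5)
    protein_len: tuple[int, int] = (80, 180)
    intron_len: tuple[int, int] = (60, 200)
    # planted novel events
    n_exon_skip_nt: int = 6
    n_intergenic_gene_nt: int = 8
    n_mutated_copy_nt: int = 4
    n_intragenic_nj: int = 4
    n_intergenic_nj: int = 4
    # planted PSM truths
    n_known_peptides: int = 60
    n_true_novel_multi: int = 12
    n_true_novel_single: int = 5
    n_mutated_known: int = 4
    n_substring_planted: int = 2
    n_mod_explained: int = 3
    n_exclusion_list: int = 2
    n_decoys: int = 150
    n_datasets: int = 3
    # score model: two normals, target mean 3 SD above the decoy null;
    # planted truths sit in the confident upper tail
    target_score_mean: float = 8.0
    decoy_score_mean: float = 5.0
    score_sd: float = 1.0
    planted_score_mean: float = 12.0
    planted_score_sd: float = 0.5
    peptide_len_range: tuple[int, int] = (7, 25)
    mass_tol: float = 0.02

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name.startswith("n_") and value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthRecord:
    item_id: str
    kind: str
    value: str  # event id, transcript id or peptide sequence
    expected_fate: str


@dataclass
class GeneInfo:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    mrna: str  # ATG..stop, spliced, sense strand
    protein: str


@dataclass
class PseudogeneInfo:
    gene: GeneInfo
    chrom: str
    start: int
    end: int
    mutated_mrna: str
    mutated_protein: str
    mutated_pos: int  # protein index of the substitution


@dataclass
class FixtureLayout:
    genes: list[GeneInfo] = field(default_factory=list)
    pseudogenes: list[PseudogeneInfo] = field(default_factory=list)
    official_proteome: list[tuple[str, str]] = field(default_factory=list)
    contaminants: list[tuple[str, str]] = field(default_factory=list)
    free_regions: dict[str, tuple[int, int]] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_mrna(rng: np.random.Generator, n_aa: int) -> str:
    codons = [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n_aa - 1)]
    stop = _STOP_CODONS[rng.integers(0, len(_STOP_CODONS))]
    return "ATG" + "".join(codons) + stop


def _split_exons(rng: np.random.Generator, length: int, n_exons: int) -> list[int]:
    """Cut points splitting [0, length) into n_exons pieces of >= 10 nt."""
    if n_exons == 1:
        return []
    for _ in range(200):
        cuts = np.sort(rng.integers(10, length - 9, n_exons - 1))
        pieces = np.diff(np.concatenate([[0], cuts, [length]]))
        if (pieces >= 10).all() and len(set(cuts)) == n_exons - 1:
            return [int(c) for c in cuts]
    raise ValueError(f"cannot split {length} nt into {n_exons} exons")


def make_genome_and_annotation(
    cfg: FixtureConfig,
) -> tuple[GenomeSequence, AnnotationSet, FixtureLayout]:
    """Random genome with planted official genes, plus unannotated mutated
    gene copies in intergenic space; official proteome by translation."""
    rng = np.random.default_rng(cfg.seed)
    layout = FixtureLayout()
    chrom_parts: dict[str, list[str]] = {}
    cursors: dict[str, int] = {}
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    for name in chrom_names:
        chrom_parts[name] = []
        cursors[name] = 0

    def _append(chrom: str, seq: str) -> int:
        start = cursors[chrom]
        chrom_parts[chrom].append(seq)
        cursors[chrom] += len(seq)
        return start

    # official genes, round-robin across chromosomes
    for k in range(cfg.n_genes):
        chrom = chrom_names[k % cfg.n_chroms]
        _append(chrom, _random_dna(rng, int(rng.integers(300, 800))))
        n_aa = int(rng.integers(*cfg.protein_len))
        mrna = _random_mrna(rng, n_aa)
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        cuts = _split_exons(rng, len(mrna), n_exons)
        bounds = [0] + cuts + [len(mrna)]
        pieces = [mrna[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [
            "GT" + _random_dna(rng, int(rng.integers(*cfg.intron_len)) - 4) + "AG"
            for _ in range(n_exons - 1)
        ]
        region = pieces[0]
        local_exons = [(0, len(pieces[0]))]
        for piece, intron in zip(pieces[1:], introns):
            region += intron
            s = len(region)
            region += piece
            local_exons.append((s, s + len(piece)))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from ._util import revcomp

            offset = _append(chrom, revcomp(region))
            L = len(region)
            exons = [(offset + L - b, offset + L - a) for a, b in local_exons]
            exons.sort()
        else:
            offset = _append(chrom, region)
            exons = [(offset + a, offset + b) for a, b in local_exons]
        gid, tid = f"OSG{k:03d}", f"OSG{k:03d}.1"
        protein = translate_frame(mrna, 0).rstrip("*")
        layout.genes.append(GeneInfo(gid, tid, chrom, strand, exons, mrna, protein))
        layout.official_proteome.append((tid, protein))
        if cursors[chrom] > cfg.chrom_len - 2000:
            raise ValueError("genes do not fit within chrom_len")

    # unannotated mutated copies of the longest-protein genes ("+" strand)
    donors = sorted(layout.genes, key=lambda g: -len(g.protein))[: cfg.n_mutated_copy_nt]
    for gene in donors:
        chrom = gene.chrom
        _append(chrom, _random_dna(rng, int(rng.integers(400, 800))))
        prot = gene.protein
        for _ in range(200):
            i = int(rng.integers(1, len(prot)))
            if prot[i] in "KRP":
                continue
            choices = [a for a in "ACDEFGHILMNQSTVWY" if a != prot[i]]
            new_aa = choices[int(rng.integers(0, len(choices)))]
            mut_prot = prot[:i] + new_aa + prot[i + 1 :]
            mut_mrna = (
                gene.mrna[: 3 * i] + _AA_TO_CODON[new_aa] + gene.mrna[3 * i + 3 :]
            )
            break
        else:  # pragma: no cover - substitution always found
            raise ValueError("no mutable residue found")
        start = _append(chrom, mut_mrna)
        layout.pseudogenes.append(
            PseudogeneInfo(gene, chrom, start, start + len(mut_mrna), mut_mrna, mut_prot, i)
        )
        if cursors[chrom] > cfg.chrom_len - 2000:
            raise ValueError("genes do not fit within chrom_len")

    # pad chromosomes; everything past the cursor is free intergenic space
    for name in chrom_names:
        free_start = cursors[name] + 500
        pad = cfg.chrom_len - cursors[name]
        if pad < 3000:
            raise ValueError("genes do not fit within chrom_len")
        _append(name, _random_dna(rng, pad))
        layout.free_regions[name] = (free_start, cfg.chrom_len)

    layout.contaminants = [
        (f"CONT{i:02d}", translate_frame(_random_mrna(rng, 150), 0).rstrip("*"))
        for i in range(3)
    ]

    genome = GenomeSequence({n: "".join(chrom_parts[n]) for n in chrom_names})
    transcripts = [
        TranscriptModel(g.transcript_id, g.chrom, g.strand, list(g.exons), g.gene_id)
        for g in layout.genes
    ]
    annotation = AnnotationSet(
        transcripts=transcripts, coding={t.id: True for t in transcripts}
    )
    return genome, annotation, layout


def make_assembled_with_novelty(
    cfg: FixtureConfig, annotation: AnnotationSet, layout: FixtureLayout
) -> tuple[list[TranscriptModel], list[Junction], list[TruthRecord]]:
    """Assembled transcripts (known copies + planted novelty) and junctions."""
    rng = np.random.default_rng(cfg.seed + 1)
    assembled: list[TranscriptModel] = []
    truths: list[TruthRecord] = []

    # exact / end-jittered copies of every official transcript -> known
    for t in annotation.transcripts:
        exons = [list(e) for e in t.exons]
        if rng.random() < 0.4:  # end jitter does not change the intron chain
            exons[0][0] = max(0, exons[0][0] - int(rng.integers(1, 30)))
            exons[-1][1] = exons[-1][1] + int(rng.integers(1, 30))
        assembled.append(
            TranscriptModel(f"asm_{t.id}", t.chrom, t.strand, [tuple(e) for e in exons])
        )

    # exon-skipping novel transcripts on distinct multi-exon genes
    skip_candidates = [t for t in annotation.transcripts if len(t.exons) >= 3]
    if len(skip_candidates) < cfg.n_exon_skip_nt:
        raise ValueError("not enough multi-exon genes for exon-skip events")
    skip_used: set[str] = set()
    for t in skip_candidates[: cfg.n_exon_skip_nt]:
        skip_used.add(t.id)
        drop = int(rng.integers(1, len(t.exons) - 1))
        exons = [e for i, e in enumerate(t.exons) if i != drop]
        tid = f"asm_skip_{t.id}"
        assembled.append(TranscriptModel(tid, t.chrom, t.strand, exons))
        truths.append(
            TruthRecord(tid, "NT_exon_skip", tid, "classified_novel_transcript")
        )

    # mono-exonic transcripts over the mutated gene copies -> novel NTs
    for pg in layout.pseudogenes[: cfg.n_mutated_copy_nt]:
        tid = f"asm_copy_{pg.gene.transcript_id}"
        assembled.append(
            TranscriptModel(tid, pg.chrom, "+", [(pg.start, pg.end)])
        )
        truths.append(
            TruthRecord(tid, "NT_mutated_copy", tid, "classified_novel_transcript")
        )

    # intergenic transcript chains over random DNA, alternating strand
    free_cursor = {c: s for c, (s, _) in layout.free_regions.items()}
    chroms = sorted(layout.free_regions)

    def _alloc(length: int) -> tuple[str, int]:
        for c in chroms:
            if free_cursor[c] + length + 400 <= layout.free_regions[c][1]:
                start = free_cursor[c]
                free_cursor[c] += length + 400
                return c, start
        raise ValueError("free intergenic space exhausted")

    for k in range(cfg.n_intergenic_gene_nt):
        n_ex = int(rng.integers(2, 4))
        exon_lens = rng.integers(150, 350, n_ex)
        intron_lens = rng.integers(*cfg.intron_len, n_ex - 1)
        total = int(exon_lens.sum() + intron_lens.sum())
        chrom, start = _alloc(total)
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        strand = "+" if k % 2 == 0 else "-"
        tid = f"asm_novelgene_{k:02d}"
        assembled.append(TranscriptModel(tid, chrom, strand, exons))
        truths.append(
            TruthRecord(tid, "NT_intergenic_gene", tid, "classified_novel_transcript")
        )

    # junctions: every official intron (twice, to exercise dedup) ...
    junctions: list[Junction] = []
    for t in annotation.transcripts:
        for s, e in t.intron_chain:
            strand = t.strand if rng.random() < 0.8 else "."
            junctions.append(Junction(t.chrom, s, e, strand))
            junctions.append(Junction(t.chrom, s, e, strand))

    # ... plus shifted (intragenic) and intergenic novel junctions
    nj_candidates = [
        t
        for t in annotation.transcripts
        if t.intron_chain and t.id not in skip_used
    ]
    if len(nj_candidates) < cfg.n_intragenic_nj:
        raise ValueError("not enough genes for intragenic novel junctions")
    for t in nj_candidates[: cfg.n_intragenic_nj]:
        s, e = t.intron_chain[0]
        j = Junction(t.chrom, s + 5, e + 5, t.strand, name=f"nj_shift_{t.id}")
        junctions.append(j)
        truths.append(
            TruthRecord(j.name, "NJ_intragenic", f"{j.chrom}:{j.start}-{j.end}",
                        "classified_novel_junction")
        )
    for k in range(cfg.n_intergenic_nj):
        ilen = int(rng.integers(70, 150))
        chrom, start = _alloc(ilen + 200)
        j = Junction(chrom, start + 100, start + 100 + ilen, "+", name=f"nj_inter_{k:02d}")
        junctions.append(j)
        truths.append(
            TruthRecord(j.name, "NJ_intergenic", f"{j.chrom}:{j.start}-{j.end}",
                        "classified_novel_junction")
        )
    # one duplicated novel junction (must still yield a single event)
    if cfg.n_intergenic_nj:
        junctions.append(replace(junctions[-1]))
    return assembled, junctions, truths


def build_fixture_database(
    genome: GenomeSequence,
    annotation: AnnotationSet,
    layout: FixtureLayout,
    assembled: list[TranscriptModel],
    junctions: list[Junction],
) -> list[DbEntry]:
    """The customized search database exactly as the pipeline would build it."""
    merged = merge_assembled([assembled])
    _, novel_t = classify_transcripts(merged, annotation)
    _, novel_j = classify_junctions(junctions, annotation)
    events = build_novel_event_set(novel_t, novel_j)
    return build_search_database(
        events, genome, layout.official_proteome, layout.contaminants
    )


def _spans_junction(entry: DbEntry, peptide: str) -> bool:
    prov = entry.provenance[0]
    if len(prov.blocks) < 2:
        return False
    boundary = prov.blocks[0][1] - prov.blocks[0][0]
    if prov.event_strand == "-":
        boundary = prov.dna_len - boundary
    off = entry.sequence.find(peptide)
    a, b = prov.product.nt_interval(off, len(peptide))
    return a < boundary < b


def make_psm_table(
    cfg: FixtureConfig,
    db_entries: list[DbEntry],
    layout: FixtureLayout,
) -> tuple[list[PsmRecord], list[TruthRecord], list[str]]:
    """PSM rows with planted truths.

    Returns (psms, truth records, external exclusion list).  Peptides
    planted to survive the cascade are verified at construction time not to
    be caught by the substring, one-mismatch or precursor-mass screens.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    proteome = [e for e in db_entries if e.category in ("official", "contaminant")]
    novel_entries = [e for e in db_entries if e.category == "novel"]
    mass_index = KnownPeptideMassIndex(proteome)
    lo, hi = cfg.peptide_len_range

    def survives_filters(pep: str) -> bool:
        if substring_filter(pep, proteome):
            return False
        if one_mismatch_filter(pep, proteome)[0]:
            return False
        mass = peptide_mono_mass(pep)
        deltas = [0.0] + [d for _, d in DEFAULT_MODS]
        return not any(mass_index.any_within(mass - d, cfg.mass_tol) for d in deltas)

    def entries_containing(pep: str, pool: list[DbEntry]) -> tuple[str, ...]:
        return tuple(e.accession for e in pool if pep in e.sequence)

    used: set[str] = set()
    psms: list[PsmRecord] = []
    truths: list[TruthRecord] = []
    counter = [0]

    def add_psm(pep: str, score: float, is_decoy: bool, db: tuple[str, ...],
                mass: float | None = None) -> None:
        i = counter[0]
        counter[0] += 1
        psms.append(
            PsmRecord(
                spectrum_id=f"sp{i:06d}",
                dataset_id=f"DS{i % cfg.n_datasets + 1}",
                peptide=pep,
                charge=int(rng.integers(2, 4)),
                precursor_mass=peptide_mono_mass(pep) if mass is None else mass,
                score=round(float(score), 6),
                is_decoy=is_decoy,
                db_entries=db,
            )
        )

    def target_score() -> float:
        return rng.normal(cfg.target_score_mean, cfg.score_sd)

    def planted_score() -> float:
        return rng.normal(cfg.planted_score_mean, cfg.planted_score_sd)

    # known peptides from the official proteome
    known_pool = sorted(
        {
            p
            for _, seq in layout.official_proteome
            for p in tryptic_digest(seq, 0, min_len=lo, max_len=hi)
        }
    )
    if len(known_pool) < cfg.n_known_peptides:
        raise ValueError("not enough tryptic peptides in the official proteome")
    idx = rng.choice(len(known_pool), cfg.n_known_peptides, replace=False)
    for i in sorted(idx):
        pep = known_pool[i]
        used.add(pep)
        for _ in range(int(rng.integers(1, 4))):
            add_psm(pep, target_score(), False, entries_containing(pep, proteome))

    # genuinely novel peptides; the construction-time filter check keeps
    # only peptides the cascade cannot explain away (peptides from entries
    # overlapping official sequence fail it and are skipped naturally)
    def novel_candidates(want_junction: bool) -> list[str]:
        out = []
        for e in novel_entries:
            for pep in tryptic_digest(e.sequence, 0, min_len=lo, max_len=hi):
                if want_junction and not _spans_junction(e, pep):
                    continue
                out.append(pep)
        return out

    def pick_novel(n: int, prefer_junction: bool = False) -> list[str]:
        picked: list[str] = []
        pools = []
        if prefer_junction:
            pools.append(novel_candidates(want_junction=True))
        pools.append(novel_candidates(want_junction=False))
        for pool in pools:
            for j in rng.permutation(len(pool)):
                if len(picked) == n:
                    break
                pep = pool[j]
                if pep in used or not survives_filters(pep):
                    continue
                picked.append(pep)
                used.add(pep)
            if len(picked) == n:
                break
        if len(picked) < n:
            raise ValueError(
                "requested novel peptides exceed available tryptic peptides"
            )
        return picked

    for pep in pick_novel(cfg.n_true_novel_multi, prefer_junction=True):
        for _ in range(int(rng.integers(2, 5))):
            add_psm(pep, planted_score(), False, entries_containing(pep, novel_entries))
        truths.append(TruthRecord(pep, "peptide_true_novel_multi", pep, "FNP"))

    for pep in pick_novel(cfg.n_true_novel_single):
        add_psm(pep, planted_score(), False, entries_containing(pep, novel_entries))
        truths.append(
            TruthRecord(pep, "peptide_true_novel_single", pep, "removed_by_low_spectra")
        )

    # one-mismatch mutants of known peptides, via the mutated gene copies;
    # missed-cleavage forms widen the candidate pool
    n_mut = 0
    for pg in layout.pseudogenes:
        if n_mut == cfg.n_mutated_known:
            break
        orig = tryptic_digest(pg.gene.protein, 1)
        mut = tryptic_digest(pg.mutated_protein, 1)
        for po, pm in zip(orig, mut):
            if n_mut == cfg.n_mutated_known:
                break
            if po == pm or not 6 <= len(pm) <= 30 or pm in used:
                continue
            if substring_filter(pm, proteome):
                continue
            db = entries_containing(pm, novel_entries)
            if not db:
                continue
            used.add(pm)
            for _ in range(2):
                add_psm(pm, planted_score(), False, db)
            truths.append(
                TruthRecord(pm, "peptide_mutated_known", pm, "removed_by_one_mismatch")
            )
            n_mut += 1
    if n_mut < cfg.n_mutated_known:
        raise ValueError("could not plant the requested mutated-known peptides")

    # non-tryptic exact substrings of known proteins, present in a copy entry
    n_sub = 0
    for pg in layout.pseudogenes:
        if n_sub == cfg.n_substring_planted:
            break
        prot = pg.gene.protein
        for start in range(2, len(prot) - 12):
            if start <= pg.mutated_pos < start + 12:
                continue
            pep = prot[start : start + 12]
            if prot[start - 1] in "KR" or pep in used:
                continue  # want a non-tryptic N terminus
            db = entries_containing(pep, novel_entries)
            if not db:
                continue
            used.add(pep)
            for _ in range(2):
                add_psm(pep, planted_score(), False, db)
            truths.append(
                TruthRecord(pep, "peptide_known_substring", pep, "removed_by_substring")
            )
            n_sub += 1
            break
    if n_sub < cfg.n_substring_planted:
        raise ValueError("could not plant the requested substring peptides")

    # novel peptides whose precursor matches a known peptide + modification
    mod_deltas = [d for _, d in DEFAULT_MODS]
    for k, pep in enumerate(pick_novel(cfg.n_mod_explained)):
        known_pep = known_pool[int(rng.integers(0, len(known_pool)))]
        delta = mod_deltas[k % len(mod_deltas)]
        shifted = peptide_mono_mass(known_pep) + delta
        for _ in range(2):
            add_psm(pep, planted_score(), False,
                    entries_containing(pep, novel_entries), mass=shifted)
        truths.append(
            TruthRecord(pep, "peptide_mod_explained", pep, "removed_by_ptm_explained")
        )

    # peptides excluded by the external list (clean masses, 2 spectra)
    exclusion: list[str] = []
    for pep in pick_novel(cfg.n_exclusion_list):
        for _ in range(2):
            add_psm(pep, planted_score(), False, entries_containing(pep, novel_entries))
        exclusion.append(pep)
        truths.append(
            TruthRecord(pep, "peptide_exclusion_list", pep, "removed_by_ptm_explained")
        )

    # decoy PSMs from the null score distribution (exact count)
    for _ in range(cfg.n_decoys):
        pep = known_pool[int(rng.integers(0, len(known_pool)))][::-1]
        add_psm(pep, rng.normal(cfg.decoy_score_mean, cfg.score_sd), True,
                (f"XXX_{layout.official_proteome[0][0]}",))

    return psms, truths, exclusion


def make_cp_training_sequences(
    n_coding: int,
    n_noncoding: int,
    seed: int,
    coding_aa_range: tuple[int, int] = (150, 350),
    noncoding_len_range: tuple[int, int] = (450, 1100),
) -> tuple[list[str], list[str]]:
    """Labeled transcript corpora for coding-potential training.

    Coding transcripts carry a long ORF with a skewed codon usage (one fixed
    codon per amino acid) between short random UTRs; noncoding transcripts
    are uniform random nucleotides, so they have short incidental ORFs and
    unbiased hexamer usage.
    """
    rng = np.random.default_rng(seed)
    aa_alphabet = sorted(_AA_TO_CODON)
    coding: list[str] = []
    for _ in range(n_coding):
        n_aa = int(rng.integers(*coding_aa_range))
        aas = [aa_alphabet[i] for i in rng.integers(0, len(aa_alphabet), n_aa)]
        orf = "ATG" + "".join(_AA_TO_CODON[a] for a in aas) + "TAA"
        utr5 = _random_dna(rng, int(rng.integers(20, 120)))
        utr3 = _random_dna(rng, int(rng.integers(20, 120)))
        coding.append(utr5 + orf + utr3)
    noncoding = [
        _random_dna(rng, int(rng.integers(*noncoding_len_range)))
        for _ in range(n_noncoding)
    ]
    return coding, noncoding


@dataclass
class FixtureBundle:
    cfg: FixtureConfig
    genome: GenomeSequence
    annotation: AnnotationSet
    layout: FixtureLayout
    assembled: list[TranscriptModel]
    junctions: list[Junction]
    db_entries: list[DbEntry]
    psms: list[PsmRecord]
    truths: list[TruthRecord]
    exclusion_list: list[str]


def build_fixture(cfg: FixtureConfig | None = None) -> FixtureBundle:
    """Generate the full miniature study in memory."""
    cfg = cfg or FixtureConfig()
    genome, annotation, layout = make_genome_and_annotation(cfg)
    assembled, junctions, ev_truths = make_assembled_with_novelty(cfg, annotation, layout)
    db = build_fixture_database(genome, annotation, layout, assembled, junctions)
    psms, psm_truths, exclusion = make_psm_table(cfg, db, layout)
    return FixtureBundle(
        cfg=cfg,
        genome=genome,
        annotation=annotation,
        layout=layout,
        assembled=assembled,
        junctions=junctions,
        db_entries=db,
        psms=psms,
        truths=ev_truths + psm_truths,
        exclusion_list=exclusion,
    )


def write_fixture(bundle: FixtureBundle, outdir) -> dict[str, str]:
    """Write the bundle in the formats the pipeline reads; returns paths."""
    import os

    from .io_formats import (
        write_fasta_entries,
        write_gtf,
        write_junction_bed,
        write_psm_table,
    )

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "reference_gtf": os.path.join(outdir, "reference.gtf"),
        "assembled_gtf": os.path.join(outdir, "assembled.gtf"),
        "junction_bed": os.path.join(outdir, "junctions.bed"),
        "proteome": os.path.join(outdir, "proteome.fa"),
        "contaminants": os.path.join(outdir, "contaminants.fa"),
        "psm_table": os.path.join(outdir, "psms.tsv"),
        "exclusion": os.path.join(outdir, "exclusion.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "cp_coding": os.path.join(outdir, "cp_coding.fa"),
        "cp_noncoding": os.path.join(outdir, "cp_noncoding.fa"),
    }
    bundle.genome.to_fasta(paths["genome"])
    write_gtf(bundle.annotation.transcripts, paths["reference_gtf"])
    write_gtf(bundle.assembled, paths["assembled_gtf"])
    write_junction_bed(bundle.junctions, paths["junction_bed"])
    write_fasta_entries(bundle.layout.official_proteome, paths["proteome"])
    write_fasta_entries(bundle.layout.contaminants, paths["contaminants"])
    write_psm_table(bundle.psms, paths["psm_table"])
    with open(paths["exclusion"], "w") as fh:
        fh.write("peptide\n")
        for pep in bundle.exclusion_list:
            fh.write(pep + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("item_id\tkind\tvalue\texpected_fate\n")
        for t in bundle.truths:
            fh.write(f"{t.item_id}\t{t.kind}\t{t.value}\t{t.expected_fate}\n")
    coding, noncoding = make_cp_training_sequences(120, 120, bundle.cfg.seed + 3)
    write_fasta_entries(
        [(f"cod{i}", s) for i, s in enumerate(coding)], paths["cp_coding"]
    )
    write_fasta_entries(
        [(f"nc{i}", s) for i, s in enumerate(noncoding)], paths["cp_noncoding"]
    )
    return paths
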