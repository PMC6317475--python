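"""Splice-aware placement of peptides onto genomic coordinates.

A peptide identified against a novel database entry is located on the genome
through the entry's provenance: protein offset -> nucleotide offset within
the translated fragment (frame-aware, including reverse frames) -> genomic
blocks through the event's exon/flank block map, splitting at junctions.
A codon crossing a block boundary contributes its nucleotides to both
blocks, so proBed blocks are nucleotide-exact rather than codon-aligned.

Peptides placed identically by several entries still count as uniquely
mapping; placement on more than one distinct locus makes them multi-mapping.
Locus classification uses official *gene spans* and ignores strand, so
intronic and antisense placements count as intragenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .annotation_events import AnnotationSet
from .io_formats import ProBedRecord
from .orf_database import DbEntry

Interval = tuple[int, int]


@dataclass
class GenomicPeptide:
    peptide: str
    chrom: str
    strand: str
    blocks: list[Interval]
    locus_class: str | None = None  # intergenic | intragenic
    mapping_class: str | None = None  # unique | multi
    source_events: tuple[str, ...] = ()
    source_entries: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.blocks = sorted(tuple(b) for b in self.blocks)
        total = sum(e - s for s, e in self.blocks)
        if total != 3 * len(self.peptide):
            raise ValueError(
                f"peptide {self.peptide}: block lengths sum to {total}, "
                f"expected {3 * len(self.peptide)}"
            )
        for (s1, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"peptide {self.peptide}: overlapping blocks")

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    def placement_key(self) -> tuple:
        return (self.chrom, self.strand, tuple(self.blocks))


def _tx_interval_to_genomic(
    blocks: tuple[Interval, ...], strand: str, a: int, b: int
) -> list[Interval]:
    """Map an event-sense dna interval [a,b) to sorted merged genomic blocks."""
    tx_blocks = list(reversed(blocks)) if strand == "-" else list(blocks)
    out: list[Interval] = []
    cum = 0
    for gs, ge in tx_blocks:
        length = ge - gs
        lo, hi = max(a, cum), min(b, cum + length)
        if lo < hi:
            if strand == "-":
                out.append((ge - (hi - cum), ge - (lo - cum)))
            else:
                out.append((gs + (lo - cum), gs + (hi - cum)))
        cum += length
    out.sort()
    merged: list[Interval] = []
    for s, e in out:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _peptide_strand(event_strand: str, frame: str) -> str:
    ev_minus = event_strand == "-"
    fr_minus = frame.startswith("-")
    return "+" if ev_minus == fr_minus else "-"


def locate_peptide(peptide: str, entry: DbEntry) -> list[GenomicPeptide]:
    """All genomic placements of ``peptide`` within one novel entry.

    One placement per provenance record per occurrence of the peptide in the
    entry sequence.  Raises if the peptide is not a substring or if the
    block map cannot accommodate it (clipped fragment).
    """
    if entry.category != "novel":
        raise ValueError(f"entry {entry.accession} is not a novel entry")
    offsets = []
    start = entry.sequence.find(peptide)
    while start != -1:
        offsets.append(start)
        start = entry.sequence.find(peptide, start + 1)
    if not offsets:
        raise ValueError(f"peptide {peptide} not found in entry {entry.accession}")

    placements: list[GenomicPeptide] = []
    for prov in entry.provenance:
        product = prov.product  # frame/offset carrier
        for off in offsets:
            a, b = product.nt_interval(off, len(peptide))
            if a < 0 or b > prov.dna_len:
                raise ValueError(
                    f"peptide {peptide} spans a clipped region of {prov.event_id}"
                )
            blocks = _tx_interval_to_genomic(prov.blocks, prov.event_strand, a, b)
            placements.append(
                GenomicPeptide(
                    peptide=peptide,
                    chrom=prov.chrom,
                    strand=_peptide_strand(prov.event_strand, prov.frame),
                    blocks=blocks,
                    source_events=(prov.event_id,),
                    source_entries=(entry.accession,),
                )
            )
    return placements


def all_placements(
    peptide: str, entries: list[DbEntry]
) -> list[GenomicPeptide]:
    """Placements of a peptide across every novel entry containing it,
    deduplicated by placement; source events/entries are unioned."""
    by_key: dict[tuple, GenomicPeptide] = {}
    for entry in entries:
        if entry.category != "novel" or peptide not in entry.sequence:
            continue
        for gp in locate_peptide(peptide, entry):
            prev = by_key.get(gp.placement_key())
            if prev is None:
                by_key[gp.placement_key()] = gp
            else:
                prev.source_events = tuple(
                    sorted(set(prev.source_events) | set(gp.source_events))
                )
                prev.source_entries = tuple(
                    sorted(set(prev.source_entries) | set(gp.source_entries))
                )
    return list(by_key.values())


def classify_mapping(placements: list[GenomicPeptide]) -> str:
    """unique iff all placements collapse to one (chrom, strand, blocks)."""
    keys = {gp.placement_key() for gp in placements}
    cls = "unique" if len(keys) == 1 else "multi"
    for gp in placements:
        gp.mapping_class = cls
    return cls


class GeneSpanIndex:
    """Interval index over official gene spans (or exon bodies)."""

    def __init__(self, official: AnnotationSet, exon_level: bool = False):
        self.trees: dict[str, IntervalTree] = {}
        if exon_level:
            for t in official.transcripts:
                tree = self.trees.setdefault(t.chrom, IntervalTree())
                for s, e in t.exons:
                    tree.addi(s, e)
        else:
            for chrom, s, e in official.gene_spans().values():
                self.trees.setdefault(chrom, IntervalTree()).addi(s, e)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False


def classify_locus(
    gp: GenomicPeptide, official: AnnotationSet | GeneSpanIndex
) -> str:
    """intragenic iff the peptide span overlaps any official gene span on
    either strand (introns and antisense placements included)."""
    index = official if isinstance(official, GeneSpanIndex) else GeneSpanIndex(official)
    s, e = gp.span
    gp.locus_class = "intragenic" if index.overlaps(gp.chrom, s, e) else "intergenic"
    return gp.locus_class


def to_probed(
    gp: GenomicPeptide,
    name: str | None = None,
    psm_score: float | None = None,
    fdr_class: str = "pass",
    modifications: str = ".",
) -> ProBedRecord:
    return ProBedRecord(
        chrom=gp.chrom,
        strand=gp.strand,
        blocks=list(gp.blocks),
        name=name or gp.peptide,
        peptide=gp.peptide,
        uniqueness=gp.mapping_class or "unique",
        psm_score=psm_score,
        fdr=fdr_class,
        modifications=modifications,
    )
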