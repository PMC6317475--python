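"""Customized protein search database from novel events.

Each novel event (NT or NJ) is turned into a spliced nucleotide fragment —
the exon chain for an NT, flanking sequence on both sides of the intron for
an NJ — translated in all six reading frames, and the single longest
stop-free product of at least five residues becomes a database entry.  The
novel entries are pooled with the official proteome and a contaminant list
to form the search database; reversed decoys can be appended.

Products are maximal stop-free stretches, not ATG-initiated ORFs: peptide
evidence does not require an initiator codon inside the fragment.

Every novel entry carries provenance (event blocks, strand, frame, codon
offset) sufficient to map any of its substrings back to genomic blocks; the
inverse mapping lives in :mod:`splicepept.peptide_genome_map`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from ._util import revcomp
from .annotation_events import NovelEvent

FRAME_ORDER = ["+0", "+1", "+2", "-0", "-1", "-2"]

_STD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STD.forward_table)
for _stop in _STD.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def translate_frame(dna: str, frame: int) -> str:
    """Translate one forward frame; any codon not fully A/C/G/T becomes X."""
    dna = dna.upper()
    out = []
    for i in range(frame, len(dna) - 2, 3):
        out.append(_CODON_TO_AA.get(dna[i : i + 3], "X"))
    return "".join(out)


@dataclass(frozen=True)
class Product:
    """One stop-free translation product of a six-frame translation."""

    seq: str
    frame: str  # one of FRAME_ORDER
    codon_start: int  # codon index within the frame
    dna_len: int

    @property
    def frame_offset(self) -> int:
        return int(self.frame[1])

    @property
    def nt_offset(self) -> int:
        """Start of the product in frame-local nucleotide coordinates."""
        return self.frame_offset + 3 * self.codon_start

    def nt_interval(self, aa_start: int = 0, aa_len: int | None = None) -> tuple[int, int]:
        """Nucleotide interval in *event-sense* dna coordinates for a
        residue range of the product (default: the whole product)."""
        if aa_len is None:
            aa_len = len(self.seq) - aa_start
        s = self.nt_offset + 3 * aa_start
        if self.frame[0] == "+":
            return (s, s + 3 * aa_len)
        return (self.dna_len - s - 3 * aa_len, self.dna_len - s)


def six_frame_products(dna: str) -> list[Product]:
    """All maximal stop-free products in the six reading frames."""
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    products: list[Product] = []
    for sense, seq in (("+", dna), ("-", revcomp(dna))):
        for f in range(3):
            aa = translate_frame(seq, f)
            start = 0
            for chunk in aa.split("*"):
                if chunk:
                    products.append(
                        Product(chunk, f"{sense}{f}", start, len(dna))
                    )
                start += len(chunk) + 1
    return products


def select_db_product(products: list[Product], min_aa: int = 5) -> Product | None:
    """The single longest product of length >= ``min_aa``; ties broken by
    frame order (+0,+1,+2,-0,-1,-2) then smallest in-frame offset."""
    candidates = [p for p in products if len(p.seq) >= min_aa]
    if not candidates:
        return None
    candidates.sort(key=lambda p: (-len(p.seq), FRAME_ORDER.index(p.frame), p.nt_offset))
    return candidates[0]


@dataclass
class EventSequence:
    """Spliced event-sense DNA with the genomic block map that produced it."""

    event_id: str
    chrom: str
    strand: str  # genomic strand of the event ("." treated as "+")
    blocks: tuple[tuple[int, int], ...]  # genomic order, non-overlapping
    dna: str
    clipped: bool = False


def event_nucleotide_sequence(
    e: NovelEvent, genome, flank: int = 96
) -> EventSequence:
    """Spliced DNA of a novel event.

    NT: concatenation of exon sequences 5'->3' (reverse-complemented on the
    minus strand).  NJ: ``flank`` nt upstream of the intron joined to
    ``flank`` nt downstream.  Blocks extending beyond the chromosome are
    clipped with a warning.
    """
    if e.kind == "NT":
        blocks = [tuple(b) for b in (e.exons or [])]
    else:
        if flank <= 0:
            raise ValueError("NJ events require flank > 0")
        s, t = e.intron  # type: ignore[misc]
        blocks = [(s - flank, s), (t, t + flank)]
    clen = genome.chrom_length(e.chrom)
    clipped = False
    clipped_blocks: list[tuple[int, int]] = []
    for s, t in blocks:
        cs, ct = max(0, s), min(clen, t)
        if (cs, ct) != (s, t):
            clipped = True
        if ct > cs:
            clipped_blocks.append((cs, ct))
    if clipped:
        warnings.warn(f"event {e.id} extends beyond chromosome; clipped", stacklevel=2)
    fwd = "".join(genome.sequence(e.chrom, s, t) for s, t in clipped_blocks)
    dna = revcomp(fwd) if e.strand == "-" else fwd
    return EventSequence(
        event_id=e.id,
        chrom=e.chrom,
        strand=e.strand,
        blocks=tuple(clipped_blocks),
        dna=dna,
        clipped=clipped,
    )


@dataclass(frozen=True)
class Provenance:
    """Where a novel database entry came from, enough to rebuild coordinates."""

    event_id: str
    chrom: str
    event_strand: str
    blocks: tuple[tuple[int, int], ...]
    frame: str
    codon_start: int
    dna_len: int

    @property
    def product(self) -> Product:
        return Product("", self.frame, self.codon_start, self.dna_len)


@dataclass
class DbEntry:
    accession: str
    sequence: str
    category: str  # official | novel | contaminant | decoy
    provenance: list[Provenance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"entry {self.accession}: empty sequence")
        self.sequence = self.sequence.upper()
        if "*" in self.sequence:
            raise ValueError(f"entry {self.accession}: stop character in sequence")

    @property
    def header_description(self) -> str:
        parts = [f"cat={self.category}"]
        if self.provenance:
            parts.append(
                "ev=" + ",".join(f"{p.event_id}|{p.frame}" for p in self.provenance)
            )
        return " ".join(parts)


def build_search_database(
    events: list[NovelEvent],
    genome,
    official: list[tuple[str, str]],
    contaminants: list[tuple[str, str]],
    decoy: bool = False,
    flank: int = 96,
    min_product_aa: int = 5,
) -> list[DbEntry]:
    """Assemble the customized database: one product per novel event, plus
    the official proteome and contaminants; reversed decoys on request.

    Events yielding identical products collapse to one entry carrying all
    provenance records.  Duplicate accessions across inputs are an error.
    """
    novel_by_seq: dict[str, DbEntry] = {}
    for e in events:
        es = event_nucleotide_sequence(e, genome, flank=flank)
        if len(es.dna) < 3:
            continue
        prod = select_db_product(six_frame_products(es.dna), min_aa=min_product_aa)
        if prod is None:
            continue
        prov = Provenance(
            event_id=e.id,
            chrom=es.chrom,
            event_strand=es.strand,
            blocks=es.blocks,
            frame=prod.frame,
            codon_start=prod.codon_start,
            dna_len=len(es.dna),
        )
        entry = novel_by_seq.get(prod.seq)
        if entry is None:
            acc = f"NOV|{e.id}|{prod.frame}"
            novel_by_seq[prod.seq] = DbEntry(acc, prod.seq, "novel", [prov])
        else:
            entry.provenance.append(prov)

    entries = list(novel_by_seq.values())
    entries += [DbEntry(acc, seq, "official") for acc, seq in official]
    entries += [DbEntry(acc, seq, "contaminant") for acc, seq in contaminants]

    seen: set[str] = set()
    for entry in entries:
        if entry.accession in seen:
            raise ValueError(f"duplicate accession: {entry.accession}")
        seen.add(entry.accession)

    if decoy:
        entries += [
            DbEntry(f"XXX_{t.accession}", t.sequence[::-1], "decoy")
            for t in list(entries)
        ]
    return entries


def export_search_fasta(entries: list[DbEntry], path, min_len: int = 6) -> None:
    """Write the searchable FASTA, dropping entries shorter than ``min_len``
    residues (search-engine minimum, distinct from the 5-aa product rule)."""
    from .io_formats import write_fasta_entries

    write_fasta_entries([e for e in entries if len(e.sequence) >= min_len], path)
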