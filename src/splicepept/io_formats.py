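"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
Internally everything is 0-based half-open on the forward genomic strand.
Conversion to the 1-based inclusive GTF convention happens only here, at the
I/O boundary.  Junctions are represented as intron intervals (first intronic
base to last intronic base + 1), which is unambiguous across BED dialects.

The PSM table is a neutral TSV with a documented header (see
:func:`read_psm_table`); it stands in for search-engine output so the rest of
the pipeline needs only a ranked score column per PSM.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .annotation_events import AnnotationSet, Junction, TranscriptModel
from .psm_processing import PsmRecord


class GenomeSequence:
    """In-memory genome with 0-based half-open retrieval."""

    def __init__(self, chroms: dict[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self._chroms[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(s), id=name, description="") for name, s in self._chroms.items()]
        SeqIO.write(recs, str(path), "fasta")


class GtfParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> AnnotationSet:
    """Assemble transcripts from the exon lines of a GTF file.

    GTF 1-based inclusive coordinates are converted to internal 0-based
    half-open.  Transcripts carrying CDS features are flagged coding.
    Malformed lines raise :class:`GtfParseError` naming the line number.
    """
    exons: dict[str, dict] = {}
    coding: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                raise GtfParseError(f"line {lineno}: {feature} without transcript_id")
            if feature == "CDS":
                coding[tid] = True
                continue
            rec = exons.setdefault(
                tid, {"chrom": chrom, "strand": strand, "gene_id": attr.get("gene_id"), "exons": []}
            )
            rec["exons"].append((start - 1, end))
    transcripts = [
        TranscriptModel(tid, rec["chrom"], rec["strand"], rec["exons"], rec["gene_id"])
        for tid, rec in exons.items()
    ]
    flags = {t.id: coding.get(t.id, False) for t in transcripts}
    return AnnotationSet(transcripts=transcripts, coding=flags)


def write_gtf(transcripts: list[TranscriptModel], path, source: str = "splicepept") -> None:
    """Emit exon lines, 1-based inclusive."""
    with open(path, "w") as fh:
        for t in transcripts:
            gid = t.gene_id or t.id
            for s, e in t.exons:
                attrs = f'gene_id "{gid}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


@dataclass
class JunctionReadResult:
    junctions: list[Junction]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.junctions)

    def __len__(self):
        return len(self.junctions)


def read_junction_bed(path) -> JunctionReadResult:
    """Read junctions from BED6 or BED12.

    BED6: the feature interval *is* the intron.  BED12 (as emitted by
    spliced aligners): the junction is the gap between the two anchor
    blocks; lines with a block count other than 2 are skipped with a
    warning and counted.
    """
    junctions: list[Junction] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 else "."
            if len(f) >= 12:
                n_blocks = int(f[9])
                if n_blocks != 2:
                    skipped += 1
                    warnings.warn(
                        f"junction BED12 line with blockCount={n_blocks} skipped",
                        stacklevel=2,
                    )
                    continue
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                intron_start = start + starts[0] + sizes[0]
                intron_end = start + starts[1]
                junctions.append(Junction(chrom, intron_start, intron_end, strand, name))
            else:
                junctions.append(Junction(chrom, start, end, strand, name))
    return JunctionReadResult(junctions, skipped)


def write_junction_bed(junctions: list[Junction], path) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            name = j.name or f"j{i}"
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t{name}\t0\t{j.strand}\n")


PROBED_COLUMNS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "reserved", "blockCount", "blockSizes",
    "chromStarts", "peptideSequence", "uniqueness", "psmScore", "fdr",
    "modifications",
]


@dataclass
class ProBedRecord:
    """One peptide placement: BED12 core plus the proBed peptide columns."""

    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    name: str
    peptide: str
    uniqueness: str = "unique"
    psm_score: float | None = None
    fdr: str = "."
    modifications: str = "."

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"proBed record {self.name}: needs at least one block")
        self.blocks = sorted(tuple(b) for b in self.blocks)
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"proBed record {self.name}: overlapping blocks")

    @property
    def chrom_start(self) -> int:
        return self.blocks[0][0]

    @property
    def chrom_end(self) -> int:
        return self.blocks[-1][1]


def write_probed(records: list[ProBedRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PROBED_COLUMNS) + "\n")
        for r in records:
            cs, ce = r.chrom_start, r.chrom_end
            for s, e in r.blocks:
                if s < cs or e > ce:
                    raise ValueError(f"block [{s},{e}) outside [{cs},{ce})")
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            starts = ",".join(str(s - cs) for s, _ in r.blocks)
            score = "." if r.psm_score is None else f"{r.psm_score:g}"
            fh.write(
                "\t".join(
                    [
                        r.chrom, str(cs), str(ce), r.name, "1000", r.strand,
                        str(cs), str(ce), "0", str(len(r.blocks)), sizes, starts,
                        r.peptide, r.uniqueness, score, r.fdr, r.modifications,
                    ]
                )
                + "\n"
            )


def read_probed(path) -> list[ProBedRecord]:
    records: list[ProBedRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            records.append(
                ProBedRecord(
                    chrom=f[0], strand=f[5], blocks=blocks, name=f[3],
                    peptide=f[12], uniqueness=f[13],
                    psm_score=None if f[14] == "." else float(f[14]),
                    fdr=f[15], modifications=f[16],
                )
            )
    return records


PSM_REQUIRED_COLUMNS = [
    "spectrum_id", "dataset_id", "peptide", "charge", "precursor_mass",
    "score", "is_decoy", "db_entries",
]

_TRUE_STRINGS = {"1", "true", "yes", "t", "y"}


def read_psm_table(path) -> list[PsmRecord]:
    """Read the neutral PSM TSV.

    Required columns: spectrum_id, dataset_id, peptide, charge,
    precursor_mass, score, is_decoy, db_entries (semicolon-separated
    accessions).  Peptides are uppercased; I/L are preserved as given.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PSM_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing required columns: {', '.join(missing)}")
    records: list[PsmRecord] = []
    for row in df.itertuples(index=False):
        records.append(
            PsmRecord(
                spectrum_id=row.spectrum_id,
                dataset_id=row.dataset_id,
                peptide=str(row.peptide).upper(),
                charge=int(row.charge),
                precursor_mass=float(row.precursor_mass),
                score=float(row.score),
                is_decoy=str(row.is_decoy).strip().lower() in _TRUE_STRINGS,
                db_entries=tuple(
                    a for a in str(row.db_entries).split(";") if a and a != "nan"
                ),
            )
        )
    return records


def write_psm_table(psms: list[PsmRecord], path) -> None:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "dataset_id": p.dataset_id,
            "peptide": p.peptide,
            "charge": p.charge,
            "precursor_mass": f"{p.precursor_mass:.4f}",
            "score": f"{p.score:.6f}",
            "is_decoy": int(p.is_decoy),
            "db_entries": ";".join(p.db_entries),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_REQUIRED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta_entries(path) -> list[tuple[str, str]]:
    """(accession, sequence) pairs from a protein FASTA."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta_entries(entries, path) -> None:
    with open(path, "w") as fh:
        for item in entries:
            acc, seq = (item.accession, item.sequence) if hasattr(item, "accession") else item
            desc = getattr(item, "header_description", "")
            fh.write(f">{acc}{(' ' + desc) if desc else ''}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
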