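"""Transcript / junction novelty calling against a reference annotation.

An assembled transcriptome and its observed splice junctions are compared with
the official gene models.  Multi-exon transcripts are *known* when their full
intron chain is annotated; observed junctions are *known* when the identical
intron interval is annotated.  Everything else becomes a novel transcript (NT)
or novel junction (NJ); together these are the novel events (NEs) that seed
the customized protein search database.

All coordinates are 0-based half-open genomic intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import stable_hash

Interval = tuple[int, int]


@dataclass(frozen=True)
class Junction:
    """An intron interval: first intronic base to last intronic base + 1."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)


@dataclass
class TranscriptModel:
    """A stranded exon chain on one chromosome."""

    id: str
    chrom: str
    strand: str
    exons: list[Interval]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: needs at least one exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"transcript {self.id}: empty exon [{s},{e})")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def intron_chain(self) -> tuple[Interval, ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    def chain_key(self) -> tuple:
        """Identity used for the '=' (known) class: chrom, strand, intron chain."""
        return (self.chrom, self.strand, self.intron_chain)


@dataclass
class AnnotationSet:
    """Official transcripts grouped by gene, with per-transcript coding flags."""

    transcripts: list[TranscriptModel] = field(default_factory=list)
    coding: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_id = {t.id: t for t in self.transcripts}
        self.genes: dict[str, list[str]] = {}
        for t in self.transcripts:
            gid = t.gene_id or t.id
            self.genes.setdefault(gid, []).append(t.id)

    def intron_keys(self) -> set[tuple[str, str, int, int]]:
        keys: set[tuple[str, str, int, int]] = set()
        for t in self.transcripts:
            for s, e in t.intron_chain:
                keys.add((t.chrom, t.strand, s, e))
        return keys

    def chain_keys(self) -> set[tuple]:
        return {t.chain_key() for t in self.transcripts if t.intron_chain}

    def gene_spans(self) -> dict[str, tuple[str, int, int]]:
        """Hull over all transcripts of each gene (strand ignored)."""
        spans: dict[str, tuple[str, int, int]] = {}
        for gid, tids in self.genes.items():
            ts = [self.by_id[tid] for tid in tids]
            spans[gid] = (
                ts[0].chrom,
                min(t.span[0] for t in ts),
                max(t.span[1] for t in ts),
            )
        return spans


@dataclass
class NovelEvent:
    """A novel junction (single intron) or novel transcript (exon chain)."""

    id: str
    kind: str  # "NT" | "NJ"
    chrom: str
    strand: str
    exons: list[Interval] | None = None  # NT only
    intron: Interval | None = None  # NJ only
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "NT" and not self.exons:
            raise ValueError(f"NT event {self.id} requires an exon chain")
        if self.kind == "NJ" and self.intron is None:
            raise ValueError(f"NJ event {self.id} requires an intron interval")

    @property
    def span(self) -> Interval:
        if self.kind == "NT":
            assert self.exons is not None
            return (self.exons[0][0], self.exons[-1][1])
        assert self.intron is not None
        return self.intron


def extract_junctions(t: TranscriptModel) -> list[Junction]:
    """Introns of a transcript: the gaps between consecutive exons."""
    return [Junction(t.chrom, s, e, t.strand) for s, e in t.intron_chain]


def classify_junctions(
    observed: list[Junction], official: AnnotationSet
) -> tuple[list[Junction], list[Junction]]:
    """Partition observed junctions into (known, novel) after site-level dedup.

    A junction is known iff the identical (chrom, strand, start, end) tuple
    occurs among the introns of an official transcript.  Junctions with
    strand "." (unstranded libraries) are known if either strand matches.
    """
    known_keys = official.intron_keys()
    seen: set[tuple] = set()
    known: list[Junction] = []
    novel: list[Junction] = []
    for j in observed:
        if j.key() in seen:
            continue
        seen.add(j.key())
        if j.strand == ".":
            hit = any(
                (j.chrom, s, j.start, j.end) in known_keys for s in ("+", "-", ".")
            )
        else:
            hit = j.key() in known_keys
        (known if hit else novel).append(j)
    return known, novel


def _mono_exon_known(t: TranscriptModel, official: AnnotationSet) -> bool:
    s, e = t.exons[0]
    for ot in official.transcripts:
        if ot.chrom != t.chrom or ot.strand != t.strand:
            continue
        for os_, oe in ot.exons:
            if os_ <= s and e <= oe:
                return True
    return False


def classify_transcripts(
    assembled: list[TranscriptModel], official: AnnotationSet
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition assembled transcripts into (known, novel).

    Multi-exon: known iff the full intron chain (same chrom/strand) equals the
    chain of some official transcript — exon-end differences are ignored.
    Mono-exonic: known iff fully contained within one exon of a same-strand
    official transcript.
    """
    chains = official.chain_keys()
    known: list[TranscriptModel] = []
    novel: list[TranscriptModel] = []
    for t in assembled:
        if t.intron_chain:
            hit = t.chain_key() in chains
        else:
            hit = _mono_exon_known(t, official)
        (known if hit else novel).append(t)
    return known, novel


def merge_assembled(runs: list[list[TranscriptModel]]) -> list[TranscriptModel]:
    """Combine per-run assemblies into one deduplicated transcript set.

    Multi-exon transcripts sharing (chrom, strand, intron chain) collapse to a
    single model with the widest span (min start / max end of the terminal
    exons).  Mono-exonic transcripts collapse by containment, keeping the
    widest.  Idempotent.
    """
    multi: dict[tuple, TranscriptModel] = {}
    mono: list[TranscriptModel] = []
    for run in runs:
        for t in run:
            if t.intron_chain:
                key = t.chain_key()
                prev = multi.get(key)
                if prev is None:
                    multi[key] = TranscriptModel(
                        t.id, t.chrom, t.strand, list(t.exons), t.gene_id
                    )
                else:
                    exons = list(prev.exons)
                    exons[0] = (min(exons[0][0], t.exons[0][0]), exons[0][1])
                    exons[-1] = (exons[-1][0], max(exons[-1][1], t.exons[-1][1]))
                    multi[key] = TranscriptModel(
                        prev.id, prev.chrom, prev.strand, exons, prev.gene_id
                    )
            else:
                mono.append(t)

    # mono-exonic: widest first, drop anything contained in a kept one
    mono.sort(key=lambda t: (t.exons[0][0] - t.exons[0][1], t.chrom, t.exons[0]))
    kept_mono: list[TranscriptModel] = []
    for t in mono:
        s, e = t.exons[0]
        contained = any(
            k.chrom == t.chrom
            and k.strand == t.strand
            and k.exons[0][0] <= s
            and e <= k.exons[0][1]
            for k in kept_mono
        )
        if not contained:
            kept_mono.append(t)

    out = list(multi.values()) + kept_mono
    out.sort(key=lambda t: (t.chrom, t.span, t.strand, t.id))
    return out


def nt_event_id(t: TranscriptModel) -> str:
    s, e = t.span
    tag = stable_hash((t.chrom, t.strand, t.intron_chain or tuple(t.exons)))
    return f"NT:{t.chrom}:{s}-{e}:{t.strand}:{tag}"


def nj_event_id(j: Junction) -> str:
    return f"NJ:{j.chrom}:{j.start}-{j.end}:{j.strand}"


def build_novel_event_set(
    novel_transcripts: list[TranscriptModel],
    novel_junctions: list[Junction],
    subsume_nj: bool = True,
) -> list[NovelEvent]:
    """Assemble the NE set: one event per NT, one per NJ.

    With ``subsume_nj`` (default) an NJ identical to an intron of a retained
    NT is not emitted separately — it is already represented by the NT and
    would double-count in downstream clusters.  Event ids are deterministic.
    """
    events: list[NovelEvent] = []
    nt_introns: set[tuple] = set()
    for t in novel_transcripts:
        events.append(
            NovelEvent(
                id=nt_event_id(t),
                kind="NT",
                chrom=t.chrom,
                strand=t.strand,
                exons=list(t.exons),
                source_ids=(t.id,),
            )
        )
        for s, e in t.intron_chain:
            nt_introns.add((t.chrom, t.strand, s, e))
            nt_introns.add((t.chrom, ".", s, e))

    seen: set[tuple] = set()
    for j in novel_junctions:
        if j.key() in seen:
            continue
        seen.add(j.key())
        if subsume_nj and (j.chrom, j.strand, j.start, j.end) in nt_introns:
            continue
        events.append(
            NovelEvent(
                id=nj_event_id(j),
                kind="NJ",
                chrom=j.chrom,
                strand=j.strand,
                intron=(j.start, j.end),
                source_ids=(j.name,) if j.name else (),
            )
        )
    return events
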