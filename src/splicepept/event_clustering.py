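"""Genomic clustering of novel events and attachment of novel peptides.

Novel events within 100 bp of each other (half-open gap: next start minus
previous end) merge into one cluster per chromosome by single linkage —
the same semantics as interval-merge tools with a distance option.
Clustering is strand-agnostic by default, matching how events are grouped
on genomic loci; a stranded mode is available.

A cluster containing at least one novel transcript is an NT cluster (the
transcript suggests the gene model, junctions complement it); a cluster of
junctions only is an NJ cluster.  An intergenic NT cluster is a novel gene
candidate; an intragenic one complements a known gene model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation_events import AnnotationSet, NovelEvent
from .peptide_genome_map import GenomicPeptide, GeneSpanIndex

Interval = tuple[int, int]


@dataclass
class EventCluster:
    id: str
    chrom: str
    span: Interval
    members: list[NovelEvent] = field(default_factory=list)
    fnps: list[str] = field(default_factory=list)
    kind: str | None = None  # NT-cluster | NJ-cluster
    locus: str | None = None  # intergenic | intragenic
    strand: str | None = None  # only set in stranded mode

    @property
    def member_ids(self) -> list[str]:
        return [e.id for e in self.members]


def merge_events(
    events: list[NovelEvent], max_gap: int = 100, stranded: bool = False
) -> list[EventCluster]:
    """Single-linkage merge of event spans per chromosome.

    Two events join iff the half-open gap (next.start - prev.end) is at most
    ``max_gap``; overlapping events always join.  Cluster spans are union
    hulls; ids are deterministic in (chrom, start).
    """
    groups: dict[tuple, list[NovelEvent]] = {}
    for e in events:
        key = (e.chrom, e.strand) if stranded else (e.chrom,)
        groups.setdefault(key, []).append(e)

    clusters: list[EventCluster] = []
    for key in sorted(groups):
        evs = sorted(groups[key], key=lambda e: (e.span, e.id))
        current: list[NovelEvent] = []
        cur_end = None
        for e in evs:
            s, t = e.span
            if current and s - cur_end <= max_gap:
                current.append(e)
                cur_end = max(cur_end, t)
            else:
                if current:
                    clusters.append(_finish(current, key, stranded))
                current = [e]
                cur_end = t
        if current:
            clusters.append(_finish(current, key, stranded))
    clusters.sort(key=lambda c: (c.chrom, c.span))
    return clusters


def _finish(members: list[NovelEvent], key: tuple, stranded: bool) -> EventCluster:
    chrom = key[0]
    start = min(e.span[0] for e in members)
    end = max(e.span[1] for e in members)
    cid = f"CL:{chrom}:{start}-{end}" + (f":{key[1]}" if stranded else "")
    return EventCluster(
        id=cid,
        chrom=chrom,
        span=(start, end),
        members=list(members),
        strand=key[1] if stranded else None,
    )


def attach_and_classify(
    clusters: list[EventCluster],
    fnps: list[GenomicPeptide],
    official: AnnotationSet,
) -> list[EventCluster]:
    """Attach unique-mapping FNPs to the clusters containing their source
    events; set cluster kind and locus.

    Raises if a peptide's source event is in no cluster (clustering must
    cover every event).
    """
    cluster_by_event: dict[str, EventCluster] = {}
    for c in clusters:
        for e in c.members:
            cluster_by_event[e.id] = c

    for gp in fnps:
        if gp.mapping_class == "multi":
            continue
        for ev_id in gp.source_events:
            c = cluster_by_event.get(ev_id)
            if c is None:
                raise ValueError(
                    f"peptide {gp.peptide}: source event {ev_id} not in any cluster"
                )
            if gp.peptide not in c.fnps:
                c.fnps.append(gp.peptide)

    index = GeneSpanIndex(official)
    for c in clusters:
        c.kind = (
            "NT-cluster" if any(e.kind == "NT" for e in c.members) else "NJ-cluster"
        )
        s, t = c.span
        c.locus = "intragenic" if index.overlaps(c.chrom, s, t) else "intergenic"
    return clusters


def cluster_report(
    clusters: list[EventCluster], peptides: list[GenomicPeptide]
) -> pd.DataFrame:
    """Count table of novel peptides and clusters by locus class.

    Rows: all FNPs (those whose placements agree on one locus class),
    unique-mapping FNPs, NT clusters, NJ clusters; columns total /
    intergenic / intragenic.  Cluster rows count only clusters with at
    least one attached FNP; totals are the sums of the two locus columns.
    """

    def pep_row(preds) -> dict:
        by_pep: dict[str, set[str]] = {}
        for gp in preds:
            by_pep.setdefault(gp.peptide, set()).add(gp.locus_class)
        inter = sum(1 for v in by_pep.values() if v == {"intergenic"})
        intra = sum(1 for v in by_pep.values() if v == {"intragenic"})
        return {"total": inter + intra, "intergenic": inter, "intragenic": intra}

    fnp_row = pep_row([gp for gp in peptides if gp.locus_class])
    uniq_row = pep_row(
        [gp for gp in peptides if gp.locus_class and gp.mapping_class == "unique"]
    )

    rows = {
        "FNPs": fnp_row,
        "unique_mapping_FNPs": uniq_row,
    }
    for kind, label in (("NT-cluster", "NT_clusters"), ("NJ-cluster", "NJ_clusters")):
        sel = [c for c in clusters if c.kind == kind and c.fnps]
        inter = sum(1 for c in sel if c.locus == "intergenic")
        intra = sum(1 for c in sel if c.locus == "intragenic")
        rows[label] = {"total": inter + intra, "intergenic": inter, "intragenic": intra}

    return pd.DataFrame.from_dict(rows, orient="index")[
        ["total", "intergenic", "intragenic"]
    ]
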