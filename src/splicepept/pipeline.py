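"""End-to-end orchestration of the proteogenomics pipeline.

Stages run in a fixed order — novelty calling, database construction,
q-value thresholding and partitioning, the exclusion cascade, peptide-to-
genome mapping, event clustering, coding-potential scoring — each writing
its table outputs under the configured output directory.  A run is a pure
function of the configuration and input files: re-running with the same
inputs reproduces every output byte.  With ``resume=True`` completed stages
are skipped when the configuration/input checksum recorded in the manifest
still matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import pickle
from dataclasses import dataclass, field

import pandas as pd

from .annotation_events import (
    build_novel_event_set,
    classify_junctions,
    classify_transcripts,
    merge_assembled,
)
from .coding_potential import coding_probability, train_cp_model
from .event_clustering import attach_and_classify, cluster_report, merge_events
from .io_formats import (
    GenomeSequence,
    read_fasta_entries,
    read_gtf,
    read_junction_bed,
    read_psm_table,
    write_fasta_entries,
    write_gtf,
    write_junction_bed,
    write_probed,
)
from .novelty_filters import CascadeConfig, final_novel_peptides, run_cascade
from .orf_database import build_search_database, event_nucleotide_sequence
from .peptide_genome_map import (
    GeneSpanIndex,
    all_placements,
    classify_locus,
    classify_mapping,
    to_probed,
)
from .psm_processing import assign_q_values, summarize_identifications, threshold_and_group


class PipelineStageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    genome: str
    reference_gtf: str
    assembled_gtf: str
    junction_bed: str
    proteome: str
    contaminants: str
    psm_table: str
    exclusion: str | None = None
    cp_coding: str | None = None
    cp_noncoding: str | None = None
    outdir: str = "splicepept_out"
    q_cut: float = 0.01
    flank: int = 96
    min_product_aa: int = 5
    min_search_len: int = 6
    min_spectra: int = 2
    mass_tol: float = 0.02
    missed_cleavages: int = 2
    max_gap: int = 100
    stranded_clustering: bool = False

    def input_paths(self) -> dict[str, str]:
        keys = [
            "genome", "reference_gtf", "assembled_gtf", "junction_bed",
            "proteome", "contaminants", "psm_table", "exclusion",
            "cp_coding", "cp_noncoding",
        ]
        return {k: getattr(self, k) for k in keys if getattr(self, k)}


@dataclass
class PipelineResult:
    summary: dict = field(default_factory=dict)
    context: dict = field(default_factory=dict)


def _config_hash(cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    d = dataclasses.asdict(cfg)
    d.pop("outdir")
    h.update(json.dumps(d, sort_keys=True).encode())
    for name, path in sorted(cfg.input_paths().items()):
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing input '{name}': {path}")
        h.update(name.encode())
        with open(path, "rb") as fh:
            h.update(hashlib.sha256(fh.read()).digest())
    return h.hexdigest()


def _stage_load(ctx: dict, cfg: PipelineConfig) -> None:
    for name, path in cfg.input_paths().items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing input '{name}': {path}")
    ctx["genome"] = GenomeSequence.from_fasta(cfg.genome)
    ctx["annotation"] = read_gtf(cfg.reference_gtf)
    ctx["assembled"] = read_gtf(cfg.assembled_gtf).transcripts
    ctx["junctions"] = list(read_junction_bed(cfg.junction_bed))
    ctx["official"] = read_fasta_entries(cfg.proteome)
    ctx["contaminants"] = read_fasta_entries(cfg.contaminants)
    ctx["psms"] = read_psm_table(cfg.psm_table)
    exclusion: set[str] = set()
    if cfg.exclusion:
        df = pd.read_csv(cfg.exclusion, sep="\t")
        exclusion = set(df["peptide"].astype(str))
    ctx["exclusion"] = exclusion


def _stage_events(ctx: dict, cfg: PipelineConfig) -> None:
    merged = merge_assembled([ctx["assembled"]])
    known_t, novel_t = classify_transcripts(merged, ctx["annotation"])
    known_j, novel_j = classify_junctions(ctx["junctions"], ctx["annotation"])
    events = build_novel_event_set(novel_t, novel_j)
    ctx["events"] = events
    ctx["summary"]["events"] = {
        "assembled_transcripts": len(merged),
        "known_transcripts": len(known_t),
        "novel_transcripts": len(novel_t),
        "known_junction_sites": len(known_j),
        "novel_junction_sites": len(novel_j),
        "novel_events": len(events),
    }
    out = ctx["outdir"]
    from .annotation_events import TranscriptModel

    nts = [
        TranscriptModel(e.id, e.chrom, e.strand if e.strand in "+-" else "+", e.exons)
        for e in events
        if e.kind == "NT"
    ]
    write_gtf(nts, os.path.join(out, "novel_transcripts.gtf"))
    from .annotation_events import Junction

    njs = [
        Junction(e.chrom, e.intron[0], e.intron[1], e.strand, e.id)
        for e in events
        if e.kind == "NJ"
    ]
    write_junction_bed(njs, os.path.join(out, "novel_junctions.bed"))
    pd.DataFrame(
        [
            {"event_id": e.id, "kind": e.kind, "chrom": e.chrom,
             "start": e.span[0], "end": e.span[1], "strand": e.strand}
            for e in events
        ]
    ).to_csv(os.path.join(out, "novel_events.tsv"), sep="\t", index=False)


def _stage_builddb(ctx: dict, cfg: PipelineConfig) -> None:
    entries = build_search_database(
        ctx["events"],
        ctx["genome"],
        ctx["official"],
        ctx["contaminants"],
        flank=cfg.flank,
        min_product_aa=cfg.min_product_aa,
    )
    ctx["db_entries"] = entries
    searchable = [e for e in entries if len(e.sequence) >= cfg.min_search_len]
    write_fasta_entries(searchable, os.path.join(ctx["outdir"], "search_db.fasta"))
    rows = [
        {"accession": e.accession, "event_id": p.event_id, "frame": p.frame,
         "chrom": p.chrom, "strand": p.event_strand,
         "blocks": ";".join(f"{s}-{t}" for s, t in p.blocks)}
        for e in entries
        if e.category == "novel"
        for p in e.provenance
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(ctx["outdir"], "db_provenance.tsv"), sep="\t", index=False
    )
    ctx["summary"]["database"] = {
        "novel_entries": sum(1 for e in entries if e.category == "novel"),
        "official_entries": sum(1 for e in entries if e.category == "official"),
        "contaminant_entries": sum(1 for e in entries if e.category == "contaminant"),
        "searchable_entries": len(searchable),
    }


def _stage_fdr(ctx: dict, cfg: PipelineConfig) -> None:
    psms = assign_q_values(ctx["psms"])
    categories = {e.accession: e.category for e in ctx["db_entries"]}
    groups = threshold_and_group(psms, categories, q_cut=cfg.q_cut)
    ctx["groups"] = groups
    summary = summarize_identifications(groups, psms)
    summary.to_csv(os.path.join(ctx["outdir"], "id_summary.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"peptide": g.sequence, "status": g.status, "spectra": g.spectral_count,
             "datasets": ",".join(sorted(g.datasets)),
             "db_entries": ";".join(sorted(g.db_entries))}
            for g in groups
        ]
    ).to_csv(os.path.join(ctx["outdir"], "peptide_groups.tsv"), sep="\t", index=False)
    ctx["summary"]["identification"] = {
        "psms_total": len(psms),
        "psms_accepted": sum(
            1 for p in psms if not p.is_decoy and p.q_value < cfg.q_cut
        ),
        "peptides": len(groups),
        "known_peptides": sum(1 for g in groups if g.status == "known"),
        "pnps": sum(1 for g in groups if g.status == "PNP"),
    }


def _stage_filter(ctx: dict, cfg: PipelineConfig) -> None:
    pnps = [g for g in ctx["groups"] if g.status == "PNP"]
    proteome = [
        e for e in ctx["db_entries"] if e.category in ("official", "contaminant")
    ]
    cascade_cfg = CascadeConfig(
        mass_tol=cfg.mass_tol,
        min_spectra=cfg.min_spectra,
        missed_cleavages=cfg.missed_cleavages,
    )
    verdicts, venn = run_cascade(
        pnps, proteome, cascade_cfg, exclusion_list=ctx["exclusion"]
    )
    ctx["verdicts"] = verdicts
    ctx["fnps"] = final_novel_peptides(verdicts)
    pd.DataFrame(
        [
            {"peptide": v.peptide, "flags": "+".join(sorted(v.flags)) or ".",
             "final": v.final}
            for v in verdicts
        ]
    ).to_csv(os.path.join(ctx["outdir"], "filter_verdicts.tsv"), sep="\t", index=False)
    venn.to_csv(os.path.join(ctx["outdir"], "filter_venn.tsv"), sep="\t", index=False)
    flag_counts: dict[str, int] = {}
    for v in verdicts:
        for f in v.flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
    ctx["summary"]["filtration"] = {
        "pnps_in": len(pnps),
        "removed": sum(1 for v in verdicts if v.final == "removed"),
        "fnps": len(ctx["fnps"]),
        **{f"flag_{k}": v for k, v in sorted(flag_counts.items())},
    }


def _stage_map(ctx: dict, cfg: PipelineConfig) -> None:
    entries = ctx["db_entries"]
    index = GeneSpanIndex(ctx["annotation"])
    placements = {}
    probed = []
    rows = []
    for pep in ctx["fnps"]:
        pls = all_placements(pep, entries)
        if not pls:
            raise PipelineStageError(f"FNP {pep} maps to no novel entry")
        mapping = classify_mapping(pls)
        for gp in pls:
            classify_locus(gp, index)
            probed.append(to_probed(gp))
        placements[pep] = pls
        rows.append(
            {"peptide": pep, "mapping": mapping, "n_placements": len(pls),
             "locus": pls[0].locus_class if mapping == "unique" else ".",
             "events": ";".join(sorted({e for gp in pls for e in gp.source_events}))}
        )
    ctx["placements"] = placements
    probed.sort(key=lambda r: (r.chrom, r.chrom_start, r.peptide))
    write_probed(probed, os.path.join(ctx["outdir"], "fnps.probed"))
    pd.DataFrame(rows).to_csv(
        os.path.join(ctx["outdir"], "peptide_classes.tsv"), sep="\t", index=False
    )
    uniq = [p for p in rows if p["mapping"] == "unique"]
    ctx["summary"]["mapping"] = {
        "fnps": len(rows),
        "unique_mapping": len(uniq),
        "multi_mapping": len(rows) - len(uniq),
        "intergenic": sum(1 for p in uniq if p["locus"] == "intergenic"),
        "intragenic": sum(1 for p in uniq if p["locus"] == "intragenic"),
    }


def _stage_cluster(ctx: dict, cfg: PipelineConfig) -> None:
    clusters = merge_events(
        ctx["events"], max_gap=cfg.max_gap, stranded=cfg.stranded_clustering
    )
    flat = [gp for pls in ctx["placements"].values() for gp in pls]
    attach_and_classify(clusters, flat, ctx["annotation"])
    report = cluster_report(clusters, flat)
    ctx["clusters"] = clusters
    ctx["cluster_table"] = report
    out = ctx["outdir"]
    with open(os.path.join(out, "clusters.bed"), "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.span[0]}\t{c.span[1]}\t{c.id}\t{len(c.fnps)}\t"
                f"{c.strand or '.'}\n"
            )
    pd.DataFrame(
        [
            {"cluster_id": c.id, "kind": c.kind, "locus": c.locus,
             "n_events": len(c.members), "n_fnps": len(c.fnps),
             "members": ";".join(c.member_ids)}
            for c in clusters
        ]
    ).to_csv(os.path.join(out, "cluster_members.tsv"), sep="\t", index=False)
    report.to_csv(os.path.join(out, "cluster_report.tsv"), sep="\t")
    with_fnps = [c for c in clusters if c.fnps]
    ctx["summary"]["clustering"] = {
        "clusters_total": len(clusters),
        "clusters_with_fnps": len(with_fnps),
        "nt_clusters": sum(1 for c in with_fnps if c.kind == "NT-cluster"),
        "nj_clusters": sum(1 for c in with_fnps if c.kind == "NJ-cluster"),
    }


def _stage_cpat(ctx: dict, cfg: PipelineConfig) -> None:
    if not (cfg.cp_coding and cfg.cp_noncoding):
        ctx["summary"]["coding_potential"] = {"skipped": 1}
        return
    coding = [s for _, s in read_fasta_entries(cfg.cp_coding)]
    noncoding = [s for _, s in read_fasta_entries(cfg.cp_noncoding)]
    model = train_cp_model(coding, noncoding)
    model.to_json(os.path.join(ctx["outdir"], "cp_model.json"))
    rows = []
    for e in ctx["events"]:
        if e.kind != "NT":
            continue
        seq = event_nucleotide_sequence(e, ctx["genome"], flank=cfg.flank).dna
        cp, label = coding_probability(seq, model)
        feats = model.features(seq)
        rows.append(
            {"event_id": e.id, "orf_size": feats[0], "fickett": round(feats[1], 4),
             "hexamer": round(feats[2], 4), "cp": round(cp, 6), "label": label}
        )
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(ctx["outdir"], "cp_scores.tsv"), sep="\t", index=False)
    ctx["cp_model"] = model
    ctx["summary"]["coding_potential"] = {
        "nts_scored": len(rows),
        "labeled_coding": int((df["label"] == "coding").sum()) if len(rows) else 0,
        "threshold": model.threshold,
    }


_STAGES = [
    ("load", _stage_load),
    ("events", _stage_events),
    ("builddb", _stage_builddb),
    ("fdr", _stage_fdr),
    ("filter", _stage_filter),
    ("map", _stage_map),
    ("cluster", _stage_cluster),
    ("cpat", _stage_cpat),
]


def run_pipeline(
    cfg: PipelineConfig, resume: bool = False, until: str | None = None
) -> PipelineResult:
    """Run all stages (or through stage ``until``); returns the stage
    summary and in-memory context.

    Any stage failure is re-raised as :class:`PipelineStageError` naming the
    stage.  With ``resume=True``, stages whose checkpoint matches the
    configuration/input checksum are restored instead of recomputed.
    """
    stage_names = [n for n, _ in _STAGES]
    if until is not None and until not in stage_names:
        raise ValueError(f"unknown stage '{until}'; stages: {stage_names}")
    stages = (
        _STAGES
        if until is None
        else _STAGES[: stage_names.index(until) + 1]
    )
    os.makedirs(cfg.outdir, exist_ok=True)
    ckpt_dir = os.path.join(cfg.outdir, ".checkpoints")
    os.makedirs(ckpt_dir, exist_ok=True)
    manifest_path = os.path.join(ckpt_dir, "manifest.json")
    conf_hash = _config_hash(cfg)

    manifest: dict[str, str] = {}
    if resume and os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)

    start_idx = 0
    ctx: dict = {"outdir": cfg.outdir, "summary": {}}
    if resume:
        for i, (name, _) in enumerate(stages):
            ckpt = os.path.join(ckpt_dir, f"{name}.pkl")
            if manifest.get(name) == conf_hash and os.path.exists(ckpt):
                start_idx = i + 1
            else:
                break
        if start_idx:
            last = stages[start_idx - 1][0]
            with open(os.path.join(ckpt_dir, f"{last}.pkl"), "rb") as fh:
                ctx = pickle.load(fh)
            ctx["outdir"] = cfg.outdir

    for name, fn in stages[start_idx:]:
        try:
            fn(ctx, cfg)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
        with open(os.path.join(ckpt_dir, f"{name}.pkl"), "wb") as fh:
            pickle.dump(ctx, fh)
        manifest[name] = conf_hash
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)

    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(ctx["summary"], fh, sort_keys=True, indent=1)
    return PipelineResult(summary=ctx["summary"], context=ctx)
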