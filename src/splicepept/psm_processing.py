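"""Target-decoy q-value estimation and known / putative-novel partitioning.

PSMs are ranked by a single search score (higher is better).  The estimated
FDR at a score threshold is (#decoys accepted) / (#targets accepted); the
q-value of a PSM is the minimum FDR over all thresholds that accept it
(running minimum from the worst score upward).  Target PSMs below the
q-value cutoff are grouped into peptides, and a peptide is *known* when at
least one of its database matches is an official or contaminant protein —
otherwise it is a putative novel peptide (PNP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._util import percent_half_up


@dataclass
class PsmRecord:
    spectrum_id: str
    dataset_id: str
    peptide: str
    charge: int
    precursor_mass: float
    score: float
    is_decoy: bool
    db_entries: tuple[str, ...] = ()
    q_value: float | None = None


@dataclass
class PeptideGroup:
    sequence: str
    psms: list[PsmRecord] = field(default_factory=list)
    status: str = "PNP"  # known | PNP | excluded
    contaminant: bool = False

    @property
    def datasets(self) -> set[str]:
        return {p.dataset_id for p in self.psms}

    @property
    def db_entries(self) -> set[str]:
        return {acc for p in self.psms for acc in p.db_entries}

    @property
    def spectral_count(self) -> int:
        return len(self.psms)


def assign_q_values(psms: list[PsmRecord]) -> list[PsmRecord]:
    """Assign target-decoy q-values in place (and return the list).

    PSMs sharing a score share counts and hence a q-value.  The FDR
    denominator counts targets only (standard decoy estimate); an all-decoy
    input gets q = 1 with a warning.
    """
    if not psms:
        return psms
    if all(p.is_decoy for p in psms):
        warnings.warn("all PSMs are decoys; q-values set to 1", stacklevel=2)
        for p in psms:
            p.q_value = 1.0
        return psms

    ranked = sorted(psms, key=lambda p: -p.score)
    # FDR at each distinct score level, walking from best to worst
    levels: list[tuple[float, float]] = []  # (score, fdr)
    n_t = n_d = 0
    i = 0
    while i < len(ranked):
        j = i
        while j < len(ranked) and ranked[j].score == ranked[i].score:
            n_d += ranked[j].is_decoy
            n_t += not ranked[j].is_decoy
            j += 1
        levels.append((ranked[i].score, n_d / max(1, n_t)))
        i = j
    # q-value: running minimum of FDR from the worst level upward
    q_by_score: dict[float, float] = {}
    running = 1.0
    for score, fdr in reversed(levels):
        running = min(running, fdr)
        q_by_score[score] = running
    for p in psms:
        p.q_value = min(1.0, q_by_score[p.score])
    return psms


def threshold_and_group(
    psms: list[PsmRecord],
    category_by_accession: dict[str, str],
    q_cut: float = 0.01,
) -> list[PeptideGroup]:
    """Keep target PSMs with q-value strictly below ``q_cut`` and group them.

    Grouping is by exact peptide sequence (I and L distinct, as reported by
    search engines).  Status: known iff any matched entry is official or
    contaminant; PNP iff all matched entries are novel.
    """
    groups: dict[str, PeptideGroup] = {}
    for p in psms:
        if p.is_decoy:
            continue
        if p.q_value is None:
            raise ValueError("q-values must be assigned before thresholding")
        if p.q_value >= q_cut:
            continue
        groups.setdefault(p.peptide, PeptideGroup(sequence=p.peptide)).psms.append(p)
    for g in groups.values():
        cats = {category_by_accession.get(acc, "novel") for acc in g.db_entries}
        g.contaminant = "contaminant" in cats
        g.status = "known" if cats & {"official", "contaminant"} else "PNP"
    return sorted(groups.values(), key=lambda g: g.sequence)


def summarize_identifications(
    groups: list[PeptideGroup],
    psms: list[PsmRecord],
    total_spectra: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-dataset identification summary plus a Total row.

    Columns: spectra, identified spectra, identification rate (percent,
    half-up to 2 decimals), identified peptides, PNPs.  Spectra columns are
    additive across datasets; peptide columns in the Total row count
    *distinct* sequences, so they can be smaller than the column sums.
    ``total_spectra`` overrides the per-dataset spectrum counts when the PSM
    table does not contain one row per acquired spectrum.
    """
    datasets = sorted({p.dataset_id for p in psms})
    accepted = {(p.dataset_id, p.spectrum_id) for g in groups for p in g.psms}
    rows = []
    for ds in datasets:
        n_spectra = (
            total_spectra[ds]
            if total_spectra is not None
            else len({p.spectrum_id for p in psms if p.dataset_id == ds})
        )
        n_ident = len({s for d, s in accepted if d == ds})
        peptides = {g.sequence for g in groups if ds in g.datasets}
        pnps = {g.sequence for g in groups if ds in g.datasets and g.status == "PNP"}
        rows.append(
            {
                "dataset": ds,
                "spectra": n_spectra,
                "identified_spectra": n_ident,
                "identification_rate_pct": percent_half_up(n_ident, n_spectra),
                "peptides": len(peptides),
                "pnps": len(pnps),
            }
        )
    tot_spec = sum(r["spectra"] for r in rows)
    tot_ident = sum(r["identified_spectra"] for r in rows)
    rows.append(
        {
            "dataset": "Total",
            "spectra": tot_spec,
            "identified_spectra": tot_ident,
            "identification_rate_pct": percent_half_up(tot_ident, tot_spec),
            "peptides": len({g.sequence for g in groups}),
            "pnps": len({g.sequence for g in groups if g.status == "PNP"}),
        }
    )
    return pd.DataFrame(rows)
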