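"""Exclusion cascade turning putative novel peptides (PNPs) into final novel
peptides (FNPs).

Four independent filters, evaluated on every PNP (never short-circuited, so
overlap tables can be reported Venn-style):

* ``substring`` — the peptide occurs verbatim inside an official or
  contaminant protein, with any (non-tryptic) termini;
* ``one_mismatch`` — some equal-length window of a protein differs from the
  peptide at at most one position (exhaustive scan; a superset of a
  one-mismatch, zero-gap BLASTp match and of the substring filter);
* ``ptm_explained`` — the spectra could instead be a known tryptic peptide
  carrying a common modification.  This is a precursor mass-delta screen
  plus intake of an externally supplied exclusion list; it is *not* a
  spectrum-level re-search;
* ``low_spectra`` — fewer than two supporting MS/MS spectra.

A PNP with no flags is an FNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .orf_database import DbEntry
from .proteolysis import peptide_mono_mass, tryptic_digest
from .psm_processing import PeptideGroup

FILTER_NAMES = ["substring", "one_mismatch", "ptm_explained", "low_spectra"]

#: common modification mass deltas (Da), applied in the precursor screen
DEFAULT_MODS: list[tuple[str, float]] = [
    ("oxidation", 15.9949),
    ("phospho", 79.9663),
    ("acetyl", 42.0106),
    ("deamidation", 0.9840),
]


@dataclass
class FilterVerdict:
    peptide: str
    flags: set[str] = field(default_factory=set)
    matched_locus: tuple[str, int] | None = None  # (accession, offset)

    @property
    def final(self) -> str:
        return "FNP" if not self.flags else "removed"


def _canon(seq: str, il_equal: bool) -> str:
    return seq.replace("L", "I") if il_equal else seq


def substring_filter(
    pnp: str, proteome: list[DbEntry], il_equal: bool = False
) -> bool:
    """True iff the peptide is an exact contiguous substring of any protein."""
    q = _canon(pnp, il_equal)
    return any(q in _canon(entry.sequence, il_equal) for entry in proteome)


def one_mismatch_filter(
    pnp: str, proteome: list[DbEntry], il_equal: bool = False
) -> tuple[bool, tuple[str, int] | None]:
    """Equal-length window match with at most one mismatch and zero gaps.

    Returns (flagged, (accession, window offset) of the first hit).
    """
    q = _canon(pnp, il_equal)
    m = len(q)
    for entry in proteome:
        s = _canon(entry.sequence, il_equal)
        n = len(s)
        if n < m:
            continue
        for i in range(n - m + 1):
            mismatches = 0
            for a, b in zip(q, s[i : i + m]):
                if a != b:
                    mismatches += 1
                    if mismatches > 1:
                        break
            if mismatches <= 1:
                return True, (entry.accession, i)
    return False, None


class KnownPeptideMassIndex:
    """Sorted monoisotopic masses of the tryptic peptides of a proteome."""

    def __init__(
        self,
        proteome: list[DbEntry],
        missed_cleavages: int = 2,
        min_len: int = 6,
        max_len: int = 45,
    ):
        peptides = set()
        for entry in proteome:
            peptides.update(
                tryptic_digest(
                    entry.sequence, missed_cleavages, min_len=min_len, max_len=max_len
                )
            )
        masses = []
        for pep in peptides:
            if set(pep) <= set("ACDEFGHIKLMNPQRSTVWY"):
                masses.append(peptide_mono_mass(pep))
        self.masses = np.sort(np.asarray(masses))

    def any_within(self, mass: float, tol: float) -> bool:
        if self.masses.size == 0:
            return False
        i = np.searchsorted(self.masses, mass)
        for j in (i - 1, i):
            if 0 <= j < self.masses.size and abs(self.masses[j] - mass) <= tol:
                return True
        return False


def ptm_mass_screen(
    group: PeptideGroup,
    known_masses: KnownPeptideMassIndex,
    mods: list[tuple[str, float]] | None = None,
    tol: float = 0.02,
    exclusion_list: set[str] | None = None,
) -> bool:
    """Modification stand-in screen.

    Flag iff (a) the peptide appears in a supplied external exclusion list,
    or (b) some PSM precursor mass equals a known tryptic peptide mass plus
    a common modification delta (or no modification) within ``tol`` Da.
    """
    if exclusion_list and group.sequence in exclusion_list:
        return True
    deltas = [0.0] + [d for _, d in (DEFAULT_MODS if mods is None else mods)]
    for psm in group.psms:
        if psm.precursor_mass is None or np.isnan(psm.precursor_mass):
            raise ValueError(
                f"peptide {group.sequence}: PSM {psm.spectrum_id} lacks a "
                "precursor mass required for the modification screen"
            )
        for delta in deltas:
            if known_masses.any_within(psm.precursor_mass - delta, tol):
                return True
    return False


def spectral_count_filter(group: PeptideGroup, min_spectra: int = 2) -> bool:
    return group.spectral_count < min_spectra


@dataclass
class CascadeConfig:
    il_equal: bool = False
    mods: list[tuple[str, float]] | None = None
    mass_tol: float = 0.02
    min_spectra: int = 2
    missed_cleavages: int = 2


def run_cascade(
    pnps: list[PeptideGroup],
    proteome: list[DbEntry],
    config: CascadeConfig | None = None,
    exclusion_list: set[str] | None = None,
    known_masses: KnownPeptideMassIndex | None = None,
) -> tuple[list[FilterVerdict], pd.DataFrame]:
    """Evaluate all four filters on every PNP and tabulate flag combinations.

    ``proteome`` should contain the official and contaminant entries only.
    Returns (verdicts, Venn table); the Venn table has one row per observed
    flag combination plus the unflagged (FNP) row.
    """
    cfg = config or CascadeConfig()
    if known_masses is None:
        known_masses = KnownPeptideMassIndex(
            proteome, missed_cleavages=cfg.missed_cleavages
        )
    verdicts: list[FilterVerdict] = []
    for g in pnps:
        v = FilterVerdict(peptide=g.sequence)
        if substring_filter(g.sequence, proteome, cfg.il_equal):
            v.flags.add("substring")
        hit, locus = one_mismatch_filter(g.sequence, proteome, cfg.il_equal)
        if hit:
            v.flags.add("one_mismatch")
            v.matched_locus = locus
        if ptm_mass_screen(
            g, known_masses, cfg.mods, cfg.mass_tol, exclusion_list
        ):
            v.flags.add("ptm_explained")
        if spectral_count_filter(g, cfg.min_spectra):
            v.flags.add("low_spectra")
        verdicts.append(v)

    combos: dict[tuple[str, ...], int] = {}
    for v in verdicts:
        key = tuple(sorted(v.flags)) if v.flags else ("FNP",)
        combos[key] = combos.get(key, 0) + 1
    venn = pd.DataFrame(
        [{"flags": "+".join(k), "peptides": n} for k, n in sorted(combos.items())]
    )
    return verdicts, venn


def final_novel_peptides(verdicts: list[FilterVerdict]) -> list[str]:
    return [v.peptide for v in verdicts if v.final == "FNP"]
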