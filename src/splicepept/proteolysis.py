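"""In-silico tryptic digestion and peptide monoisotopic masses."""

from __future__ import annotations

from pyteomics import mass as _pt_mass


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 0,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[str]:
    """Tryptic peptides: cleave C-terminal to K or R, but not before P.

    Returns peptides in N-to-C order, including products with up to
    ``missed_cleavages`` internal sites; duplicates are preserved.
    """
    sequence = sequence.upper()
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    peptides: list[str] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            pep = sequence[cuts[i] : cuts[j]]
            if len(pep) >= min_len and (max_len is None or len(pep) <= max_len):
                peptides.append(pep)
    return peptides


def peptide_mono_mass(peptide: str) -> float:
    """Neutral monoisotopic mass (residues + water), in Da."""
    return _pt_mass.fast_mass(peptide, ion_type="M", charge=0)
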