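"""The four-filter exclusion cascade."""

import numpy as np
import pytest

from splicepept.novelty_filters import (
    CascadeConfig,
    KnownPeptideMassIndex,
    one_mismatch_filter,
    ptm_mass_screen,
    run_cascade,
    spectral_count_filter,
    substring_filter,
)
from splicepept.orf_database import DbEntry
from splicepept.proteolysis import peptide_mono_mass, tryptic_digest
from splicepept.psm_processing import PeptideGroup, PsmRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _entry(seq, acc="P1"):
    return DbEntry(acc, seq, "official")


def _group(pep, n_psms=2, mass=None):
    g = PeptideGroup(sequence=pep)
    for i in range(n_psms):
        g.psms.append(
            PsmRecord(
                f"s{i}", "D1", pep, 2,
                peptide_mono_mass(pep) if mass is None else mass,
                10.0, False, ("N1",),
            )
        )
    return g


class TestSubstring:
    def test_internal_substring_flagged(self):
        assert substring_filter("PEPTIDE", [_entry("XXPEPTIDEYY")])

    def test_one_mismatch_not_flagged_here(self):
        assert not substring_filter("PEPTIDK", [_entry("XXPEPTIDEYY")])

    def test_empty_proteome_never_flags(self):
        assert not substring_filter("PEPTIDE", [])

    def test_il_equivalence_optional(self):
        assert not substring_filter("PELTIDE", [_entry("XXPEITIDEYY")])
        assert substring_filter("PELTIDE", [_entry("XXPEITIDEYY")], il_equal=True)


class TestOneMismatch:
    def test_exact_match_flagged(self):
        hit, locus = one_mismatch_filter("PEPTIDE", [_entry("AAPEPTIDEBB")])
        assert hit and locus == ("P1", 2)

    def test_single_mismatch_flagged(self):
        hit, _ = one_mismatch_filter("PEPTIDK", [_entry("AAPEPTIDEBB")])
        assert hit

    def test_two_mismatches_not_flagged(self):
        hit, _ = one_mismatch_filter("PKPTIDK", [_entry("AAPEPTIDEBB")])
        assert not hit

    def test_substring_implies_one_mismatch(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            prot = "".join(rng.choice(list(AA), 60))
            i = int(rng.integers(0, 50))
            pep = prot[i : i + 8]
            proteome = [_entry(prot)]
            assert substring_filter(pep, proteome)
            assert one_mismatch_filter(pep, proteome)[0]

    @staticmethod
    def brute_force_oracle(pep, proteins):
        """Independent numpy all-window scanner."""
        q = np.frombuffer(pep.encode(), dtype=np.uint8)
        for prot in proteins:
            s = np.frombuffer(prot.encode(), dtype=np.uint8)
            for i in range(len(s) - len(q) + 1):
                if (s[i : i + len(q)] != q).sum() <= 1:
                    return True
        return False

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(200):
            proteins = [
                "".join(rng.choice(list(AA), int(rng.integers(20, 70))))
                for _ in range(3)
            ]
            if trial % 3 == 0:  # plant a near-match to balance outcomes
                base = proteins[0]
                i = int(rng.integers(0, len(base) - 10))
                pep = list(base[i : i + 10])
                for _ in range(int(rng.integers(0, 3))):
                    j = int(rng.integers(0, 10))
                    pep[j] = AA[int(rng.integers(0, 20))]
                pep = "".join(pep)
            else:
                pep = "".join(rng.choice(list(AA), int(rng.integers(6, 25))))
            got, _ = one_mismatch_filter(pep, [_entry(p) for p in proteins])
            assert got == self.brute_force_oracle(pep, proteins)


class TestPtmScreen:
    # PEPTIDER is a tryptic product here (R followed by G cleaves)
    PROTEOME = [_entry("PEPTIDERGGGKAAAWW")]

    def _index(self):
        return KnownPeptideMassIndex(self.PROTEOME, missed_cleavages=0, min_len=6)

    def test_phospho_shift_flagged(self):
        mass = peptide_mono_mass("PEPTIDER") + 79.9663
        g = _group("QQQQQWY", mass=mass)
        assert ptm_mass_screen(g, self._index(), tol=0.01)

    def test_no_match_not_flagged(self):
        g = _group("QQQQQWY", mass=5000.0)
        assert not ptm_mass_screen(g, self._index(), tol=0.01)

    def test_unmodified_mass_match_flagged(self):
        g = _group("QQQQQWY", mass=peptide_mono_mass("PEPTIDER"))
        assert ptm_mass_screen(g, self._index(), tol=0.01)

    def test_exclusion_list_overrides_masses(self):
        g = _group("QQQQQWY", mass=5000.0)
        assert ptm_mass_screen(
            g, self._index(), tol=0.01, exclusion_list={"QQQQQWY"}
        )

    def test_missing_precursor_mass_errors(self):
        g = _group("QQQQQWY", mass=float("nan"))
        with pytest.raises(ValueError, match="precursor mass"):
            ptm_mass_screen(g, self._index())


class TestSpectralCount:
    def test_single_spectrum_flagged(self):
        assert spectral_count_filter(_group("AAAAAK", n_psms=1))

    def test_two_spectra_kept(self):
        assert not spectral_count_filter(_group("AAAAAK", n_psms=2))

    def test_min_one_disables(self):
        assert not spectral_count_filter(_group("AAAAAK", n_psms=1), min_spectra=1)


class TestCascade:
    PROTEOME = [_entry("MAAAKPEPTIDERGGGKWWWWYYYY")]

    def test_flags_evaluated_independently(self):
        # internal substring, single spectrum: both flags present
        g = _group("PEPTIDER", n_psms=1)
        verdicts, venn = run_cascade([g], self.PROTEOME)
        assert {"substring", "one_mismatch", "low_spectra"} <= verdicts[0].flags
        assert verdicts[0].final == "removed"

    def test_clean_peptide_is_fnp(self):
        g = _group("QQQNNNCCC", n_psms=3, mass=12345.0)
        verdicts, _ = run_cascade([g], self.PROTEOME)
        assert verdicts[0].final == "FNP" and not verdicts[0].flags

    def test_empty_input(self):
        verdicts, venn = run_cascade([], self.PROTEOME)
        assert verdicts == [] and len(venn) == 0

    def test_venn_counts_sum_to_input(self):
        groups = [
            _group("PEPTIDER", n_psms=1),
            _group("QQQNNNCCC", n_psms=3, mass=12345.0),
            _group("HHHHHHWW", n_psms=1, mass=23456.0),
        ]
        _, venn = run_cascade(groups, self.PROTEOME)
        assert venn["peptides"].sum() == 3

    def test_order_independence(self, bundle):
        """Evaluating PNPs in any order yields identical verdicts."""
        from splicepept.psm_processing import assign_q_values, threshold_and_group

        psms = assign_q_values(list(bundle.psms))
        cats = {e.accession: e.category for e in bundle.db_entries}
        pnps = [
            g for g in threshold_and_group(psms, cats) if g.status == "PNP"
        ]
        proteome = [
            e for e in bundle.db_entries if e.category in ("official", "contaminant")
        ]
        fwd, _ = run_cascade(pnps, proteome, exclusion_list=set(bundle.exclusion_list))
        rev, _ = run_cascade(
            pnps[::-1], proteome, exclusion_list=set(bundle.exclusion_list)
        )
        assert {v.peptide: frozenset(v.flags) for v in fwd} == {
            v.peptide: frozenset(v.flags) for v in rev
        }
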