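"""Splice-aware peptide placement and locus classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from splicepept._util import revcomp
from splicepept.annotation_events import AnnotationSet, TranscriptModel
from splicepept.io_formats import GenomeSequence, read_probed, write_probed
from splicepept.peptide_genome_map import (
    GenomicPeptide,
    all_placements,
    classify_locus,
    classify_mapping,
    locate_peptide,
    to_probed,
)


def spliced_translation(genome, gp):
    """Round-trip oracle: extract blocks, splice, orient, translate."""
    seq = "".join(genome.sequence(gp.chrom, s, e) for s, e in gp.blocks)
    if gp.strand == "-":
        seq = revcomp(seq)
    return str(Seq(seq).translate())


@pytest.fixture
def plus_entry():
    """Single-exon novel entry in frame +0 starting at genomic 1000."""
    from splicepept.orf_database import DbEntry, Provenance

    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    pad = "".join(bases[rng.integers(0, 4, 1000)])
    coding = "ATG" + "GCTTGTGATGAGTTTGGTCATATTAAGCTGATGAATCCGCAGAGGAGTACT" * 2
    coding = coding[: 3 * (len(coding) // 3)]
    genome = GenomeSequence({"chr1": pad + coding + pad})
    protein = str(Seq(coding).translate())
    assert "*" not in protein
    entry = DbEntry(
        "NOV|NT:x|+0", protein, "novel",
        [Provenance("NT:x", "chr1", "+", ((1000, 1000 + len(coding)),),
                    "+0", 0, len(coding))],
    )
    return genome, entry


class TestLocatePeptide:
    def test_plus_strand_offset_arithmetic(self, plus_entry):
        genome, entry = plus_entry
        pep = entry.sequence[4:11]  # protein offset 4, length 7
        gps = locate_peptide(pep, entry)
        assert gps[0].blocks == [(1012, 1033)]
        assert spliced_translation(genome, gps[0]) == pep

    def test_not_a_substring_errors(self, plus_entry):
        _, entry = plus_entry
        with pytest.raises(ValueError, match="not found"):
            locate_peptide("WWWWWWWW", entry)

    def test_block_lengths_always_three_per_residue(self, plus_entry):
        _, entry = plus_entry
        gp = locate_peptide(entry.sequence[:6], entry)[0]
        assert sum(e - s for s, e in gp.blocks) == 18


class TestFixtureRoundTrip:
    def test_every_novel_entry_round_trips(self, bundle):
        """Full-sequence and random-substring placements reproduce the
        peptide by genomic extraction + translation, both strands."""
        rng = np.random.default_rng(23)
        checked_minus = checked_junction = 0
        for entry in bundle.db_entries:
            if entry.category != "novel":
                continue
            for gps, pep in self._sample_peptides(entry, rng):
                for gp in gps:
                    assert spliced_translation(bundle.genome, gp) == pep
                    if gp.strand == "-":
                        checked_minus += 1
                    if len(gp.blocks) > 1:
                        checked_junction += 1
        assert checked_minus > 0, "fixture must exercise minus-strand entries"
        assert checked_junction > 0, "fixture must exercise junction-spanning"

    @staticmethod
    def _sample_peptides(entry, rng):
        peps = {entry.sequence}
        for _ in range(3):
            if len(entry.sequence) > 10:
                i = int(rng.integers(0, len(entry.sequence) - 8))
                peps.add(entry.sequence[i : i + 8])
        return [(locate_peptide(p, entry), p) for p in peps]

    def test_fnp_probed_round_trip(self, pipeline_result, tmp_path):
        placements = [
            gp for pls in pipeline_result.context["placements"].values() for gp in pls
        ]
        records = [to_probed(gp) for gp in placements]
        path = tmp_path / "rt.probed"
        write_probed(sorted(records, key=lambda r: (r.chrom, r.chrom_start)), path)
        back = read_probed(path)
        assert sorted(tuple(r.blocks) for r in back) == sorted(
            tuple(gp.blocks) for gp in placements
        )


class TestClassifyMapping:
    def _gp(self, chrom="chr1", start=0, pep="AAAAAA"):
        return GenomicPeptide(pep, chrom, "+", [(start, start + 18)])

    def test_single_placement_unique(self):
        assert classify_mapping([self._gp()]) == "unique"

    def test_identical_placements_unique(self):
        assert classify_mapping([self._gp(), self._gp()]) == "unique"

    def test_two_chromosomes_multi(self):
        assert classify_mapping([self._gp("chr1"), self._gp("chr2")]) == "multi"

    def test_duplicate_entries_deduplicated_by_all_placements(self, bundle):
        novel = [e for e in bundle.db_entries if e.category == "novel"]
        entry = novel[0]
        pep = entry.sequence[:8]
        pls = all_placements(pep, novel)
        keys = [gp.placement_key() for gp in pls]
        assert len(keys) == len(set(keys))


class TestClassifyLocus:
    @pytest.fixture
    def official(self):
        return AnnotationSet(
            transcripts=[
                TranscriptModel("t1", "chr1", "+", [(1000, 1200), (1800, 2000)], "g1")
            ]
        )

    def test_intronic_is_intragenic(self, official):
        gp = GenomicPeptide("AAAAAA", "chr1", "+", [(1400, 1418)])
        assert classify_locus(gp, official) == "intragenic"

    def test_distant_is_intergenic(self, official):
        gp = GenomicPeptide("AAAAAA", "chr1", "+", [(12000, 12018)])
        assert classify_locus(gp, official) == "intergenic"

    def test_antisense_is_intragenic(self, official):
        gp = GenomicPeptide("AAAAAA", "chr1", "-", [(1100, 1118)])
        assert classify_locus(gp, official) == "intragenic"

    def test_against_brute_force_overlap_oracle(self, official):
        spans = [(c, s, e) for c, s, e in official.gene_spans().values()]
        rng = np.random.default_rng(9)
        for _ in range(200):
            start = int(rng.integers(0, 3000))
            gp = GenomicPeptide(
                "AAAAAA", "chr1", "+" if rng.random() < 0.5 else "-",
                [(start, start + 18)],
            )
            oracle = any(
                c == gp.chrom and start < e and s < start + 18 for c, s, e in spans
            )
            got = classify_locus(gp, official)
            assert (got == "intragenic") == oracle
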