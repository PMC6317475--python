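"""100-bp event clustering, FNP attachment and the count table."""

import numpy as np
import pytest

from splicepept.annotation_events import AnnotationSet, NovelEvent, TranscriptModel
from splicepept.event_clustering import attach_and_classify, cluster_report, merge_events
from splicepept.peptide_genome_map import GenomicPeptide


def _nj(chrom, start, end, strand="+", name=None):
    return NovelEvent(
        name or f"NJ:{chrom}:{start}-{end}:{strand}", "NJ", chrom, strand,
        intron=(start, end),
    )


def _nt(chrom, exons, strand="+", name=None):
    return NovelEvent(
        name or f"NT:{chrom}:{exons[0][0]}-{exons[-1][1]}:{strand}", "NT",
        chrom, strand, exons=exons,
    )


class TestMerge:
    def test_gap_exactly_100_merges(self):
        clusters = merge_events([_nj("chr1", 0, 100), _nj("chr1", 200, 300)])
        assert len(clusters) == 1
        assert clusters[0].span == (0, 300)

    def test_gap_101_splits(self):
        clusters = merge_events([_nj("chr1", 0, 100), _nj("chr1", 201, 300)])
        assert len(clusters) == 2

    def test_chromosomes_never_merge(self):
        clusters = merge_events([_nj("chr1", 0, 100), _nj("chr2", 0, 100)])
        assert len(clusters) == 2

    @staticmethod
    def transitive_closure_oracle(spans, max_gap=100):
        """O(n^2) union-find over the pairwise 'within gap' relation."""
        n = len(spans)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                (s1, e1), (s2, e2) = spans[i], spans[j]
                gap = max(s1, s2) - min(e1, e2)
                if gap <= max_gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(spans[i])
        return sorted(
            (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
        )

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            spans = [
                (int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 3000, 50), rng.integers(1, 400, 50))
            ]
            events = [_nj("chr1", s, e, name=f"e{i}") for i, (s, e) in enumerate(spans)]
            got = sorted(c.span for c in merge_events(events))
            assert got == self.transitive_closure_oracle(spans)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(21)
        spans = [(int(s), int(s) + 50) for s in rng.integers(0, 2000, 30)]
        events = [_nj("chr1", s, e, name=f"e{i}") for i, (s, e) in enumerate(spans)]
        base = [c.span for c in merge_events(events)]
        for _ in range(5):
            perm = [events[i] for i in rng.permutation(len(events))]
            assert [c.span for c in merge_events(perm)] == base

    def test_every_event_in_exactly_one_cluster_separated(self):
        rng = np.random.default_rng(2)
        events = [
            _nj("chr1", int(s), int(s) + 60, name=f"e{i}")
            for i, s in enumerate(rng.integers(0, 5000, 40))
        ]
        clusters = merge_events(events)
        assert sum(len(c.members) for c in clusters) == len(events)
        for a, b in zip(clusters, clusters[1:]):
            assert b.span[0] - a.span[1] > 100


class TestAttachAndClassify:
    @pytest.fixture
    def official(self):
        return AnnotationSet(
            transcripts=[TranscriptModel("t", "chr1", "+", [(0, 500)], "g1")]
        )

    def test_mixed_cluster_is_nt_cluster(self, official):
        events = [_nt("chr1", [(100, 160), (200, 260)]), _nj("chr1", 170, 190),
                  _nj("chr1", 260, 280)]
        clusters = attach_and_classify(merge_events(events), [], official)
        assert clusters[0].kind == "NT-cluster"

    def test_nj_only_cluster(self, official):
        clusters = attach_and_classify(
            merge_events([_nj("chr1", 100, 200)]), [], official
        )
        assert clusters[0].kind == "NJ-cluster"

    def test_removing_nts_reclassifies(self, official):
        events = [_nt("chr1", [(100, 260)]), _nj("chr1", 270, 290)]
        clusters = attach_and_classify(merge_events(events), [], official)
        assert clusters[0].kind == "NT-cluster"
        nj_only = [e for e in events if e.kind == "NJ"]
        reclusters = attach_and_classify(merge_events(nj_only), [], official)
        assert reclusters[0].kind == "NJ-cluster"

    def test_intergenic_cluster_novel_gene_candidate(self, official):
        clusters = attach_and_classify(
            merge_events([_nt("chr1", [(9000, 9300)])]), [], official
        )
        assert clusters[0].kind == "NT-cluster" and clusters[0].locus == "intergenic"

    def test_fnp_attachment_and_uncovered_event_error(self, official):
        ev = _nt("chr1", [(9000, 9300)], name="NT:a")
        clusters = merge_events([ev])
        gp = GenomicPeptide(
            "AAAAAA", "chr1", "+", [(9000, 9018)], mapping_class="unique",
            source_events=("NT:a",),
        )
        attach_and_classify(clusters, [gp], official)
        assert clusters[0].fnps == ["AAAAAA"]
        orphan = GenomicPeptide(
            "CCCCCC", "chr1", "+", [(9000, 9018)], mapping_class="unique",
            source_events=("NT:missing",),
        )
        with pytest.raises(ValueError, match="not in any cluster"):
            attach_and_classify(clusters, [orphan], official)


class TestClusterReport:
    def _gp(self, pep, locus, mapping="unique"):
        gp = GenomicPeptide(pep, "chr1", "+", [(0, 3 * len(pep))])
        gp.locus_class = locus
        gp.mapping_class = mapping
        return gp

    def test_totals_are_row_sums(self, bundle, pipeline_result):
        table = pipeline_result.context["cluster_table"]
        for row in table.index:
            assert (
                table.loc[row, "total"]
                == table.loc[row, "intergenic"] + table.loc[row, "intragenic"]
            )

    def test_zero_clusters_all_zero(self):
        table = cluster_report([], [])
        assert (table.to_numpy() == 0).all()

    def test_nt_row_counts_fnp_bearing_clusters(self):
        official = AnnotationSet(
            transcripts=[TranscriptModel("t", "chr1", "+", [(0, 100)], "g")]
        )
        events = [
            _nt("chr1", [(2000 + 1000 * i, 2300 + 1000 * i)], name=f"NT:{i}")
            for i in range(3)
        ]
        clusters = merge_events(events)
        gps = [
            self._gp("AAAAAA", "intergenic"),
            self._gp("CCCCCC", "intergenic"),
        ]
        gps[0].source_events = ("NT:0",)
        gps[1].source_events = ("NT:1",)
        attach_and_classify(clusters, gps, official)
        table = cluster_report(clusters, gps)
        # third cluster has no FNP: excluded from the cluster rows
        assert table.loc["NT_clusters", "total"] == 2
        assert table.loc["unique_mapping_FNPs", "total"] == 2
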