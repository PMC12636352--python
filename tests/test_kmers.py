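import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kprob._encode import code_to_kmer, kmer_codes
from kprob.kmers import (build_count_matrix, cluster_kmers, enumerate_kmers,
                         kmer_count_dict, order_kmers)
from kprob.pan_io import ExpressionTable, PromoterRecord, PromoterSet

from _oracles import greedy_cluster_reference


def _ps(seqs):
    return PromoterSet([
        PromoterRecord(f"pan{i % 2}", f"acc{i}", f"g{i:03d}", s)
        for i, s in enumerate(seqs)])


class TestEnumerate:
    @pytest.mark.parametrize("seq,k,expected", [
        ("AAAAA", 4, {"AAAA": 2}),
        ("AANAA", 2, {"AA": 2}),
        ("ACGT", 4, {"ACGT": 1}),
    ])
    def test_counts(self, seq, k, expected):
        idx = enumerate_kmers(_ps([seq]), k)
        assert kmer_count_dict(idx) == expected

    def test_k_larger_than_all_promoters(self):
        with pytest.raises(ValueError):
            enumerate_kmers(_ps(["ACG", "TGA"]), 5)

    def test_positions_retained(self):
        idx = enumerate_kmers(_ps(["AAAAT"]), 4)
        code = kmer_codes("AAAA", 4)[0]
        assert list(idx.occurrence_offsets(0, np.array([code]))) == [0]


class TestOrdering:
    def test_count_then_lexicographic(self):
        kmers = ["AAAT", "TTTT", "AAAA"]
        codes = np.array([kmer_codes(s, 4)[0] for s in kmers])
        counts = np.array([3, 5, 5])
        order = order_kmers(codes, counts)
        assert [kmers[i] for i in order] == ["AAAA", "TTTT", "AAAT"]

    def test_pure_lexicographic_on_ties(self):
        kmers = ["TT", "AC", "GA"]
        codes = np.array([kmer_codes(s, 2)[0] for s in kmers])
        order = order_kmers(codes, np.ones(3))
        assert [kmers[i] for i in order] == ["AC", "GA", "TT"]


class TestClustering:
    def _cluster(self, ordered_kmers):
        k = len(ordered_kmers[0])
        codes = np.array([kmer_codes(s, k)[0] for s in ordered_kmers])
        return cluster_kmers(codes, k=k)

    def test_hamming_one_joins(self):
        cs = self._cluster(["AAAA", "TTTT", "AAAT"])
        assert cs.n_clusters == 2
        assert cs.members(0) == {"AAAA": 1, "AAAT": 1}
        assert cs.representative(1) == "TTTT"

    def test_hamming_two_separates(self):
        assert self._cluster(["AAAA", "AATT"]).n_clusters == 2

    def test_representative_only_comparison(self):
        # AATT is d=2 from rep AAAA even though d=1 from member AAAT
        cs = self._cluster(["AAAA", "AAAT", "AATT"])
        assert cs.n_clusters == 2
        assert cs.members(1) == {"AATT": 1}

    def test_partition_property(self):
        cs = self._cluster(["ACGT", "ACGA", "TCGA", "GGGG", "GGGT"])
        assert np.sort(np.unique(cs.assign)).tolist() == \
            list(range(cs.n_clusters))
        sizes = [len(cs.members(i)) for i in range(cs.n_clusters)]
        assert sum(sizes) == 5

    @given(st.lists(st.text(alphabet="ACGT", min_size=5, max_size=5),
                    min_size=1, max_size=40, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_matches_string_reference(self, kmers):
        cs = self._cluster(kmers)
        ref_assign, ref_reps = greedy_cluster_reference(kmers)
        assert cs.assign.tolist() == ref_assign
        assert [cs.representative(i) for i in range(cs.n_clusters)] == ref_reps

    def test_determinism_and_input_order_invariance(self, small_fixture):
        promoters, _, _ = small_fixture
        idx1 = enumerate_kmers(promoters, 8)
        shuffled = PromoterSet(
            sorted(promoters, key=lambda r: r.sequence))
        idx2 = enumerate_kmers(shuffled, 8)
        c1, c2 = cluster_kmers(idx1), cluster_kmers(idx2)
        assert np.array_equal(c1.codes, c2.codes)
        assert np.array_equal(c1.assign, c2.assign)


class TestCountMatrix:
    def _matrix(self, seqs, values, k=4, **kw):
        ps = _ps(seqs)
        expr = ExpressionTable({f"g{i:03d}": v for i, v in enumerate(values)})
        idx = enumerate_kmers(ps, k)
        clusters = cluster_kmers(idx)
        return build_count_matrix(clusters, idx, expr, **kw), clusters

    def test_overlapping_member_occurrences_summed(self):
        # cluster {AAAA, AAAT}: "AAAAAT" holds AAAA twice (overlap) + AAAT once
        m, cs = self._matrix(["AAAAAT", "AAAA", "AAAT", "CCCC"],
                             [1.0, 2.0, 3.0, 4.0], min_prevalence=0.0)
        col = [c for c in range(m.p)
               if set(cs.members(int(m.cluster_ids[c]))) >= {"AAAA", "AAAT"}]
        x = m.X[:, col[0]].toarray().ravel()
        assert x[m.gene_ids.index("g000")] == 3  # 2 + 1 overlapping windows

    def test_prevalence_strictly_greater(self):
        seqs = ["AAAA"] + ["CCCC"] * 199
        m, cs = self._matrix(seqs, np.arange(200.0), min_prevalence=0.01)
        # AAAA present in 1/200 = 0.005 <= 0.01 -> dropped
        reps = {cs.representative(int(c)) for c in m.cluster_ids}
        assert "AAAA" not in reps
        seqs = ["AAAA"] * 3 + ["CCCC"] * 197
        m, cs = self._matrix(seqs, np.arange(200.0), min_prevalence=0.01)
        reps = {cs.representative(int(c)) for c in m.cluster_ids}
        assert "AAAA" in reps  # 0.015 > 0.01 -> retained

    def test_missing_expression_drops_row(self):
        ps = _ps(["ACGT", "ACGG", "TTTT"])
        expr = ExpressionTable({"g000": 1.0, "g001": 2.0})
        idx = enumerate_kmers(ps, 4)
        clusters = cluster_kmers(idx)
        with pytest.warns(UserWarning, match="without expression"):
            m = build_count_matrix(clusters, idx, expr, min_prevalence=0.0)
        assert m.n == 2 and "g002" not in m.gene_ids

    def test_column_sums_equal_total_occurrences(self, small_fixture):
        promoters, expression, _ = small_fixture
        idx = enumerate_kmers(promoters, 8)
        clusters = cluster_kmers(idx)
        m = build_count_matrix(clusters, idx, expression, min_prevalence=0.0)
        col_sums = np.asarray(m.X.sum(axis=0)).ravel()
        for col in [0, m.p // 2, m.p - 1]:
            members = clusters.member_codes(int(m.cluster_ids[col]))
            total = sum(int((idx.codes == c).sum()) for c in members)
            assert col_sums[col] == total

    def test_pangene_covariates_one_hot(self):
        m, _ = self._matrix(["ACGT", "ACGG", "TTTT", "TTTA"],
                            [1, 2, 3, 4.0], covariates="pangene",
                            min_prevalence=0.0)
        assert m.C.shape == (4, 2)
        assert np.allclose(m.C.sum(axis=1), 1.0)
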