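import numpy as np
import pytest

from kprob._encode import kmer_codes, revcomp
from kprob.kmers import cluster_kmers, enumerate_kmers
from kprob.motifs import (PositionWeightMatrix, cluster_pwm,
                          cluster_matches_library, occurrence_positions,
                          overlap_fractions, peak_overlap_enrichment,
                          permutation_enrichment, pwm_threshold, read_meme,
                          scan_kmer, write_meme)
from kprob.pan_io import GenomicInterval, PromoterRecord, PromoterSet

from _oracles import brute_force_tail


def sharp_pwm(consensus, p=0.97, motif_id="m"):
    w = len(consensus)
    probs = np.full((4, w), (1 - p) / 3)
    for i, ch in enumerate(consensus):
        probs["ACGT".index(ch), i] = p
    return PositionWeightMatrix(motif_id, probs)


class TestClusterPwm:
    def test_single_member_one_hot(self):
        pwm = cluster_pwm({"ACGT": 10})
        assert pwm.consensus() == "ACGT"
        assert pwm.probs[0, 0] > 0.99

    def test_equal_weights(self):
        pwm = cluster_pwm({"AAAA": 1, "AAAT": 1})
        assert pwm.probs[0, 3] == pytest.approx(0.5, abs=0.02)
        assert pwm.probs[3, 3] == pytest.approx(0.5, abs=0.02)

    def test_weighted_counts(self):
        pwm = cluster_pwm({"AAAA": 3, "AAAT": 1})
        assert pwm.probs[0, 3] == pytest.approx(0.75, abs=0.02)
        assert pwm.probs[3, 3] == pytest.approx(0.25, abs=0.02)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_pwm({})


class TestThreshold:
    @pytest.mark.parametrize("width", [2, 3, 5])
    def test_tail_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        probs = rng.dirichlet(np.ones(4) * 2, size=width).T
        bg = rng.dirichlet(np.ones(4) * 5)
        pwm = PositionWeightMatrix("t", probs, bg)
        thr = pwm_threshold(pwm, 1e-3)
        oracle = brute_force_tail(thr.int_scores, bg)
        assert np.allclose(thr.tail, oracle, atol=1e-12)

    def test_p_target_one_accepts_everything(self):
        thr = pwm_threshold(sharp_pwm("ACGT"), 1.0)
        assert thr.int_threshold == 0

    def test_degenerate_pwm_step_tail(self):
        pwm = PositionWeightMatrix("flat", np.full((4, 3), 0.25))
        thr = pwm_threshold(pwm, 0.5)
        assert thr.tail[0] == pytest.approx(1.0)


class TestScan:
    def test_consensus_matches(self):
        pwm = sharp_pwm("ACGTACGTACG")
        thr = pwm_threshold(pwm, 1e-4)
        assert scan_kmer(thr, "ACGTACGTACG")[0]

    def test_reverse_complement_matches(self):
        pwm = sharp_pwm("AACCGGTTACG")
        thr = pwm_threshold(pwm, 1e-4)
        assert scan_kmer(thr, revcomp("AACCGGTTACG"))[0]

    def test_non_acgt_never_matches(self):
        thr = pwm_threshold(sharp_pwm("ACGT"), 1.0)
        assert not scan_kmer(thr, "ACNT")[0]

    def test_match_rate_approximates_p_target(self):
        pwm = sharp_pwm("ACGTACGTACG")
        thr = pwm_threshold(pwm, 1e-2)
        rng = np.random.default_rng(0)
        n = 3000
        hits = 0
        for _ in range(n):
            kmer = "".join("ACGT"[i] for i in rng.integers(0, 4, pwm.width))
            hits += scan_kmer(thr, kmer)[0]
        # two strands + 1 offset -> rate close to 2 * p_target
        assert hits / n < 6e-2 and hits / n > 1e-3

    def test_shorter_kmer_scans_sub_windows(self):
        pwm = sharp_pwm("AACCGGTTACG")
        thr = pwm_threshold(pwm, 1e-3)
        cache = {}
        assert scan_kmer(thr, "AACCGGTT", _sub_cache=cache)[0]
        assert cache  # sub-window thresholds were built


class TestPermutation:
    def _clusters(self):
        kmers = ["ACGTACGTACG", "TTTTTTTTTTT", "GGGGGGGGGGG", "CACACACACAC",
                 "TGCATGCATGC", "AAAAAAAAAAA"]
        codes = np.array([kmer_codes(s, 11)[0] for s in kmers])
        return cluster_kmers(codes, k=11)

    def test_only_planted_cluster_matches(self):
        cs = self._clusters()
        library = [sharp_pwm("ACGTACGTACG")]
        matched = cluster_matches_library(cs, list(range(6)), library)
        assert matched.tolist() == [True, False, False, False, False, False]

    def test_planted_library_minimal_p(self):
        # 4 matched clusters among 60, all selected: a null draw of 4 almost
        # never contains all of them, so p bottoms out at 1/(n_iter+1)
        matched = np.zeros(60, dtype=bool)
        matched[:4] = True
        res = permutation_enrichment(list(range(4)), list(range(60)),
                                     None, [], matched=matched,
                                     n_iter=999, seed=1)
        assert res.observed == 4
        assert res.p_empirical == pytest.approx(1 / 1000)
        assert res.fold > 10

    def test_sig_equals_all(self):
        cs = self._clusters()
        library = [sharp_pwm("ACGTACGTACG")]
        res = permutation_enrichment(list(range(6)), list(range(6)), cs,
                                     library, n_iter=500, seed=2)
        assert res.fold == pytest.approx(1.0)
        assert res.p_empirical > 0.5

    def test_library_matching_nothing(self):
        cs = self._clusters()
        matched = np.zeros(6, dtype=bool)
        res = permutation_enrichment([0, 1], list(range(6)), cs, [],
                                     matched=matched, n_iter=200, seed=3)
        assert res.observed == 0 and res.p_empirical == 1.0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            permutation_enrichment([0], [0], self._clusters(), [])


class TestOccurrencesAndPeaks:
    def _indexed(self):
        seq = "A" * 10 + "ACGTACGTACG" + "A" * 10
        # g2 stores the same oriented sequence but maps to the - strand:
        # its genomic window holds the reverse complement
        ps = PromoterSet([
            PromoterRecord("p", "a", "g1", seq,
                           GenomicInterval("c", 1000, 1000 + len(seq), "+")),
            PromoterRecord("p", "a", "g2", seq,
                           GenomicInterval("c", 2000, 2000 + len(seq), "-")),
        ])
        idx = enumerate_kmers(ps, 11)
        codes, counts = idx.unique_counts()
        clusters = cluster_kmers(idx)
        return ps, idx, clusters

    def test_plus_strand_arithmetic(self):
        ps, idx, clusters = self._indexed()
        table = clusters.cluster_of_code_table()
        cl = int(table[kmer_codes("ACGTACGTACG", 11)[0]])
        occ = occurrence_positions(clusters, [cl], idx)
        plus = occ[occ["gene_id"] == "g1"]
        assert (plus["start"] == 1010).any() and (plus["end"] == 1021).any()

    def test_minus_strand_mirrored(self):
        ps, idx, clusters = self._indexed()
        table = clusters.cluster_of_code_table()
        cl = int(table[kmer_codes("ACGTACGTACG", 11)[0]])
        occ = occurrence_positions(clusters, [cl], idx)
        minus = occ[occ["gene_id"] == "g2"]
        # oriented offset 10 -> genomic [end-10-11, end-10) = [2010, 2021)
        assert ((minus["start"] == 2010) & (minus["end"] == 2021)).any()

    def test_half_open_adjacency(self):
        occ = overlap_fractions(
            __import__("pandas").DataFrame(
                [{"cluster_id": 0, "gene_id": "g", "contig": "c",
                  "start": 10, "end": 21},
                 {"cluster_id": 1, "gene_id": "g", "contig": "c",
                  "start": 10, "end": 20}]),
            [GenomicInterval("c", 20, 30)])
        frac = occ.set_index("cluster_id")["fraction"]
        assert frac[0] == 1.0 and frac[1] == 0.0

    def test_constructed_fold(self):
        import pandas as pd
        rows = []
        # 4 "sig" clusters always in peaks; 8 background, half in peaks
        for cl in range(4):
            rows.append({"cluster_id": cl, "gene_id": "g", "contig": "c",
                         "start": 100, "end": 111})
        for cl in range(4, 12):
            inside = cl % 2 == 0
            rows.append({"cluster_id": cl, "gene_id": "g", "contig": "c",
                         "start": 100 if inside else 500, "end":
                         111 if inside else 511})
        occ = pd.DataFrame(rows)
        peaks = [GenomicInterval("c", 90, 120)]
        res = peak_overlap_enrichment(list(range(4)), list(range(12)), occ,
                                      peaks, n_boot=200, seed=1)
        assert res.fold == pytest.approx(1.0 / res.null_mean)

    def test_merging_peaks_never_decreases_fraction(self):
        import pandas as pd
        occ = pd.DataFrame([{"cluster_id": 0, "gene_id": "g", "contig": "c",
                             "start": s, "end": s + 11} for s in range(0, 100, 7)])
        split = [GenomicInterval("c", 10, 30), GenomicInterval("c", 30, 60)]
        merged = [GenomicInterval("c", 10, 60)]
        f_split = overlap_fractions(occ, split)["fraction"][0]
        f_merged = overlap_fractions(occ, merged)["fraction"][0]
        assert f_merged >= f_split


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        motifs = [sharp_pwm("ACGTACG", motif_id="m1"),
                  sharp_pwm("TTGACA", motif_id="m2")]
        path = tmp_path / "lib.meme"
        write_meme(motifs, path)
        back = read_meme(path)
        assert [m.motif_id for m in back] == ["m1", "m2"]
        assert np.allclose(back[0].probs, motifs[0].probs, atol=1e-5)
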