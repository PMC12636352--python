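"""Motif enrichment of significant k-mer clusters and peak-overlap analysis.

Contains a cluster -> position-weight-matrix builder, an exact-p-value PWM
scanner (the null distribution of the discretized log-odds score of a random
word under the background is computed by dynamic programming, FIMO-style),
a permutation test for TF-binding-motif enrichment of the selected clusters,
and occurrence-in-peak enrichment against interval sets (ATAC/DAP-seq style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._encode import revcomp, seq_to_base_codes
from .kmers import KmerClusterSet, PromoterKmerIndex
from .pan_io import GenomicInterval

BASES = "ACGT"


@dataclass
class PositionWeightMatrix:
    """4 x w base probabilities with a 0-order background."""

    motif_id: str
    probs: np.ndarray                       # shape (4, w), columns sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def log_odds(self) -> np.ndarray:
        return np.log(self.probs / self.background[:, None])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


def cluster_pwm(cluster_members: dict[str, int], motif_id: str = "cluster",
                pseudocount: float = 0.01,
                background: np.ndarray | None = None) -> PositionWeightMatrix:
    """PWM from a cluster's member k-mers weighted by pan-genome frequency."""
    if not cluster_members:
        raise ValueError("empty cluster")
    total = sum(cluster_members.values())
    if total <= 0:
        raise ValueError("zero total member frequency")
    width = len(next(iter(cluster_members)))
    counts = np.full((4, width), pseudocount, dtype=float)
    for kmer, freq in cluster_members.items():
        codes = seq_to_base_codes(kmer)
        for pos, b in enumerate(codes):
            if b == 255:
                raise ValueError(f"non-ACGT member k-mer {kmer!r}")
            counts[b, pos] += freq
    probs = counts / counts.sum(axis=0, keepdims=True)
    bg = background if background is not None else np.full(4, 0.25)
    return PositionWeightMatrix(motif_id, probs, bg)


@dataclass
class ScoreThreshold:
    """Exact null distribution of the discretized PWM log-odds score.

    Scores are mapped to integer bins (bin width = score range / n_bins,
    per-column minimum shifted to 0); the null pmf over the total integer
    score of a random width-w word under the background is built by
    convolving the per-position score histograms. The threshold is the
    smallest integer score whose tail probability is <= p_target.
    """

    pwm: PositionWeightMatrix
    p_target: float
    n_bins: int
    bin_width: float
    col_min: np.ndarray            # per-column real-score shift
    int_scores: np.ndarray         # (4, w) integer scores after shift
    tail: np.ndarray               # tail[t] = P(int score >= t) under background
    int_threshold: int

    @property
    def threshold(self) -> float:
        """Threshold on the real log-odds scale."""
        return float(self.col_min.sum() + self.int_threshold * self.bin_width)

    def int_score(self, kmer: str, offset: int = 0) -> int:
        codes = seq_to_base_codes(kmer)
        w = self.pwm.width
        if codes.size - offset < w:
            raise ValueError("window shorter than motif")
        window = codes[offset:offset + w]
        if (window == 255).any():
            return -1
        return int(self.int_scores[window, np.arange(w)].sum())

    def tail_probability(self, int_score: int) -> float:
        if int_score < 0:
            return 1.0
        if int_score >= self.tail.size:
            return 0.0
        return float(self.tail[int_score])


def pwm_threshold(pwm: PositionWeightMatrix, p_target: float = 1e-4,
                  n_bins: int = 10000) -> ScoreThreshold:
    """Exact score threshold at a target p-value, by DP over positions."""
    if not 0 < p_target <= 1:
        raise ValueError("p_target must be in (0, 1]")
    lods = pwm.log_odds()
    col_min = lods.min(axis=0)
    col_max = lods.max(axis=0)
    score_range = float((col_max - col_min).sum())
    bin_width = score_range / n_bins if score_range > 0 else 1.0
    int_scores = np.rint((lods - col_min[None, :]) / bin_width).astype(np.int64)
    max_total = int(int_scores.max(axis=0).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    for pos in range(pwm.width):
        nxt = np.zeros_like(pmf)
        for b in range(4):
            s = int_scores[b, pos]
            w = pwm.background[b]
            if w > 0:
                nxt[s:] += w * pmf[:pmf.size - s if s else pmf.size]
        pmf = nxt
    tail = np.cumsum(pmf[::-1])[::-1]
    passing = np.flatnonzero(tail <= p_target)
    int_thr = int(passing[0]) if passing.size else max_total + 1
    return ScoreThreshold(pwm, p_target, n_bins, bin_width, col_min,
                          int_scores, tail, int_thr)


def scan_kmer(threshold: ScoreThreshold, kmer: str,
              _sub_cache: dict | None = None) -> tuple[bool, float]:
    """Match a k-mer against a PWM at the threshold's significance level.

    Both strands and every alignment of the shorter sequence within the
    longer are scanned. When the k-mer is shorter than the motif, each
    alignment is judged against a threshold recomputed for the overlapping
    motif columns. Returns (matched, best real-scale log-odds score).
    Non-ACGT characters never match.
    """
    pwm = threshold.pwm
    w = pwm.width
    best_int, best_real, matched = -1, -np.inf, False
    for strand_seq in (kmer, revcomp(kmer)):
        if len(strand_seq) >= w:
            for off in range(len(strand_seq) - w + 1):
                s = threshold.int_score(strand_seq, off)
                if s < 0:
                    continue
                if s >= threshold.int_threshold:
                    matched = True
                if s > best_int:
                    best_int = s
                    best_real = threshold.col_min.sum() + s * threshold.bin_width
        else:
            klen = len(strand_seq)
            for off in range(w - klen + 1):
                sub = _sub_threshold(threshold, off, klen, _sub_cache)
                s = sub.int_score(strand_seq, 0)
                if s < 0:
                    continue
                if s >= sub.int_threshold:
                    matched = True
                real = sub.col_min.sum() + s * sub.bin_width
                if real > best_real:
                    best_real = real
    return matched, float(best_real)


def _sub_threshold(threshold: ScoreThreshold, offset: int, width: int,
                   cache: dict | None) -> ScoreThreshold:
    key = (offset, width)
    if cache is not None and key in cache:
        return cache[key]
    sub_pwm = PositionWeightMatrix(
        f"{threshold.pwm.motif_id}[{offset}:{offset + width}]",
        threshold.pwm.probs[:, offset:offset + width],
        threshold.pwm.background)
    sub = pwm_threshold(sub_pwm, threshold.p_target, threshold.n_bins)
    if cache is not None:
        cache[key] = sub
    return sub


def cluster_matches_library(clusters: KmerClusterSet, cluster_ids,
                            library: list[PositionWeightMatrix],
                            p_target: float = 1e-4) -> np.ndarray:
    """Per-cluster flag: does any member k-mer match any library motif?"""
    thresholds = [pwm_threshold(pwm, p_target) for pwm in library]
    caches = [dict() for _ in library]
    out = np.zeros(len(cluster_ids), dtype=bool)
    for i, cl in enumerate(cluster_ids):
        for kmer in clusters.members(int(cl)):
            hit = False
            for thr, cache in zip(thresholds, caches):
                if scan_kmer(thr, kmer, _sub_cache=cache)[0]:
                    hit = True
                    break
            if hit:
                out[i] = True
                break
    return out


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    null_quantiles: dict
    fold: float
    p_empirical: float
    ci: tuple[float, float] | None
    n_iter: int
    seed: int | None


def permutation_enrichment(sig_cluster_ids, all_cluster_ids,
                           clusters: KmerClusterSet,
                           library: list[PositionWeightMatrix],
                           p_target: float = 1e-4,
                           n_iter: int = 10000,
                           seed: int | None = None,
                           matched: np.ndarray | None = None) -> EnrichmentResult:
    """Are the selected clusters enriched for library-motif matches?

    The observed statistic is the number of selected clusters with at least
    one member matching at least one motif. The null redraws |selected|
    clusters uniformly without replacement from the full model set; since
    matching is a fixed per-cluster property, the null count is exactly
    hypergeometric, which is sampled directly.
    """
    if not library and matched is None:
        raise ValueError("empty motif library")
    sig = list(sig_cluster_ids)
    allc = list(all_cluster_ids)
    if len(sig) > len(allc):
        raise ValueError("selected set larger than the model set")
    if matched is None:
        matched = cluster_matches_library(clusters, allc, library, p_target)
    matched = np.asarray(matched, dtype=bool)
    pos = {cl: i for i, cl in enumerate(allc)}
    observed = int(sum(matched[pos[cl]] for cl in sig))
    rng = np.random.default_rng(seed)
    K = int(matched.sum())
    null = rng.hypergeometric(K, len(allc) - K, len(sig), size=n_iter)
    p = (1 + int((null >= observed).sum())) / (1 + n_iter)
    nm = float(null.mean())
    return EnrichmentResult(
        observed=float(observed), null_mean=nm, null_sd=float(null.std(ddof=1)),
        null_quantiles={q: float(np.quantile(null, q)) for q in (0.025, 0.5, 0.975)},
        fold=float(observed / nm) if nm > 0 else np.inf,
        p_empirical=float(p), ci=None, n_iter=n_iter, seed=seed)


# ---------------------------------------------------------------------------
# genomic occurrences and peak overlap


def occurrence_positions(clusters: KmerClusterSet, cluster_ids,
                         index: PromoterKmerIndex) -> pd.DataFrame:
    """Genomic interval of every member-k-mer occurrence of the clusters.

    Promoters without a genomic interval are skipped with a warning. For a
    + strand promoter at [s, e), an occurrence at offset o spans
    [s+o, s+o+k); for a - strand promoter the arithmetic is mirrored because
    the stored sequence is the reverse complement of the genomic window.
    """
    k = clusters.k
    table = clusters.cluster_of_code_table()
    wanted = np.full(clusters.n_clusters, -1, dtype=np.int64)
    for cl in cluster_ids:
        wanted[int(cl)] = int(cl)
    rows = []
    skipped = 0
    for i, rec in enumerate(index.records):
        codes = index.promoter_codes(i)
        valid = codes >= 0
        cl = np.where(valid, table[np.where(valid, codes, 0)], -1)
        hit = np.flatnonzero((cl >= 0) & (wanted[np.maximum(cl, 0)] >= 0))
        if hit.size == 0:
            continue
        if rec.interval is None:
            skipped += 1
            continue
        iv = rec.interval
        for o in hit:
            if iv.strand == "-":
                start, end = iv.end - int(o) - k, iv.end - int(o)
            else:
                start, end = iv.start + int(o), iv.start + int(o) + k
            rows.append({"cluster_id": int(cl[o]), "gene_id": rec.gene_id,
                         "contig": iv.contig, "start": start, "end": end})
    if skipped:
        warnings.warn(f"{skipped} promoters lack intervals; occurrences skipped")
    return pd.DataFrame(rows, columns=["cluster_id", "gene_id", "contig",
                                       "start", "end"])


def overlap_fractions(occurrences: pd.DataFrame,
                      peaks: list[GenomicInterval]) -> pd.DataFrame:
    """Per-cluster fraction of occurrences intersecting >= 1 peak
    (any shared base, half-open semantics)."""
    trees: dict[str, IntervalTree] = {}
    for pk in peaks:
        trees.setdefault(pk.contig, IntervalTree()).addi(pk.start, pk.end)
    if occurrences.empty:
        return pd.DataFrame(columns=["cluster_id", "n_occurrences", "fraction"])
    hits = []
    for row in occurrences.itertuples(index=False):
        tree = trees.get(row.contig)
        hits.append(bool(tree is not None and tree.overlap(row.start, row.end)))
    df = occurrences.assign(in_peak=hits)
    out = df.groupby("cluster_id").agg(
        n_occurrences=("in_peak", "size"), fraction=("in_peak", "mean"))
    return out.reset_index()


def peak_overlap_enrichment(sig_cluster_ids, all_cluster_ids,
                            occurrences: pd.DataFrame,
                            peaks: list[GenomicInterval],
                            bin_threshold: float = 0.20,
                            n_boot: int = 1000,
                            seed: int | None = None) -> EnrichmentResult:
    """High-overlap-bin enrichment of selected vs all model clusters.

    Each cluster's occurrence-in-peak fraction is binned at ``bin_threshold``
    (strictly greater = high bin); the fold is P(selected cluster in high
    bin) / P(model cluster in high bin), with a percentile bootstrap CI that
    resamples clusters within each group. Clusters with zero located
    occurrences are excluded with a warning.
    """
    frac = overlap_fractions(occurrences, peaks).set_index("cluster_id")
    sig = [cl for cl in sig_cluster_ids if cl in frac.index]
    allc = [cl for cl in all_cluster_ids if cl in frac.index]
    dropped = (len(list(sig_cluster_ids)) - len(sig)) + \
              (len(list(all_cluster_ids)) - len(allc))
    if dropped:
        warnings.warn(f"{dropped} clusters with no located occurrences excluded")
    if not sig or not allc:
        raise ValueError("no clusters with located occurrences")
    sig_high = np.array([frac.loc[cl, "fraction"] > bin_threshold for cl in sig])
    all_high = np.array([frac.loc[cl, "fraction"] > bin_threshold for cl in allc])
    base = all_high.mean()
    fold = float(sig_high.mean() / base) if base > 0 else np.inf
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bs = sig_high[rng.integers(0, sig_high.size, sig_high.size)].mean()
        ba = all_high[rng.integers(0, all_high.size, all_high.size)].mean()
        boots.append(bs / ba if ba > 0 else np.nan)
    boots = np.array(boots, dtype=float)
    ok = boots[np.isfinite(boots)]
    ci = (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5))) \
        if ok.size else (np.nan, np.nan)
    return EnrichmentResult(
        observed=float(sig_high.mean()), null_mean=float(base),
        null_sd=float(all_high.std(ddof=1)) if all_high.size > 1 else 0.0,
        null_quantiles={}, fold=fold, p_empirical=np.nan, ci=ci,
        n_iter=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# MEME-format io


def read_meme(path: str | Path) -> list[PositionWeightMatrix]:
    """Read a MEME (minimal) motif file into PWMs."""
    motifs: list[PositionWeightMatrix] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = np.array([float(vals[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(x) for x in lines[i + j].split()])
            probs = np.array(rows).T
            probs = probs / probs.sum(axis=0, keepdims=True)
            motifs.append(PositionWeightMatrix(motif_id, probs, background))
            i += w + 1
            continue
        i += 1
    return motifs


def write_meme(motifs: list[PositionWeightMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 20 E= 0\n")
            for col in pwm.probs.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")
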