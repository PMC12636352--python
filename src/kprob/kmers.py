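"""Promoter k-mer enumeration, ordering, one-mismatch clustering, and the
prevalence-filtered cluster count matrix.

K-mers are enumerated on the forward strand of the oriented promoter with
stride 1 (windows containing N are skipped), ordered by descending pan-genome
abundance with lexicographic tie-break, then greedily clustered: scanning in
that order, a k-mer joins the earliest-founded cluster whose *representative*
is within Hamming distance 1, else founds a new cluster. With equal-length
words and a similarity threshold of 1 - 1/k, identity clustering admits at
most one substitution and no gaps, so this deterministic Hamming-1 scheme
realizes the same rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

from ._encode import code_to_kmer, kmer_codes, revcomp_code
from .pan_io import ExpressionTable, PromoterSet

_MAX_DENSE_K = 13  # dense 4^k lookup tables up to ~268 MB


class PromoterKmerIndex:
    """Per-promoter k-mer codes for a PromoterSet, rows sorted by gene_id.

    Keeps the stride-1 window codes of every promoter (-1 where the window
    contains N), which supports total counts, count-matrix assembly, and
    occurrence-position lookups from one structure.
    """

    def __init__(self, promoters: PromoterSet, k: int,
                 count_revcomp: bool = False):
        self.k = k
        self.count_revcomp = count_revcomp
        ordered = promoters.sorted_by_gene()
        self.gene_ids = ordered.gene_ids
        self.pangene_ids = ordered.pangene_ids()
        self.accession_ids = [r.accession_id for r in ordered]
        self.records = list(ordered)
        chunks, offsets = [], [0]
        for rec in ordered:
            c = kmer_codes(rec.sequence, k)
            if count_revcomp:
                rc = np.array([revcomp_code(x, k) if x >= 0 else -1 for x in c])
                c = np.minimum(c, np.where(c >= 0, rc, -1))
            chunks.append(c)
            offsets.append(offsets[-1] + c.size)
        if not chunks:
            raise ValueError("empty promoter set")
        self.codes = np.concatenate(chunks) if chunks else np.empty(0, np.int64)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        if (self.codes >= 0).sum() == 0:
            raise ValueError(f"k={k} larger than every promoter's valid span")

    @property
    def n_promoters(self) -> int:
        return len(self.gene_ids)

    def promoter_codes(self, i: int) -> np.ndarray:
        return self.codes[self.offsets[i]:self.offsets[i + 1]]

    def unique_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted distinct codes, total pan-genome counts)."""
        valid = self.codes[self.codes >= 0]
        return np.unique(valid, return_counts=True)

    def occurrence_offsets(self, i: int, member_codes: np.ndarray) -> np.ndarray:
        """Window offsets within promoter i whose code is in member_codes."""
        c = self.promoter_codes(i)
        return np.flatnonzero(np.isin(c, member_codes))


def enumerate_kmers(promoters: PromoterSet, k: int,
                    count_revcomp: bool = False) -> PromoterKmerIndex:
    """Build the promoter k-mer index (see PromoterKmerIndex)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return PromoterKmerIndex(promoters, k, count_revcomp=count_revcomp)


def kmer_count_dict(index: PromoterKmerIndex) -> dict[str, int]:
    """Total pan-genome count per k-mer string (convenience for small data)."""
    codes, counts = index.unique_counts()
    return {code_to_kmer(int(c), index.k): int(n) for c, n in zip(codes, counts)}


def order_kmers(codes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Descending count, ties broken by ascending lexicographic order."""
    if codes.size == 0:
        raise ValueError("no k-mers to order")
    idx = np.lexsort((codes, -counts))
    return idx


@njit(cache=True)
def _greedy_cluster_dense(codes, k, table_size):
    """Sequential greedy Hamming-1 assignment using a dense rep -> cluster map."""
    rep_of = np.full(table_size, -1, dtype=np.int64)
    assign = np.empty(codes.shape[0], dtype=np.int64)
    n_clusters = 0
    for i in range(codes.shape[0]):
        c = codes[i]
        best = np.int64(-1)
        for pos in range(k):
            shift = 2 * (k - 1 - pos)
            cur = (c >> shift) & 3
            stripped = c & ~(np.int64(3) << shift)
            for b in range(4):
                if b == cur:
                    continue
                cand = stripped | (np.int64(b) << shift)
                cl = rep_of[cand]
                if cl >= 0 and (best < 0 or cl < best):
                    best = cl
        if best < 0:
            rep_of[c] = n_clusters
            assign[i] = n_clusters
            n_clusters += 1
        else:
            assign[i] = best
    return assign, n_clusters


def _greedy_cluster_dict(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    # reference implementation / fallback for k > _MAX_DENSE_K
    rep_of: dict[int, int] = {}
    assign = np.empty(codes.size, dtype=np.int64)
    n_clusters = 0
    for i, c in enumerate(codes.tolist()):
        best = -1
        for pos in range(k):
            shift = 2 * (k - 1 - pos)
            cur = (c >> shift) & 3
            stripped = c & ~(3 << shift)
            for b in range(4):
                if b == cur:
                    continue
                cl = rep_of.get(stripped | (b << shift), -1)
                if cl >= 0 and (best < 0 or cl < best):
                    best = cl
        if best < 0:
            rep_of[c] = n_clusters
            assign[i] = n_clusters
            n_clusters += 1
        else:
            assign[i] = best
    return assign, n_clusters


@dataclass
class KmerClusterSet:
    """Partition of the ordered unique k-mers into Hamming-1 clusters.

    ``codes``/``counts`` are in clustering (priority) order; ``assign[i]`` is
    the cluster of codes[i]; the representative of a cluster is its founding
    (first-scanned) member.
    """

    k: int
    codes: np.ndarray      # int64, priority order
    counts: np.ndarray     # pan-genome totals aligned with codes
    assign: np.ndarray     # cluster index per k-mer
    n_clusters: int

    def __post_init__(self):
        first = np.full(self.n_clusters, -1, dtype=np.int64)
        seen = np.zeros(self.n_clusters, dtype=bool)
        for i, cl in enumerate(self.assign):
            if not seen[cl]:
                seen[cl] = True
                first[cl] = i
        self._rep_idx = first

    def __len__(self) -> int:
        return self.n_clusters

    def representative(self, cluster_id: int) -> str:
        return code_to_kmer(int(self.codes[self._rep_idx[cluster_id]]), self.k)

    def member_codes(self, cluster_id: int) -> np.ndarray:
        return self.codes[self.assign == cluster_id]

    def members(self, cluster_id: int) -> dict[str, int]:
        mask = self.assign == cluster_id
        return {
            code_to_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes[mask], self.counts[mask])
        }

    def cluster_of_code_table(self) -> np.ndarray:
        """Dense code -> cluster index map (-1 = unseen); k <= 13 only."""
        if self.k > _MAX_DENSE_K:
            raise ValueError("dense table only supported for k <= 13")
        table = np.full(4 ** self.k, -1, dtype=np.int64)
        table[self.codes] = self.assign
        return table

    def to_frame(self) -> pd.DataFrame:
        reps = [self.representative(cl) for cl in range(self.n_clusters)]
        return pd.DataFrame({
            "cluster_id": [f"cluster_{cl}" for cl in self.assign],
            "representative": [reps[cl] for cl in self.assign],
            "member": [code_to_kmer(int(c), self.k) for c in self.codes],
            "member_count": self.counts,
        })


def cluster_kmers(index_or_codes, k: int | None = None,
                  counts: np.ndarray | None = None) -> KmerClusterSet:
    """Cluster unique k-mers at one mismatch (greedy, deterministic).

    Accepts either a PromoterKmerIndex or (codes, k, counts) pre-ordered
    arrays. When given an index, k-mers are ordered by abundance then
    lexicographic rank first.
    """
    if isinstance(index_or_codes, PromoterKmerIndex):
        index = index_or_codes
        k = index.k
        codes, cnts = index.unique_counts()
        order = order_kmers(codes, cnts)
        codes, cnts = codes[order], cnts[order]
    else:
        codes = np.asarray(index_or_codes, dtype=np.int64)
        if k is None:
            raise ValueError("k required when passing raw codes")
        cnts = (np.asarray(counts, dtype=np.int64) if counts is not None
                else np.ones(codes.size, dtype=np.int64))
    if codes.size == 0:
        raise ValueError("no k-mers to cluster")
    if codes.max() >= 4 ** k or codes.min() < 0:
        raise ValueError("k-mer codes inconsistent with k (mixed lengths?)")
    if k <= _MAX_DENSE_K:
        assign, n_clusters = _greedy_cluster_dense(codes, k, 4 ** k)
    else:
        assign, n_clusters = _greedy_cluster_dict(codes, k)
    return KmerClusterSet(k, codes, cnts, assign, int(n_clusters))


@dataclass
class ClusterCountMatrix:
    """Genes x retained-clusters occurrence counts with response and covariates.

    ``X`` is sparse CSC; ``cluster_ids`` maps columns back to cluster indices
    in the originating KmerClusterSet. Rows are sorted by gene_id.
    """

    X: sparse.csc_matrix
    y: np.ndarray
    C: np.ndarray
    gene_ids: list[str]
    pangene_ids: list[str]
    accession_ids: list[str]
    cluster_ids: np.ndarray
    clusters: KmerClusterSet
    covariate_kind: str = "intercept"

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_of_cluster(self, cluster_id: int) -> int:
        hits = np.flatnonzero(self.cluster_ids == cluster_id)
        if hits.size == 0:
            raise KeyError(f"cluster {cluster_id} not retained")
        return int(hits[0])


def _build_covariates(kind, pangene_ids: list[str], n: int) -> tuple[np.ndarray, str]:
    if isinstance(kind, np.ndarray):
        if kind.shape[0] != n:
            raise ValueError("covariate matrix rows != promoters")
        return kind.astype(float), "custom"
    if kind == "intercept":
        return np.ones((n, 1)), "intercept"
    if kind == "pangene":
        cats = pd.Categorical(pangene_ids)
        C = np.zeros((n, len(cats.categories)))
        C[np.arange(n), cats.codes] = 1.0
        return C, "pangene"
    raise ValueError(f"unknown covariate kind {kind!r}")


def count_clusters_in_index(index: PromoterKmerIndex,
                            clusters: KmerClusterSet,
                            columns: np.ndarray | None = None) -> sparse.csc_matrix:
    """Occurrence counts of (retained) clusters in each promoter of ``index``.

    ``columns`` selects/orders cluster indices as matrix columns (defaults to
    all clusters). Clusters absent from a promoter contribute 0 — this is also
    how held-out promoters are projected onto training clusters in CV.
    """
    table = clusters.cluster_of_code_table()
    n = index.n_promoters
    valid = index.codes >= 0
    cl = np.where(valid, table[np.where(valid, index.codes, 0)], -1)
    rows = np.repeat(np.arange(n), np.diff(index.offsets))
    keep = cl >= 0
    rows, cl = rows[keep], cl[keep]
    if columns is not None:
        remap = np.full(clusters.n_clusters, -1, dtype=np.int64)
        remap[columns] = np.arange(columns.size)
        cl = remap[cl]
        keep = cl >= 0
        rows, cl = rows[keep], cl[keep]
        ncol = columns.size
    else:
        ncol = clusters.n_clusters
    M = sparse.coo_matrix(
        (np.ones(rows.size), (rows, cl)), shape=(n, ncol)
    ).tocsc()
    M.sum_duplicates()
    return M


def build_count_matrix(clusters: KmerClusterSet, index: PromoterKmerIndex,
                       expression: ExpressionTable,
                       covariates="intercept",
                       min_prevalence: float = 0.01) -> ClusterCountMatrix:
    """Assemble the model's X (cluster counts), y (expression) and C.

    Promoters without an expression value are dropped (with a warning);
    prevalence — the fraction of remaining promoters containing a cluster —
    must be strictly greater than ``min_prevalence`` for a column to be kept.
    """
    have = [i for i, g in enumerate(index.gene_ids) if g in expression]
    if len(have) < index.n_promoters:
        warnings.warn(
            f"{index.n_promoters - len(have)} promoters without expression dropped"
        )
    if not have:
        raise ValueError("no promoters with expression")
    M = count_clusters_in_index(index, clusters)
    M = M[have, :].tocsc()
    n = len(have)
    prevalence = np.diff(M.indptr) / n  # counts >=1 everywhere nnz
    retained = np.flatnonzero(prevalence > min_prevalence)
    if retained.size == 0:
        raise ValueError("no clusters pass the prevalence filter")
    X = M[:, retained].tocsc()
    gene_ids = [index.gene_ids[i] for i in have]
    pangene_ids = [index.pangene_ids[i] for i in have]
    accession_ids = [index.accession_ids[i] for i in have]
    y = expression.vector(gene_ids)
    C, kind = _build_covariates(covariates, pangene_ids, n)
    return ClusterCountMatrix(X, y, C, gene_ids, pangene_ids, accession_ids,
                              retained, clusters, kind)
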