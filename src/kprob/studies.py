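"""Reference simulation studies bundled with the package.

These run the full pipeline end-to-end on the synthetic fixtures at fixed,
documented study conditions and return the quantities a user would quote:
planted-motif recovery, null-calibration behaviour, and cross-validated k
selection. Problem sizes are scaled to desk hardware (see docs/methods.md);
the generator parameters are the study conditions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bvs import fit_bvs
from .kmers import build_count_matrix, cluster_kmers, enumerate_kmers
from .kselect import cv_r2, select_k
from .simulate import (attribute_selections, simulate_expression,
                       simulate_pangenome)
from .sites import filter_functional_sites

#: study conditions for planted-motif recovery (26 accessions x 300 pangenes,
#: 5 planted motifs, signal fraction ~0.6); the 500 bp window keeps the
#: k-mer space dense enough for realistic cluster structure at desk scale.
RECOVERY_CONDITIONS = dict(
    n_pangenes=300, n_accessions=26, promoter_len=500,
    n_planted=5, motif_len=11, k=11, iters=1200, burn_in=400, thin=2,
)

#: pure-noise conditions for null calibration.
NULL_CONDITIONS = dict(
    n_pangenes=60, n_accessions=10, promoter_len=250,
    n_planted=0, k=11, iters=1000, burn_in=400, thin=2,
)

#: conditions for the cross-validated k study: a width-8 planted motif with
#: one-mismatch binding-word degeneracy across pangenes.
KSELECT_CONDITIONS = dict(
    n_pangenes=60, n_accessions=12, promoter_len=200,
    n_planted=3, motif_len=8, pangenes_per_motif=25,
    baseline_sd=0.5, motif_mismatch_prob=0.5,
    k_values=(6, 7, 8, 9, 10), n_folds=10, iters=600, burn_in=200, thin=2,
)


@dataclass
class RecoveryResult:
    n_planted: int
    n_recovered: int
    n_selected: int
    n_false: int
    recovered_by_mode: dict     # "sv"/"snp" -> (recovered, total)


def recovery_run(seed: int, target_fdr: float = 0.1) -> RecoveryResult:
    """One end-to-end planted-motif recovery experiment."""
    c = RECOVERY_CONDITIONS
    promoters, truth = simulate_pangenome(
        n_pangenes=c["n_pangenes"], n_accessions=c["n_accessions"],
        promoter_len=c["promoter_len"], n_planted=c["n_planted"],
        motif_len=c["motif_len"], seed=seed)
    expression = simulate_expression(promoters, truth, seed=seed + 10_000)
    index = enumerate_kmers(promoters, c["k"])
    clusters = cluster_kmers(index)
    matrix = build_count_matrix(clusters, index, expression,
                                covariates="pangene")
    fit = fit_bvs(matrix, iters=c["iters"], burn_in=c["burn_in"],
                  thin=c["thin"], seed=seed + 20_000)
    _, selected, _ = fit.select(target_fdr)
    attributed, false_cols = attribute_selections(
        matrix, selected, promoters, truth)
    by_mode: dict = {}
    for j, pm in enumerate(truth.planted):
        rec, tot = by_mode.get(pm.mode, (0, 0))
        by_mode[pm.mode] = (rec + bool(attributed[j]), tot + 1)
    return RecoveryResult(
        n_planted=len(truth.planted),
        n_recovered=sum(bool(v) for v in attributed.values()),
        n_selected=int(selected.size),
        n_false=len(false_cols),
        recovered_by_mode=by_mode)


@dataclass
class NullResult:
    n_selected: int
    estimated_fdr: float        # mean(1 - PIP) over selected; 0 if none
    max_pip: float
    site_pairs_tested: int
    site_pairs_retained: int


def null_run(seed: int, target_fdr: float = 0.1,
             alpha: float = 0.05, n_probe_clusters: int = 15) -> NullResult:
    """Pure-noise fixture: selection behaviour and null site-filter retention.

    The per-pangene site filter is probed on ``n_probe_clusters`` arbitrary
    retained clusters (forced through as if selected), since on null data the
    FDR selection itself is typically empty.
    """
    c = NULL_CONDITIONS
    promoters, truth = simulate_pangenome(
        n_pangenes=c["n_pangenes"], n_accessions=c["n_accessions"],
        promoter_len=c["promoter_len"], n_planted=c["n_planted"], seed=seed)
    expression = simulate_expression(promoters, truth, seed=seed + 10_000)
    index = enumerate_kmers(promoters, c["k"])
    clusters = cluster_kmers(index)
    matrix = build_count_matrix(clusters, index, expression,
                                covariates="pangene")
    fit = fit_bvs(matrix, iters=c["iters"], burn_in=c["burn_in"],
                  thin=c["thin"], seed=seed + 20_000)
    _, selected, _ = fit.select(target_fdr)
    est_fdr = float((1 - fit.pip[selected]).mean()) if selected.size else 0.0
    rng = np.random.default_rng(seed + 30_000)
    probe = rng.choice(matrix.p, size=min(n_probe_clusters, matrix.p),
                       replace=False)
    sites = filter_functional_sites(fit, matrix, alpha=alpha,
                                    selected_columns=probe)
    return NullResult(
        n_selected=int(selected.size), estimated_fdr=est_fdr,
        max_pip=float(fit.pip.max()),
        site_pairs_tested=len(sites),
        site_pairs_retained=int(sites["retained"].sum()) if len(sites) else 0)


@dataclass
class KSelectResult:
    mean_r2: dict               # scheme -> {k: mean R^2}
    best_k: dict                # scheme -> argmax k


def kselect_run(seed: int, schemes=("by_gene", "by_pangene")) -> KSelectResult:
    """Cross-validated R^2 over k for the planted width-8 motif fixture."""
    c = KSELECT_CONDITIONS
    promoters, truth = simulate_pangenome(
        n_pangenes=c["n_pangenes"], n_accessions=c["n_accessions"],
        promoter_len=c["promoter_len"], n_planted=c["n_planted"],
        motif_len=c["motif_len"], pangenes_per_motif=c["pangenes_per_motif"],
        baseline_sd=c["baseline_sd"],
        motif_mismatch_prob=c["motif_mismatch_prob"], seed=seed)
    expression = simulate_expression(promoters, truth, seed=seed + 10_000)
    mean_r2, best = {}, {}
    for scheme in schemes:
        results = cv_r2(promoters, expression, c["k_values"], scheme=scheme,
                        n_folds=c["n_folds"], iters=c["iters"],
                        burn_in=c["burn_in"], thin=c["thin"],
                        seed=seed + 20_000)
        mean_r2[scheme] = {r.k: r.mean_r2 for r in results}
        best[scheme] = select_k(results)
    return KSelectResult(mean_r2, best)
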