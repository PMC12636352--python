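"""Pangene-level promoter-similarity and expression-variability metrics.

Promoter similarity is the alignment-free count of distinct 31-mers shared by
two promoter windows (0..1970 for 2 kb windows, log2 up to 10.94). Expression
variability is log10(CV^2) of log2(TPM+1) across a pangene's gene copies,
decorrelated from mean expression by subtracting a running median. Highly
variable (hv) pangenes sit in the extreme quantiles of both metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._encode import unique_kmer_codes
from .pan_io import ExpressionTable, PromoterSet

CV2_LOG10_FLOOR = -6.0  # clamp for invariant pangenes (CV == 0)


def promoter_similarity(seq_a: str, seq_b: str, k: int = 31) -> int:
    """Number of distinct k-mers shared by two promoters (k-mers with N excluded)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(len(seq_a), len(seq_b)):
        warnings.warn(f"k={k} longer than a sequence; similarity set to 0")
        return 0
    a = unique_kmer_codes(seq_a, k)
    b = unique_kmer_codes(seq_b, k)
    return int(np.intersect1d(a, b, assume_unique=True).size)


def pangene_similarity(promoters: list, k: int = 31) -> tuple[float, float]:
    """Mean pairwise shared-k-mer count over all C(n,2) promoter pairs.

    Returns (mean_score, log2_similarity). A mean score of 0 is reported as
    log2 similarity 0 (the documented floor, matching the scale's lower end).
    Raises for single-promoter pangenes, where the metric is undefined.
    """
    seqs = [p.sequence if hasattr(p, "sequence") else p for p in promoters]
    if len(seqs) < 2:
        raise ValueError("pangene similarity needs >= 2 promoters")
    kmer_sets = [unique_kmer_codes(s, k) for s in seqs]
    total, pairs = 0, 0
    for i in range(len(kmer_sets)):
        for j in range(i + 1, len(kmer_sets)):
            total += np.intersect1d(kmer_sets[i], kmer_sets[j], assume_unique=True).size
            pairs += 1
    mean = total / pairs
    log2_sim = float(np.log2(mean)) if mean > 0 else 0.0
    return mean, log2_sim


def expression_cv(values) -> float:
    """log10 of the squared coefficient of variation of log2(TPM+1) values.

    Uses the sample (n-1) standard deviation. Requires >= 2 values and a
    positive mean; an exactly invariant pangene is clamped to the documented
    floor instead of -inf.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("expression CV needs >= 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean expression must be > 0 (silent pangene)")
    sd = v.std(ddof=1)
    if sd == 0:
        return CV2_LOG10_FLOOR
    return max(float(np.log10((sd / mean) ** 2)), CV2_LOG10_FLOOR)


@dataclass
class PangeneVariation:
    pangene_id: str
    n_genes: int
    mean_expr: float
    similarity: float
    log2_similarity: float
    log10_cv2: float
    norm_log10_cv2: float = np.nan


def variation_table(promoters: PromoterSet, expression: ExpressionTable,
                    k: int = 31) -> pd.DataFrame:
    """Per-pangene similarity and CV metrics for every pangene with >= 2
    expressed gene copies; silent pangenes (mean == 0) are skipped with a flag
    column left out of the table."""
    rows = []
    for pangene, recs in promoters.by_pangene().items():
        recs = [r for r in recs if r.gene_id in expression]
        if len(recs) < 2:
            continue
        exprs = np.array([expression[r.gene_id] for r in recs])
        mean_expr = exprs.mean()
        if mean_expr <= 0:
            continue
        mean_sim, log2_sim = pangene_similarity(recs, k=k)
        rows.append(PangeneVariation(
            pangene, len(recs), float(mean_expr), mean_sim, log2_sim,
            expression_cv(exprs),
        ))
    df = pd.DataFrame([vars(r) for r in rows])
    if len(df):
        df = normalize_cv(df)
    return df


def normalize_cv(table: pd.DataFrame, window: int | None = None) -> pd.DataFrame:
    """Subtract the running-median expected log10_cv2 given mean expression.

    Pangenes are ranked by mean_expr; the expected value at rank i is the
    median of log10_cv2 over a centered window that shrinks symmetrically at
    the edges. Default full window width: max(101, 1% of pangene count),
    forced odd.
    """
    df = table.copy()
    n = len(df)
    if n < 3:
        warnings.warn("fewer than 3 pangenes; CV normalization is the identity")
        df["norm_log10_cv2"] = df["log10_cv2"] - df["log10_cv2"].median()
        return df
    if window is None:
        window = max(101, int(np.ceil(0.01 * n)))
    window = min(window, n)
    if window % 2 == 0:
        window += 1
    half = window // 2
    order = np.argsort(df["mean_expr"].to_numpy(), kind="stable")
    cv = df["log10_cv2"].to_numpy()[order]
    expected = np.empty(n)
    for i in range(n):
        d = min(half, i, n - 1 - i)
        expected[i] = np.median(cv[i - d:i + d + 1])
    norm = np.empty(n)
    norm[order] = cv - expected
    df["norm_log10_cv2"] = norm
    return df


def select_hv(table: pd.DataFrame, top_fraction: float = 0.30,
              min_genes: int = 6, min_expr: float = 1.0) -> tuple[set[str], set[str]]:
    """Highly-variable and least-variable pangene id sets.

    Small (n_genes < min_genes) and weakly expressed (mean < min_expr)
    pangenes are removed first. hv pangenes fall at or below the
    ``top_fraction`` quantile of log2 similarity (most dissimilar promoters)
    AND at or above the ``1-top_fraction`` quantile of normalized log10 CV^2.
    The least-variable set is the mirrored selection. Quantiles use linear
    interpolation; comparisons are inclusive.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    df = table[(table["n_genes"] >= min_genes) & (table["mean_expr"] >= min_expr)]
    if df.empty:
        warnings.warn("no pangenes pass the size/expression filters")
        return set(), set()
    sim_lo = df["log2_similarity"].quantile(top_fraction)
    sim_hi = df["log2_similarity"].quantile(1 - top_fraction)
    cv_hi = df["norm_log10_cv2"].quantile(1 - top_fraction)
    cv_lo = df["norm_log10_cv2"].quantile(top_fraction)
    hv = set(df.loc[(df["log2_similarity"] <= sim_lo)
                    & (df["norm_log10_cv2"] >= cv_hi), "pangene_id"])
    lv = set(df.loc[(df["log2_similarity"] >= sim_hi)
                    & (df["norm_log10_cv2"] <= cv_lo), "pangene_id"])
    if not hv:
        warnings.warn("hv selection is empty")
    return hv, lv


@dataclass
class BootstrapComparison:
    mean_a: float
    mean_b: float
    diff: float
    ci_low: float
    ci_high: float
    n_boot: int


def bootstrap_mean_ci(group_a, group_b, n_boot: int = 10000,
                      seed: int | None = None, ci: float = 0.95) -> BootstrapComparison:
    """Bootstrap the difference of group means with a percentile CI.

    Each group is resampled with replacement ``n_boot`` times; the CI is the
    percentile interval of the bootstrap distribution of mean(a) - mean(b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable CI")
    rng = np.random.default_rng(seed)
    boot_a = rng.choice(a, size=(n_boot, a.size), replace=True).mean(axis=1)
    boot_b = rng.choice(b, size=(n_boot, b.size), replace=True).mean(axis=1)
    diff = boot_a - boot_b
    lo, hi = np.percentile(diff, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return BootstrapComparison(float(a.mean()), float(b.mean()),
                               float(a.mean() - b.mean()), float(lo), float(hi), n_boot)


def spearman_decorrelation(table: pd.DataFrame) -> float:
    """|Spearman rho| between normalized CV and mean expression (diagnostic)."""
    rho, _ = stats.spearmanr(table["norm_log10_cv2"], table["mean_expr"])
    return abs(float(rho))
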