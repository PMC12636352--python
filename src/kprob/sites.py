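"""Per-pangene functional-site filtering of significant k-mer clusters.

The Bayesian fit reports the average per-occurrence effect of a cluster over
all its genomic occurrences, functional or not. To isolate functional sites,
each selected cluster is regressed (OLS) against expression within every
pangene where its counts vary; pairs with an FDR-corrected p < alpha whose
slope agrees in sign with the cluster's global posterior-mean effect are
retained as putative functional sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def per_pangene_effect(counts, expr) -> tuple[float, float, float]:
    """OLS slope of expression on cluster counts within one pangene.

    Returns (slope, se, two-sided p). Requires >= 3 genes and non-constant
    counts; the caller skips untestable pairs.
    """
    counts = np.asarray(counts, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if counts.size < 3:
        raise ValueError("need >= 3 genes")
    if np.ptp(counts) == 0:
        raise ValueError("counts are constant; slope undefined")
    res = stats.linregress(counts, expr)
    p = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return float(res.slope), float(res.stderr), float(p)


def filter_functional_sites(fit, matrix, alpha: float = 0.05,
                            target_fdr: float = 0.1,
                            selected_columns=None,
                            bh_scope: str = "global") -> pd.DataFrame:
    """Run per-pangene regressions for selected clusters and filter.

    ``fit`` is a SpikeSlabResults on ``matrix`` (ClusterCountMatrix). Pairs
    with < 3 informative genes or zero count variance are excluded from the
    BH family. ``bh_scope`` is ``"global"`` (one family across all tested
    pairs) or ``"per_cluster"``. Returns the FunctionalSite table with a
    per-cluster retention fraction joined in.
    """
    if selected_columns is None:
        _, selected_columns, _ = fit.select(target_fdr)
    selected_columns = np.asarray(selected_columns, dtype=int)
    pangenes = np.asarray(matrix.pangene_ids)
    Xcsc = matrix.X.tocsc()
    rows = []
    for col in selected_columns:
        x = np.asarray(Xcsc[:, col].todense()).ravel()
        gbeta = fit.beta_mean[col]
        for pg in pd.unique(pangenes):
            mask = pangenes == pg
            if mask.sum() < 3:
                continue
            cx = x[mask]
            if cx.max() == 0 or np.ptp(cx) == 0:
                continue  # absent or constant: not testable
            slope, se, p = per_pangene_effect(cx, matrix.y[mask])
            rows.append({
                "column": int(col),
                "cluster_id": int(matrix.cluster_ids[col]),
                "pangene_id": pg,
                "n_genes": int(mask.sum()),
                "slope": slope,
                "se": se,
                "p": p,
                "sign_concordant": bool(np.sign(slope) == np.sign(gbeta)),
                "global_beta": float(gbeta),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        df["q"] = df["retained"] = pd.Series(dtype=float)
        return df
    if bh_scope == "global":
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    elif bh_scope == "per_cluster":
        df["q"] = np.nan
        for col, sub in df.groupby("column"):
            df.loc[sub.index, "q"] = multipletests(sub["p"], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    df["retained"] = (df["q"] < alpha) & df["sign_concordant"]
    frac = df.groupby("column")["retained"].mean().rename("retention_fraction")
    return df.merge(frac, on="column")
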