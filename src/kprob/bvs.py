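"""Spike-and-slab Bayesian variable selection for cluster-count regression.

Model
-----
    y = C a + X b + e,        e ~ N(0, de^2 I)
    b_j ~ (1 - g_j) N(0, d0^2) + g_j N(0, d1^2)
    g_j ~ Bernoulli(pi),      pi ~ Beta(a_pi, b_pi)
    d1^-2 ~ Gamma(a1, b1),    de^-2 ~ Gamma(ae, be)

The spike variance d0^2 is fixed from the data as q * Var(y) / sum_j Var(X_j)
with q (default 0.05) the fraction of expression variance attributed to
background effects. Covariate effects a get an improper flat prior. Inference
is a Gibbs sampler that updates (g_j, b_j) jointly per column — g_j is drawn
from its conditional with b_j integrated out under the two-component normal
prior, then b_j from its conjugate normal conditional. The posterior
inclusion probability PIP_j = E[g_j | y, C, X] is the mean of retained g
draws; selection at a target FDR uses the Bayesian local-FDR rule (average of
1 - PIP over the selected set).

The module is organised statsmodels-style: ``SpikeSlabRegression`` is the
model, its ``fit`` returns a ``SpikeSlabResults`` carrying estimates,
uncertainties, traces, convergence diagnostics and a ``summary`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse


@dataclass
class BVSModelSpec:
    """Hyperparameters of the spike-and-slab hierarchy."""

    q: float = 0.05
    a_pi: float = 1.0
    b_pi: float = 1.0
    a1: float = 0.01
    b1: float = 0.01
    a_e: float = 0.01
    b_e: float = 0.01
    delta0_sq: float | None = None
    # fixing any of these to a value collapses its prior to a point mass
    fix_pi: float | None = None
    fix_delta1_sq: float | None = None
    fix_deltae_sq: float | None = None

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        for name in ("a_pi", "b_pi", "a1", "b1", "a_e", "b_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def compute_delta0(y: np.ndarray, X, q: float = 0.05) -> float:
    """Spike variance d0^2 = q * Var(y) / sum_j Var(X_j) (sample variances)."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need >= 2 rows")
    if sparse.issparse(X):
        n = X.shape[0]
        Xc = X.tocsc()
        s1 = np.asarray(Xc.sum(axis=0)).ravel()
        s2 = np.asarray(Xc.multiply(Xc).sum(axis=0)).ravel()
        col_var = (s2 - s1 ** 2 / n) / (n - 1)
    else:
        col_var = np.var(np.asarray(X, dtype=float), axis=0, ddof=1)
    total = float(col_var.sum())
    if total <= 0:
        raise ValueError("sum of column variances is zero")
    return q * float(np.var(y, ddof=1)) / total


@njit(cache=True)
def _gibbs_core(y, C, P, A, has_cov, xdata, xind, xptr, xtx,
                d0, a_pi, b_pi, a1, b1, ae, be,
                n_iter, burn_in, thin, seed,
                fix_pi, fix_d1, fix_de, random_scan):
    n = y.shape[0]
    p = xptr.shape[0] - 1
    c = C.shape[1]
    np.random.seed(seed)
    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=np.int8)
    alpha = np.zeros(c)
    if has_cov:
        alpha = P @ y
    r = y - C @ alpha if has_cov else y.copy()
    vy = np.var(y)
    if vy <= 0.0:
        vy = 1.0
    pi = 0.1 if fix_pi < 0 else fix_pi
    d1 = vy if fix_d1 < 0 else fix_d1
    de = vy if fix_de < 0 else fix_de
    n_keep = 0
    for it in range(n_iter):
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
    pip = np.zeros(p)
    beta_sum = np.zeros(p)
    beta_sq_sum = np.zeros(p)
    slab_sum = np.zeros(p)
    slab_cnt = np.zeros(p)
    alpha_sum = np.zeros(c)
    tr_pi = np.zeros(n_keep)
    tr_d1 = np.zeros(n_keep)
    tr_de = np.zeros(n_keep)
    tr_size = np.zeros(n_keep)
    kept = 0
    order = np.arange(p)
    status = 0
    for it in range(n_iter):
        logit_pi = np.log(pi) - np.log(1.0 - pi)
        if random_scan:
            order = np.random.permutation(p)
        for oj in range(p):
            j = order[oj]
            lo = xptr[j]
            hi = xptr[j + 1]
            bj = beta[j]
            if bj != 0.0:
                for t in range(lo, hi):
                    r[xind[t]] += xdata[t] * bj
            b = 0.0
            for t in range(lo, hi):
                b += xdata[t] * r[xind[t]]
            s = xtx[j]
            var1 = 1.0 / (s / de + 1.0 / d1)
            var0 = 1.0 / (s / de + 1.0 / d0)
            m1 = var1 * b / de
            m0 = var0 * b / de
            l1 = 0.5 * np.log(var1 / d1) + 0.5 * m1 * m1 / var1
            l0 = 0.5 * np.log(var0 / d0) + 0.5 * m0 * m0 / var0
            z = logit_pi + l1 - l0
            if z > 35.0:
                p1 = 1.0
            elif z < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-z))
            if np.random.random() < p1:
                gamma[j] = 1
                bj = m1 + np.sqrt(var1) * np.random.standard_normal()
            else:
                gamma[j] = 0
                bj = m0 + np.sqrt(var0) * np.random.standard_normal()
            beta[j] = bj
            for t in range(lo, hi):
                r[xind[t]] -= xdata[t] * bj
        if has_cov:
            t_full = r + C @ alpha
            mean_a = P @ t_full
            zc = np.random.standard_normal(c)
            alpha = mean_a + np.sqrt(de) * (A @ zc)
            r = t_full - C @ alpha
        size = 0
        for j in range(p):
            size += gamma[j]
        if fix_pi < 0:
            pi = np.random.beta(a_pi + size, b_pi + p - size)
            if pi < 1e-12:
                pi = 1e-12
            elif pi > 1.0 - 1e-12:
                pi = 1.0 - 1e-12
        if fix_d1 < 0:
            ssb = 0.0
            for j in range(p):
                if gamma[j] == 1:
                    ssb += beta[j] * beta[j]
            g = np.random.gamma(a1 + 0.5 * size, 1.0 / (b1 + 0.5 * ssb))
            if g < 1e-300:  # tiny-shape Gamma draws can underflow to 0
                g = 1e-300
            d1 = 1.0 / g
            if d1 < d0:
                d1 = d0  # keep the slab at least as wide as the spike
            elif d1 > 1e12:
                d1 = 1e12
        if fix_de < 0:
            ssr = 0.0
            for i in range(n):
                ssr += r[i] * r[i]
            g = np.random.gamma(ae + 0.5 * n, 1.0 / (be + 0.5 * ssr))
            if g < 1e-300:
                g = 1e-300
            de = 1.0 / g
        if not np.isfinite(de) or de > 1e15:
            status = 1
            break
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(p):
                if gamma[j] == 1:
                    pip[j] += 1.0
                    slab_sum[j] += beta[j]
                    slab_cnt[j] += 1.0
                beta_sum[j] += beta[j]
                beta_sq_sum[j] += beta[j] * beta[j]
            for ci in range(c):
                alpha_sum[ci] += alpha[ci]
            tr_pi[kept] = pi
            tr_d1[kept] = d1
            tr_de[kept] = de
            tr_size[kept] = size
            kept += 1
    return (pip, beta_sum, beta_sq_sum, slab_sum, slab_cnt, alpha_sum,
            tr_pi, tr_d1, tr_de, tr_size, kept, status)


def geweke_z(trace, first_frac: float = 0.1, last_frac: float = 0.5,
             n_batches: int = 10) -> float:
    """Geweke convergence z-score on one retained trace.

    Compares the mean of the first ``first_frac`` of the chain with the mean
    of the last ``last_frac``; each segment's variance of the mean is
    estimated by batch means (up to ``n_batches`` batches).
    """
    t = np.asarray(trace, dtype=float)
    if t.size < 20:
        raise ValueError("trace too short for the Geweke test (need >= 20)")
    na = max(2, int(np.floor(first_frac * t.size)))
    nb = max(2, int(np.floor(last_frac * t.size)))
    a, b = t[:na], t[t.size - nb:]

    def _var_of_mean(seg):
        nb_eff = min(n_batches, seg.size)
        batches = np.array_split(seg, nb_eff)
        means = np.array([np.mean(x) for x in batches])
        if nb_eff < 2:
            return 0.0
        return float(np.var(means, ddof=1) / nb_eff)

    va, vb = _var_of_mean(a), _var_of_mean(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0 if np.isclose(a.mean(), b.mean()) else np.inf
    return float((a.mean() - b.mean()) / denom)


def pip_fdr(pips: np.ndarray, target: float = 0.1):
    """PIP-based Bayesian FDR selection.

    For each candidate threshold t (distinct PIP values, descending),
    FDR(t) = sum_{PIP_i >= t} (1 - PIP_i) / #{PIP_i >= t}. The selected set is
    the largest whose estimated FDR is <= target. Returns
    (threshold, selected index array, fdr table DataFrame).
    """
    pips = np.asarray(pips, dtype=float)
    if pips.size == 0:
        return 1.0, np.empty(0, dtype=int), pd.DataFrame(
            columns=["threshold", "n_selected", "fdr"])
    order = np.argsort(-pips, kind="stable")
    sorted_p = pips[order]
    cum_fdr = np.cumsum(1.0 - sorted_p) / np.arange(1, pips.size + 1)
    # candidate thresholds: last index of each distinct PIP value
    rows, best_m, best_t = [], 0, 1.0 + 1e-12
    i = 0
    while i < pips.size:
        j = i
        while j + 1 < pips.size and sorted_p[j + 1] == sorted_p[i]:
            j += 1
        t = sorted_p[i]
        fdr = cum_fdr[j]
        rows.append({"threshold": t, "n_selected": j + 1, "fdr": fdr})
        if fdr <= target:
            best_m, best_t = j + 1, t
        i = j + 1
    selected = np.sort(order[:best_m])
    return float(best_t), selected, pd.DataFrame(rows)


@dataclass
class GewekeReport:
    z_scores: dict = field(default_factory=dict)
    converged: bool = True


class SpikeSlabResults:
    """Posterior summaries of a fitted spike-and-slab regression."""

    def __init__(self, model, pip, beta_mean, beta_sd, beta_slab_mean,
                 alpha_mean, traces, n_kept, seed, mcmc_params):
        self.model = model
        self.pip = pip
        self.beta_mean = beta_mean
        self.beta_sd = beta_sd
        self.beta_slab_mean = beta_slab_mean
        self.alpha_mean = alpha_mean
        self.traces = traces  # dict name -> retained samples
        self.n_kept = n_kept
        self.seed = seed
        self.mcmc_params = mcmc_params
        self.geweke = self._geweke()

    def _geweke(self) -> GewekeReport:
        rep = GewekeReport()
        monitored = {
            "log_deltae_sq": np.log(self.traces["deltae_sq"]),
            "pi": self.traces["pi"],
            "model_size": self.traces["model_size"],
        }
        for name, tr in monitored.items():
            if tr.size < 20:
                continue
            z = geweke_z(tr)
            rep.z_scores[name] = z
            if not (abs(z) <= 1.96):
                rep.converged = False
        return rep

    def select(self, target_fdr: float = 0.1):
        """(threshold, selected column indices, fdr table) at a target FDR."""
        return pip_fdr(self.pip, target_fdr)

    def predict(self, C_new=None, X_new=None) -> np.ndarray:
        """Posterior-mean prediction C_new @ alpha + X_new @ beta."""
        n = None
        out = 0.0
        if X_new is not None:
            if X_new.shape[1] != self.beta_mean.size:
                raise ValueError("X_new columns do not match the training matrix")
            out = out + X_new @ self.beta_mean
            n = X_new.shape[0]
        if self.model.has_cov:
            if C_new is None:
                raise ValueError("model was fit with covariates; C_new required")
            out = out + C_new @ self.alpha_mean
            n = C_new.shape[0]
        if n is None:
            raise ValueError("need X_new and/or C_new")
        return np.asarray(out) + self.model.y_offset

    def to_frame(self, names=None) -> pd.DataFrame:
        names = names if names is not None else [
            f"x{j}" for j in range(self.pip.size)]
        return pd.DataFrame({
            "name": names,
            "pip": self.pip,
            "beta_mean": self.beta_mean,
            "beta_sd": self.beta_sd,
            "beta_slab_mean": self.beta_slab_mean,
        })

    def summary(self, target_fdr: float = 0.1, max_rows: int = 20) -> str:
        thr, sel, _ = self.select(target_fdr)
        lines = [
            "Spike-and-slab Bayesian variable selection",
            "=" * 58,
            f"n obs:              {self.model.n}",
            f"n predictors:       {self.model.p}",
            f"covariates:         {self.model.C.shape[1] if self.model.has_cov else 0}",
            f"delta0^2 (spike):   {self.model.spec.delta0_sq:.4g}",
            f"retained draws:     {self.n_kept}  (seed={self.seed})",
            f"posterior mean pi:  {self.traces['pi'].mean():.4g}",
            f"posterior mean de2: {self.traces['deltae_sq'].mean():.4g}",
            f"Geweke converged:   {self.geweke.converged} "
            f"({ {k: round(v, 2) for k, v in self.geweke.z_scores.items()} })",
            f"selected at FDR<={target_fdr}: {sel.size} (PIP threshold {thr:.3g})",
            "-" * 58,
        ]
        df = self.to_frame().sort_values("pip", ascending=False).head(max_rows)
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class SpikeSlabRegression:
    """Spike-and-slab regression of expression on cluster counts.

    Parameters
    ----------
    y : response vector (log2(TPM+1)).
    X : n x p count matrix (dense or sparse); columns are NOT standardized so
        effects stay per-occurrence.
    C : covariate matrix, or None. With no covariates ``center_y`` defaults
        on so the intercept is absorbed.
    spec : BVSModelSpec; ``delta0_sq`` is computed from the data when unset.
    """

    def __init__(self, y, X, C=None, spec: BVSModelSpec | None = None,
                 center_y: bool | None = None):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        self.spec = spec if spec is not None else BVSModelSpec()
        Xc = sparse.csc_matrix(X, dtype=float)
        if Xc.shape[0] != y.size:
            raise ValueError("rows of X do not match y")
        self.has_cov = C is not None
        if center_y is None:
            center_y = not self.has_cov
        self.y_offset = y.mean() if center_y else 0.0
        self.y = y - self.y_offset
        self.X = Xc
        self.C = (np.asarray(C, dtype=float) if self.has_cov
                  else np.zeros((y.size, 1)))
        if self.has_cov and self.C.shape[0] != y.size:
            raise ValueError("rows of C do not match y")
        if self.spec.delta0_sq is None:
            self.spec.delta0_sq = compute_delta0(y, Xc, self.spec.q)

    @classmethod
    def from_count_matrix(cls, matrix, spec: BVSModelSpec | None = None):
        """Build from a ClusterCountMatrix (kmers.build_count_matrix)."""
        return cls(matrix.y, matrix.X, C=matrix.C, spec=spec)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def fit(self, iters: int = 10000, burn_in: int | None = None,
            thin: int = 5, seed: int = 0,
            random_scan: bool = False) -> SpikeSlabResults:
        if burn_in is None:
            burn_in = iters // 2
        if iters <= burn_in:
            raise ValueError("iters must exceed burn_in")
        sp = self.spec
        X = self.X
        xtx = np.asarray(X.multiply(X).sum(axis=0)).ravel()
        if self.has_cov:
            CtC = self.C.T @ self.C
            L = np.linalg.cholesky(CtC + 1e-12 * np.eye(CtC.shape[0]))
            P = np.linalg.solve(CtC + 1e-12 * np.eye(CtC.shape[0]), self.C.T)
            A = np.linalg.inv(L).T  # cov = de^2 * A @ A.T
        else:
            P = np.zeros((1, self.n))
            A = np.zeros((1, 1))
        out = _gibbs_core(
            self.y, self.C, np.ascontiguousarray(P), np.ascontiguousarray(A),
            self.has_cov,
            X.data, X.indices.astype(np.int64), X.indptr.astype(np.int64), xtx,
            sp.delta0_sq, sp.a_pi, sp.b_pi, sp.a1, sp.b1, sp.a_e, sp.b_e,
            iters, burn_in, thin, seed % (2 ** 31),
            -1.0 if sp.fix_pi is None else sp.fix_pi,
            -1.0 if sp.fix_delta1_sq is None else sp.fix_delta1_sq,
            -1.0 if sp.fix_deltae_sq is None else sp.fix_deltae_sq,
            random_scan,
        )
        (pip, beta_sum, beta_sq_sum, slab_sum, slab_cnt, alpha_sum,
         tr_pi, tr_d1, tr_de, tr_size, kept, status) = out
        if status != 0:
            raise RuntimeError("divergent residual variance in the Gibbs chain")
        if kept == 0:
            raise RuntimeError("no retained samples (check iters/burn_in/thin)")
        beta_mean = beta_sum / kept
        beta_var = np.maximum(beta_sq_sum / kept - beta_mean ** 2, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            slab_mean = np.where(slab_cnt > 0, slab_sum / np.maximum(slab_cnt, 1), 0.0)
        traces = {
            "pi": tr_pi[:kept], "delta1_sq": tr_d1[:kept],
            "deltae_sq": tr_de[:kept], "model_size": tr_size[:kept],
        }
        return SpikeSlabResults(
            self, pip / kept, beta_mean, np.sqrt(beta_var), slab_mean,
            alpha_sum / kept, traces, int(kept), seed,
            {"iters": iters, "burn_in": burn_in, "thin": thin},
        )


def fit_bvs(matrix, spec: BVSModelSpec | None = None, iters: int = 10000,
            burn_in: int | None = None, thin: int = 5, seed: int = 0,
            random_scan: bool = False) -> SpikeSlabResults:
    """One-call fit from a ClusterCountMatrix."""
    model = SpikeSlabRegression.from_count_matrix(matrix, spec=spec)
    return model.fit(iters=iters, burn_in=burn_in, thin=thin, seed=seed,
                     random_scan=random_scan)
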