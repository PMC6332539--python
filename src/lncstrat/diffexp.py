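"""Moderated linear-model differential expression with duplicate correlation.

The model fitted per gene is a precision-weighted generalized least squares
regression of log2-CPM on the study design, with block-equicorrelated
errors: observations from the same patient share a consensus intra-patient
correlation rho, estimated once across genes ("duplicate correlation").
Per-observation precision weights come from the empirical mean-variance
trend of log-counts. Residual variances are shrunk toward a common prior by
inverse-gamma empirical Bayes (moment matching on log s^2), and contrasts
are tested with moderated t-statistics on augmented degrees of freedom.

:class:`DEModel` follows the statsmodels convention: construct from data,
``fit()`` returns a :class:`DEResults` carrying estimates, uncertainties,
diagnostics and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular
from scipy.special import digamma, polygamma

from lncstrat._stats import bh_adjust

P_MAX_DEFAULT = 0.01
FC_MIN_DEFAULT = 1.5


def logcpm(counts: pd.DataFrame, norm_factors=None) -> pd.DataFrame:
    """log2 counts per million: log2((count + 0.5) / (libsize + 1) * 1e6).

    ``norm_factors`` (e.g. from :func:`tmm_norm_factors`) rescale the
    column-sum library sizes to effective library sizes.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"zero library size for sample {bad}")
    if norm_factors is not None:
        lib = lib * np.asarray(norm_factors, dtype=float)
    return np.log2((counts + 0.5).div(lib + 1.0, axis=1) * 1e6)


def tmm_norm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                     trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scale normalization factors.

    Corrects the compositional bias of plain CPM when differential
    expression is asymmetric between groups: per sample, the log-ratio
    (M) of gene proportions against a reference sample is doubly trimmed
    (by M and by average abundance A) and averaged with inverse
    asymptotic-variance weights. Factors are scaled to geometric mean 1.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    n = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array([
            np.quantile(col[col > 0], 0.75) / l if (col > 0).any() else 0.0
            for col, l in zip(X.T, lib)
        ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.ones(n)
    pr = X[:, ref] / lib[ref]
    for j in range(n):
        if j == ref:
            continue
        pj = X[:, j] / lib[j]
        ok = (pj > 0) & (pr > 0)
        if ok.sum() < 10:
            continue
        M = np.log2(pj[ok] / pr[ok])
        A = 0.5 * np.log2(pj[ok] * pr[ok])
        # inverse asymptotic variance of M (delta method on two binomials)
        w = 1.0 / ((lib[j] - X[ok, j]) / (lib[j] * X[ok, j])
                   + (lib[ref] - X[ok, ref]) / (lib[ref] * X[ok, ref]))
        ml, mh = np.quantile(M, [trim_m, 1 - trim_m])
        al, ah = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= ml) & (M <= mh) & (A >= al) & (A <= ah)
        if keep.sum() == 0:
            continue
        f[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    f = f / np.exp(np.mean(np.log(f)))
    return f


def _ols_fit(y: np.ndarray, X: np.ndarray):
    """Vectorized OLS of each row of y on X; returns (coef, fitted, resid)."""
    pinv = np.linalg.pinv(X)
    coef = y @ pinv.T
    fitted = coef @ X.T
    return coef, fitted, y - fitted


def voom_weights(logcpm_mat, design: np.ndarray, span: float = 0.5) -> np.ndarray:
    """Observation precision weights from the empirical mean-variance trend.

    Per gene, OLS residual sqrt-standard-deviations (variance^(1/4)) are
    regressed on mean log-CPM by lowess (default span 0.5); each
    observation's weight is the trend-predicted sqrt-SD at its fitted
    log-CPM, raised to the -4, with prediction clamped to the trend's
    range at the extremes. Weights are finite and > 0.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    y = np.asarray(logcpm_mat, dtype=float)
    n_genes, n = y.shape
    if n_genes < 10:
        raise ValueError("need at least 10 genes for a stable mean-variance trend")
    p = np.linalg.matrix_rank(design)
    if n - p < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    _, fitted, resid = _ols_fit(y, design)
    s2 = (resid ** 2).sum(axis=1) / (n - p)
    sqrt_sd = s2 ** 0.25
    x = y.mean(axis=1)
    trend = lowess(sqrt_sd, x, frac=span, return_sorted=True)
    xs, ys = trend[:, 0], trend[:, 1]
    xs, uniq = np.unique(xs, return_index=True)
    ys = ys[uniq]
    floor = max(1e-8, 0.5 * float(np.min(ys[ys > 0], initial=1e-4)))
    pred = np.interp(np.clip(fitted, xs[0], xs[-1]), xs, ys)
    pred = np.maximum(pred, floor)
    return pred ** -4.0


def duplicate_correlation(
    logcpm_mat, weights, design: np.ndarray, block, trim: float = 0.15
) -> float:
    """Consensus intra-block correlation of expression residuals.

    Per gene, weighted least-squares residuals e = (I - H) y are treated
    as a random-intercept sample with covariance sigma^2 (I - H) R (I - H)
    where R is block-equicorrelated. Because the residual projector leaks
    variance across observations (E[e_i e_j] != rho sigma^2), rho is
    solved from the two moment equations

        mean_pairs e_i e_j = sigma^2 (a0 + rho a1)
        mean e_i^2         = sigma^2 (d0 + rho d1)

    with a/d coefficients computed from M = I - H and the within-block
    indicator; the naive ratio estimator is biased downward by ~p/n. The
    consensus is tanh(trimmed mean of atanh(per-gene estimates)), trimming
    ``trim`` from each tail; it lies in (-1, 1).
    """
    y = np.asarray(logcpm_mat, dtype=float)
    w = np.asarray(weights, dtype=float)
    block = np.asarray(block)
    blocks = pd.Series(block).groupby(pd.Series(block)).indices
    pair_idx = []
    for _b, idx in blocks.items():
        idx = np.asarray(idx)
        if len(idx) >= 2:
            ii, jj = np.triu_indices(len(idx), k=1)
            pair_idx.append((idx[ii], idx[jj]))
    if not pair_idx:
        raise ValueError(
            "no block has >= 2 samples; fit without blocking (block=None)"
        )
    pi = np.concatenate([a for a, _ in pair_idx])
    pj = np.concatenate([b for _, b in pair_idx])
    n = y.shape[1]
    B = (block[:, None] == block[None, :]).astype(float)
    np.fill_diagonal(B, 0.0)
    sw = np.sqrt(w)
    rhos = np.empty(y.shape[0])
    for g in range(y.shape[0]):
        Xw = design * sw[g][:, None]
        yw = y[g] * sw[g]
        Q, _ = np.linalg.qr(Xw)
        H = Q @ Q.T
        M = np.eye(n) - H          # symmetric idempotent: M M' = M
        e = M @ yw
        MBM = M @ B @ M
        a0 = float(np.mean(M[pi, pj]))
        a1 = float(np.mean(MBM[pi, pj]))
        d0 = float(np.mean(np.diag(M)))
        d1 = float(np.mean(np.diag(MBM)))
        cpair = float(np.mean(e[pi] * e[pj]))
        cvar = float(np.mean(e ** 2))
        denom = cvar * a1 - cpair * d1
        if cvar <= 0 or abs(denom) < 1e-12 * max(cvar, 1e-30):
            rhos[g] = 0.0
            continue
        rhos[g] = np.clip((cpair * d0 - cvar * a0) / denom, -0.99, 0.99)
    z = np.arctanh(rhos)
    return float(np.tanh(stats.trim_mean(z, trim)))


def _squeeze_var(s2: np.ndarray, df: float):
    """Empirical-Bayes (d0, s0^2) by moment matching on log s^2 (inverse-
    gamma prior on residual variances). Returns (d0, s0sq, s2_post)."""
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    evar_excess = evar - float(polygamma(1, df / 2.0))
    if evar_excess > 0:
        d0 = 2.0 * _trigamma_inverse(evar_excess)
        s0sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    if np.isfinite(d0):
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
    else:
        s2_post = np.full_like(s2, s0sq)
    return d0, s0sq, s2_post


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _block_chol(block, rho: float, n: int) -> np.ndarray:
    """Cholesky factor of the block-equicorrelation matrix R (lower)."""
    R = np.eye(n)
    if block is not None and rho != 0.0:
        b = np.asarray(block)
        same = b[:, None] == b[None, :]
        R = np.where(same, rho, 0.0)
        np.fill_diagonal(R, 1.0)
    return cholesky(R, lower=True)


def fit_moderated(
    logcpm_mat,
    weights,
    design: np.ndarray,
    contrast,
    block=None,
    consensus_rho: float = 0.0,
    gene_ids=None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated GLS contrast test.

    Under block-equicorrelated errors (correlation ``consensus_rho``
    within block, 0 across), each gene is whitened and fitted by least
    squares; residual variances are shrunk by empirical Bayes and the
    contrast tested with a moderated t on d0 + d_g degrees of freedom.
    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary GLS t).
    """
    y = np.asarray(logcpm_mat, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n_genes, n = y.shape
    p = X.shape[1]
    if c.shape != (p,):
        raise ValueError("contrast length must equal number of coefficients")
    if not -1.0 < consensus_rho < 1.0:
        raise ValueError("consensus_rho must lie in (-1, 1)")
    L = _block_chol(block, consensus_rho, n)
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    est = np.empty(n_genes)
    se_unit = np.empty(n_genes)
    s2 = np.empty(n_genes)
    sw = np.sqrt(w)
    for g in range(n_genes):
        Z = solve_triangular(L, X * sw[g][:, None], lower=True)
        u = solve_triangular(L, y[g] * sw[g], lower=True)
        beta, *_ = np.linalg.lstsq(Z, u, rcond=None)
        r = u - Z @ beta
        s2[g] = float(r @ r) / df_resid
        XtX_inv = np.linalg.pinv(Z.T @ Z)
        est[g] = float(c @ beta)
        se_unit[g] = float(np.sqrt(c @ XtX_inv @ c))

    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0.0:
            s2_post = s2.copy()
        elif np.isinf(d0):
            _, s0sq, _ = _squeeze_var(s2, df_resid)
            s2_post = np.full_like(s2, s0sq)
        else:
            _, s0sq, _ = _squeeze_var(s2, df_resid)
            s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
    else:
        d0, _s0sq, s2_post = _squeeze_var(s2, df_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / (se_unit * np.sqrt(s2_post))
    df_total = d0 + df_resid
    if np.isfinite(df_total):
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    out = pd.DataFrame(
        {
            "gene_id": gene_ids if gene_ids is not None else np.arange(n_genes),
            "log2fc": est,
            "t": t,
            "p": np.clip(pvals, 0.0, 1.0),
            "mean_logcpm": y.mean(axis=1),
            "s2": s2,
            "s2_post": s2_post,
        }
    )
    out["q_bh"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out.attrs["prior_df"] = float(d0)
    out.attrs["df_resid"] = float(df_resid)
    return out


def call_differential(
    results: pd.DataFrame, p_max: float = P_MAX_DEFAULT, fc_min: float = FC_MIN_DEFAULT
) -> pd.DataFrame:
    """Threshold calling: keep p < p_max and |log2fc| >= log2(fc_min)."""
    if results.empty:
        return results.copy()
    keep = (results["p"] < p_max) & (results["log2fc"].abs() >= np.log2(fc_min))
    return results.loc[keep].copy()


def detected_genes(counts: pd.DataFrame, fpkm: pd.DataFrame | None = None,
                   min_total: int = 10) -> pd.Index:
    """Detection filter: FPKM > 0 in >= 1 sample (when FPKM is given) and
    total count >= min_total for model stability."""
    keep = counts.sum(axis=1) >= min_total
    if fpkm is not None:
        keep &= (fpkm.loc[counts.index] > 0).any(axis=1)
    return counts.index[keep]


@dataclass
class DEResults:
    """Results of a moderated differential-expression fit.

    ``table`` has one row per gene: log2fc, moderated t, two-sided p,
    BH-adjusted q, mean log-CPM and direction. ``consensus_rho`` is the
    intra-patient correlation used in the GLS covariance; ``prior_df`` /
    ``prior_var`` are the empirical-Bayes hyperparameters.
    """

    table: pd.DataFrame
    consensus_rho: float
    prior_df: float
    prior_var: float
    df_resid: float
    contrast_name: str = ""

    def called(self, p_max: float = P_MAX_DEFAULT, fc_min: float = FC_MIN_DEFAULT
               ) -> pd.DataFrame:
        return call_differential(self.table, p_max=p_max, fc_min=fc_min)

    def summary(self, p_max: float = P_MAX_DEFAULT, fc_min: float = FC_MIN_DEFAULT) -> str:
        called = self.called(p_max, fc_min)
        up = int((called["direction"] == "up").sum())
        lines = [
            f"Moderated differential expression: {self.contrast_name or 'contrast'}",
            f"  genes tested:        {len(self.table)}",
            f"  residual df:         {self.df_resid:g}",
            f"  prior df (d0):       {self.prior_df:.3g}",
            f"  prior variance s0^2: {self.prior_var:.4g}",
            f"  consensus rho:       {self.consensus_rho:.3f}",
            f"  called (p<{p_max:g}, |FC|>={fc_min:g}): {len(called)} "
            f"({up} up, {len(called) - up} down)",
        ]
        return "\n".join(lines)


class DEModel:
    """Precision-weighted moderated linear model for one contrast.

    Parameters
    ----------
    counts : DataFrame, genes x samples (nonnegative integers)
    design : array, samples x coefficients (full column rank)
    contrast : coefficient-space vector
    block : per-sample patient labels, or None for unblocked fitting
    """

    def __init__(self, counts: pd.DataFrame, design, contrast, block=None,
                 contrast_name: str = "", normalize: bool = True):
        design = np.asarray(design, dtype=float)
        if design.shape[0] != counts.shape[1]:
            raise ValueError("design rows must match number of samples")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("design matrix is not full column rank")
        self.counts = counts
        self.design = design
        self.contrast = np.asarray(contrast, dtype=float)
        self.block = None if block is None else np.asarray(block)
        self.contrast_name = contrast_name
        self.norm_factors = tmm_norm_factors(counts) if normalize else None
        self.logcpm = logcpm(counts, self.norm_factors)

    @classmethod
    def from_cohort(cls, counts: pd.DataFrame, samples: pd.DataFrame, mode: str,
                    subtype: str, fpkm: pd.DataFrame | None = None,
                    min_total: int = 10) -> "DEModel":
        """Build the subtype-vs-rest or within-subtype ID-vs-REL model.

        ``subtype`` mode: all samples, design [intercept, in-subtype,
        is-REL], contrast on the subtype coefficient, patient blocking.
        ``relapse`` mode: the subtype's samples only, design [intercept,
        is-REL], contrast on the REL coefficient, patient blocking.
        """
        samples = (samples.set_index("sample_id").loc[counts.columns]
                   .rename_axis("sample_id").reset_index())
        if mode == "subtype":
            sub = samples
            x_group = (sub["subtype"] == subtype).astype(float).to_numpy()
            if x_group.sum() == 0:
                raise ValueError(f"no samples with subtype {subtype}")
            x_rel = (sub["timepoint"] == "REL").astype(float).to_numpy()
            design = np.column_stack([np.ones(len(sub)), x_group, x_rel])
            contrast = np.array([0.0, 1.0, 0.0])
            cmat = counts
            name = f"{subtype} vs rest"
        elif mode == "relapse":
            mask = (samples["subtype"] == subtype).to_numpy()
            sub = samples.loc[mask]
            if len(sub) < 4:
                raise ValueError(f"too few samples in subtype {subtype}")
            x_rel = (sub["timepoint"] == "REL").astype(float).to_numpy()
            if x_rel.sum() == 0 or x_rel.sum() == len(sub):
                raise ValueError(f"subtype {subtype} lacks one of the timepoints")
            design = np.column_stack([np.ones(len(sub)), x_rel])
            contrast = np.array([0.0, 1.0])
            cmat = counts.loc[:, sub["sample_id"]]
            name = f"{subtype}: REL vs ID"
        else:
            raise ValueError("mode must be 'subtype' or 'relapse'")
        keep = detected_genes(cmat, None if fpkm is None else fpkm[cmat.columns],
                              min_total=min_total)
        block = sub["patient_id"].to_numpy()
        if pd.Series(block).value_counts().max() < 2:
            block = None
        return cls(cmat.loc[keep], design, contrast, block=block, contrast_name=name)

    def fit(self, prior_df: float | None = None, span: float = 0.5,
            trim: float = 0.15) -> DEResults:
        y = self.logcpm.to_numpy()
        w = voom_weights(y, self.design, span=span)
        if self.block is not None:
            rho = duplicate_correlation(y, w, self.design, self.block, trim=trim)
        else:
            rho = 0.0
        table = fit_moderated(y, w, self.design, self.contrast, block=self.block,
                              consensus_rho=rho, gene_ids=self.counts.index.to_numpy(),
                              prior_df=prior_df)
        d0 = table.attrs["prior_df"]
        _, s0sq, _ = _squeeze_var(table["s2"].to_numpy(), table.attrs["df_resid"])
        return DEResults(table=table, consensus_rho=rho, prior_df=d0, prior_var=s0sq,
                         df_resid=table.attrs["df_resid"], contrast_name=self.contrast_name)


def subtype_specific_de(counts, samples, subtype, fpkm=None,
                        p_max=P_MAX_DEFAULT, fc_min=FC_MIN_DEFAULT) -> pd.DataFrame:
    """One-vs-rest DE for a subtype (timepoint covariate, patient blocking);
    returns the called subset."""
    res = DEModel.from_cohort(counts, samples, "subtype", subtype, fpkm=fpkm).fit()
    return res.called(p_max=p_max, fc_min=fc_min)


def relapse_specific_de(counts, samples, subtype, fpkm=None,
                        p_max=P_MAX_DEFAULT, fc_min=FC_MIN_DEFAULT) -> pd.DataFrame:
    """Within-subtype ID-vs-REL DE with patient blocking; called subset."""
    res = DEModel.from_cohort(counts, samples, "relapse", subtype, fpkm=fpkm).fit()
    return res.called(p_max=p_max, fc_min=fc_min)
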