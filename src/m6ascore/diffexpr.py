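"""Moderated two-group differential expression with BH control.

Per gene, an ordinary two-group linear model is fit and the residual
variances are shrunk toward a common prior by empirical Bayes: the sample
variances are modeled as scaled F-distributed around a prior variance s0^2
with prior degrees of freedom d0, both estimated by moment-matching the log
sample variances. The moderated t uses the posterior variance
(d0*s0^2 + d*s^2)/(d0 + d) on d + d0 degrees of freedom. Genes are flagged
at BH-adjusted p below ``alpha_adj`` (default 0.01), with no fold-change
filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini--Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (used in the variance-prior fit)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    lo, hi = 1e-8, 1e8
    f = lambda x: special.polygamma(1, x) - y
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def fit_variance_prior(s2, df: float):
    """Moment-match log sample variances to a scaled F distribution.

    Returns ``(d0, s0_sq)``: prior degrees of freedom (may be inf) and the
    prior variance. Mirrors the standard empirical-Bayes squeeze used for
    moderated t-statistics. Zero variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() == 0:
        return np.inf, float(np.mean(s2) if s2.size else 1.0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if ok.sum() < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def squeeze_variances(s2, df: float, prior_df=None, prior_var=None):
    """Posterior (squeezed) variances; prior estimated unless supplied."""
    s2 = np.asarray(s2, dtype=float)
    if prior_df is None or prior_var is None:
        prior_df, prior_var = fit_variance_prior(s2, df)
    if np.isinf(prior_df):
        post = np.full_like(s2, prior_var)
    else:
        post = (prior_df * prior_var + df * s2) / (prior_df + df)
    return post, prior_df, prior_var


def moderated_de(expr: ExpressionMatrix, labels, alpha_adj: float = 0.01,
                 group_a="A", group_b="B", prior_df=None) -> pd.DataFrame:
    """Moderated-t differential expression between two sample groups.

    Parameters
    ----------
    expr
        Log-scale expression (typically batch-corrected and merged).
    labels
        Per-sample group labels aligned to ``expr.samples``; exactly two
        groups, each with >= 2 samples. Log2 fold change is group A minus
        group B.
    alpha_adj
        BH-adjusted significance threshold (default 0.01).
    prior_df
        Force the prior degrees of freedom (``0`` reproduces the ordinary
        pooled two-sample t); estimated from the data when None.

    Returns
    -------
    DataFrame indexed by gene: ``log2fc, t, p, p_adj, significant``.
    """
    labels = pd.Series(labels).reindex(expr.samples)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    if group_a not in uniq or group_b not in uniq:
        group_a, group_b = sorted(uniq)
    mask_a = (labels == group_a).to_numpy()
    mask_b = (labels == group_b).to_numpy()
    n1, n2 = int(mask_a.sum()), int(mask_b.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    X = expr.data.to_numpy(dtype=float)
    xa, xb = X[:, mask_a], X[:, mask_b]
    m1, m2 = xa.mean(axis=1), xb.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((xa - m1[:, None]) ** 2).sum(axis=1) + ((xb - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is not None and prior_df == 0:
        post_var, d0, _ = s2.copy(), 0.0, np.nan
    else:
        if prior_df is None:
            post_var, d0, _ = squeeze_variances(s2, df_resid)
        else:
            _, _, s0_sq = squeeze_variances(s2, df_resid)
            d0 = float(prior_df)
            post_var = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)

    stderr = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    logfc = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(stderr > 0, logfc / stderr, 0.0)
    # zero posterior variance can only happen if every variance is zero and
    # the prior collapses; the statistic is defined as 0 there, never NaN
    t = np.where(np.isfinite(t), t, 0.0)
    df_total = df_resid + (0.0 if not np.isfinite(d0) else d0)
    if np.isinf(d0):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2fc": logfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha_adj,
        },
        index=expr.genes,
    )


def significant_genes(de: pd.DataFrame) -> list:
    return de.index[de["significant"]].tolist()
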