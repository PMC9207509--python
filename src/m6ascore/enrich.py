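"""Gene-set scoring: ssGSEA, two-phenotype GSEA, TIS, immune marker sets.

Single-sample scores use the ssGSEA running-sum estimator (rank-weighted
in-set ECDF minus out-set ECDF, integrated over the ranking, weight exponent
0.25, final scores scaled by the overall range). Two-group GSEA ranks genes
by signal-to-noise, computes the weighted Kolmogorov--Smirnov enrichment
score (weight exponent 1), and obtains NES and nominal p from a phenotype
permutation null. The tumor inflammation signature (TIS) is the per-sample
mean of log10-transformed linear expression over a configured 18-gene panel.
Immune-infiltration scoring applies ssGSEA to user-supplied marker sets as a
functional stand-in for external web estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, GeneSet
from .survstat import spearman, wilcoxon_ranksum

__all__ = [
    "ssgsea_score", "gsea_two_group", "tis_score", "immune_marker_scores",
    "GseaResult",
]


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_sample(order_desc, ranks, in_set, alpha):
    """Integrated weighted running-sum for one sample (genes pre-ordered)."""
    m = in_set[order_desc]
    w = ranks[order_desc] ** alpha
    w_in = np.where(m, w, 0.0)
    denom_in = w_in.sum()
    if denom_in == 0:
        return np.nan
    p_in = np.cumsum(w_in) / denom_in
    n_out = (~m).sum()
    p_out = np.cumsum(~m) / max(n_out, 1)
    return float(np.sum(p_in - p_out))


def ssgsea_score(expr: ExpressionMatrix, sets, alpha: float = 0.25,
                 normalize: bool = True) -> pd.DataFrame:
    """Per-sample, per-set ssGSEA scores (sets as rows, samples as columns).

    Genes are ranked per sample by expression (rank-based, hence invariant
    to monotone per-sample transformations); each set's weighted running-sum
    statistic is integrated over the full ranking. With ``normalize=True``
    the whole score matrix is scaled by its overall range. A sample with
    constant expression across genes carries no ranking information and
    scores 0 for every set; a set with no member present scores NA with a
    warning.
    """
    X = expr.data.to_numpy(dtype=float)
    genes = expr.genes
    n_genes, n_samples = X.shape
    memberships = []
    names = []
    for s in sets:
        mask = np.asarray(genes.isin(s.members))
        if mask.sum() == 0:
            warnings.warn(f"gene set '{s.name}': no members present", UserWarning)
        memberships.append(mask)
        names.append(s.name)

    out = np.full((len(names), n_samples), np.nan)
    for j in range(n_samples):
        col = X[:, j]
        if np.ptp(col) == 0:
            out[:, j] = [0.0 if m.any() else np.nan for m in memberships]
            continue
        ranks = stats.rankdata(col, method="average")  # 1 = lowest expression
        order_desc = np.argsort(-col, kind="stable")
        for i, m in enumerate(memberships):
            if not m.any():
                continue
            out[i, j] = _ssgsea_sample(order_desc, ranks, m, alpha)
    if normalize:
        finite = out[np.isfinite(out)]
        if finite.size and np.ptp(finite) > 0:
            out = out / np.ptp(finite)
    return pd.DataFrame(out, index=pd.Index(names, name="set"), columns=expr.samples)


# ---------------------------------------------------------------------------
# two-group GSEA
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    """Per-set enrichment: ES, NES, nominal permutation p, significance flag
    (|NES| > nes_min and p < alpha)."""

    table: pd.DataFrame
    nes_min: float
    alpha: float


def _signal_to_noise(X, mask_a, mask_b):
    m1 = X[:, mask_a].mean(axis=1)
    m2 = X[:, mask_b].mean(axis=1)
    s1 = X[:, mask_a].std(axis=1, ddof=1)
    s2 = X[:, mask_b].std(axis=1, ddof=1)
    # Broad-style SD floor keeps constant genes from dominating the ranking
    s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 1e-8))
    s2 = np.maximum(s2, np.maximum(0.2 * np.abs(m2), 1e-8))
    return (m1 - m2) / (s1 + s2)


def _es_all_sets(metric, membership, weight_exp=1.0):
    """Weighted KS enrichment scores for every set under one gene ranking.

    ``membership``: (n_sets, n_genes) boolean. Returns (n_sets,) signed ES.
    """
    order = np.argsort(-metric, kind="stable")
    w = np.abs(metric[order]) ** weight_exp
    M = membership[:, order]
    w_in = M * w
    denom_in = w_in.sum(axis=1, keepdims=True)
    denom_in = np.where(denom_in > 0, denom_in, 1.0)
    p_hit = np.cumsum(w_in, axis=1) / denom_in
    n_out = (~M).sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~M, axis=1) / np.maximum(n_out, 1)
    dev = p_hit - p_miss
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


def gsea_two_group(expr: ExpressionMatrix, labels, sets, n_perm: int = 1000,
                   seed: int = 0, nes_min: float = 1.0, alpha: float = 0.05,
                   weight_exp: float = 1.0) -> GseaResult:
    """Two-phenotype GSEA with a permutation null.

    Genes are ranked by signal-to-noise between the two groups; the weighted
    KS enrichment score of each set is normalized against the mean |ES| of
    same-sign phenotype permutations (NES) and the nominal p is the same-sign
    permutation tail. With a group smaller than 3 samples, phenotype
    permutation is infeasible and gene-set permutation is used instead (with
    a warning).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = pd.Series(labels).reindex(expr.samples)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    mask_a = (labels == uniq[0]).to_numpy()
    mask_b = ~mask_a
    X = expr.data.to_numpy(dtype=float)
    genes = expr.genes
    membership = np.vstack([np.asarray(genes.isin(s.members)) for s in sets])
    names = [s.name for s in sets]
    empty = membership.sum(axis=1) == 0
    if empty.any():
        bad = [n for n, e in zip(names, empty) if e]
        warnings.warn(f"sets with no members present: {bad}", UserWarning)

    metric = _signal_to_noise(X, mask_a, mask_b)
    es = _es_all_sets(metric, membership, weight_exp)

    rng = np.random.default_rng(seed)
    n = X.shape[1]
    n_a = int(mask_a.sum())
    use_geneset_perm = min(n_a, n - n_a) < 3
    null = np.empty((n_perm, len(names)))
    if use_geneset_perm:
        warnings.warn(
            "group smaller than 3: falling back to gene-set permutation",
            UserWarning,
        )
        sizes = membership.sum(axis=1)
        for p_i in range(n_perm):
            perm_membership = np.zeros_like(membership)
            for s_i, size in enumerate(sizes):
                if size > 0:
                    pick = rng.choice(len(genes), size=size, replace=False)
                    perm_membership[s_i, pick] = True
            null[p_i] = _es_all_sets(metric, perm_membership, weight_exp)
    else:
        for p_i in range(n_perm):
            perm = rng.permutation(n)
            pa = np.zeros(n, dtype=bool)
            pa[perm[:n_a]] = True
            pm = _signal_to_noise(X, pa, ~pa)
            null[p_i] = _es_all_sets(pm, membership, weight_exp)

    nes = np.full(len(names), np.nan)
    pvals = np.full(len(names), np.nan)
    for i in range(len(names)):
        if empty[i]:
            continue
        obs = es[i]
        same = null[:, i][np.sign(null[:, i]) == np.sign(obs)] if obs != 0 else null[:, i]
        if same.size == 0:
            same = np.abs(null[:, i])
        denom = np.mean(np.abs(same))
        nes[i] = obs / denom if denom > 0 else 0.0
        pvals[i] = (1.0 + np.sum(np.abs(same) >= abs(obs))) / (1.0 + same.size)
    flag = (np.abs(nes) > nes_min) & (pvals < alpha)
    table = pd.DataFrame(
        {"es": es, "nes": nes, "p": pvals, "significant": flag},
        index=pd.Index(names, name="set"),
    )
    return GseaResult(table=table, nes_min=nes_min, alpha=alpha)


# ---------------------------------------------------------------------------
# TIS
# ---------------------------------------------------------------------------

def tis_score(expr_linear: ExpressionMatrix, tis_genes, pseudocount: float = 0.0
              ) -> pd.Series:
    """Tumor inflammation signature: per-sample mean of log10 expression.

    ``expr_linear`` must be on a linear scale; the 18 configured panel genes
    must all be present (the panel is a required input, not hardcoded).
    """
    tis_genes = list(tis_genes)
    missing = [g for g in tis_genes if g not in expr_linear.genes]
    if missing:
        raise KeyError(f"TIS genes absent from expression matrix: {missing}")
    V = expr_linear.data.loc[tis_genes].to_numpy(dtype=float)
    if (V + pseudocount <= 0).any():
        raise ValueError("non-positive values under log10; increase pseudocount")
    return pd.Series(
        np.log10(V + pseudocount).mean(axis=0), index=expr_linear.samples,
        name="tis",
    )


# ---------------------------------------------------------------------------
# immune marker scoring
# ---------------------------------------------------------------------------

def immune_marker_scores(expr: ExpressionMatrix, marker_sets,
                         scores: pd.Series = None, groups: pd.Series = None):
    """Marker-set ssGSEA as cell-type abundance, with optional reporting.

    Returns ``(cell_scores, report)``: per-sample per-cell-type ssGSEA
    scores, plus — when an m6A ``scores`` series and/or high-low ``groups``
    are provided — a per-cell-type table of Spearman correlation with the
    score and the Wilcoxon p of the high-vs-low group difference.
    """
    cell_scores = ssgsea_score(expr, marker_sets)
    report = None
    if scores is not None or groups is not None:
        rows = {}
        for name, row in cell_scores.iterrows():
            entry = {}
            valid = row.dropna()
            if scores is not None and len(valid) >= 2:
                rho, p = spearman(
                    scores.reindex(valid.index).to_numpy(), valid.to_numpy()
                )
                entry["spearman_rho"], entry["spearman_p"] = rho, p
            if groups is not None and len(valid) >= 4:
                g = groups.reindex(valid.index)
                hi = valid[g == "high"].to_numpy()
                lo = valid[g == "low"].to_numpy()
                if len(hi) >= 2 and len(lo) >= 2:
                    entry["wilcoxon_p"] = wilcoxon_ranksum(hi, lo)
            rows[name] = entry
        report = pd.DataFrame(rows).T
    return cell_scores, report


def make_gene_set(name: str, members, description: str = "") -> GeneSet:
    return GeneSet(name=name, members=tuple(members), description=description)
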