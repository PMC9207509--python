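"""The m6A scoring model: gene trimming, PCA fit, scoring, cutpoint, sign.

The score condenses the prognostic cluster-differential genes into one
number per patient: genes are z-scored on the training cohort, the first two
principal components are extracted, and the m6A score of a sample is the sum
of its PC1 and PC2 sample scores. Upstream, a random-forest classifier
removes DEGs redundant for separating the clusters (permutation importance
above the median is kept) and a univariate Cox filter keeps genes with Wald
p below 0.05. The score is dichotomized at a maximally selected log-rank
cutpoint and oriented so that LOW score means worse prognosis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .dataio import ClinicalTable, ExpressionMatrix
from .survstat import cox_univariate, km_median_or_rmst, logrank_z


# ---------------------------------------------------------------------------
# gene trimming
# ---------------------------------------------------------------------------

def rf_redundancy_filter(expr_deg: ExpressionMatrix, labels, n_trees: int = 500,
                         seed: int = 0, n_repeats: int = 5,
                         min_genes: int = 10,
                         threshold_quantile: float = 0.5) -> list:
    """Drop DEGs that a random forest finds uninformative for the clusters.

    A bootstrap random-forest classifier (sqrt(p) features per split)
    predicts the cluster labels from the DEG matrix; genes are ranked by
    permutation importance and those above the ``threshold_quantile`` of the
    importance distribution (default: the median) are kept. A higher
    quantile prunes more aggressively when most DEGs are noise. With fewer
    than ``min_genes`` DEGs the filter is skipped with a warning.
    """
    genes = list(expr_deg.genes)
    if len(genes) < min_genes:
        warnings.warn(
            f"only {len(genes)} DEGs (<{min_genes}): redundancy filter skipped",
            UserWarning,
        )
        return genes
    labels = pd.Series(labels).reindex(expr_deg.samples)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    X = expr_deg.data.to_numpy(dtype=float).T
    y = labels.to_numpy()
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        random_state=seed, n_jobs=1,
    )
    rf.fit(X, y)
    # log-loss scoring keeps the importance signal when features are so
    # redundant that permuting one never flips a hard class prediction
    imp = permutation_importance(
        rf, X, y, n_repeats=n_repeats, random_state=seed, n_jobs=1,
        scoring="neg_log_loss",
    ).importances_mean
    if np.ptp(imp) == 0:
        warnings.warn("permutation importances all equal: filter keeps all genes",
                      UserWarning)
        return genes
    keep = imp > np.quantile(imp, threshold_quantile)
    return [g for g, k in zip(genes, keep) if k]


def cox_univariate_filter(expr: ExpressionMatrix, clinical: ClinicalTable,
                          genes, alpha: float = 0.05) -> list:
    """Keep genes whose standardized expression is prognostic at Wald p<alpha.

    Each gene enters a univariate Cox proportional-hazards fit (Efron ties,
    Newton--Raphson on the partial likelihood). Non-converging genes are
    dropped with a warning.
    """
    clin = clinical.aligned_to(expr.samples).table
    times = clin["os_time"].to_numpy(float)
    events = clin["os_event"].to_numpy(int)
    kept = []
    for g in genes:
        x = expr.data.loc[g].to_numpy(float)
        sd = x.std()
        if sd == 0:
            warnings.warn(f"gene {g}: zero variance, dropped", UserWarning)
            continue
        x = (x - x.mean()) / sd
        try:
            _, _, p = cox_univariate(times, events, x)
        except Exception as err:  # non-convergence
            warnings.warn(f"gene {g}: Cox fit failed ({err}), dropped", UserWarning)
            continue
        if p < alpha:
            kept.append(g)
    return kept


# ---------------------------------------------------------------------------
# PCA scoring model
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Frozen scoring artifact.

    ``loadings`` is a (2, n_genes) array of unit-norm, mutually orthogonal
    PC loading vectors; each PC's sign is fixed so its largest-magnitude
    loading is positive, and ``orientation`` records a subsequent global
    sign flip (prognostic convention: low score = worse outcome).
    """

    genes: list
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    orientation: float = 1.0
    cutoff: float = None

    def __post_init__(self) -> None:
        if (np.asarray(self.sds) <= 0).any():
            raise ValueError("standardization SDs must be positive")
        norms = np.linalg.norm(self.loadings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loadings must be unit norm")
        if abs(float(self.loadings[0] @ self.loadings[1])) > 1e-9:
            raise ValueError("loadings must be orthogonal")

    def flip(self) -> None:
        """Reverse the sign convention of both PCs (and the cutoff)."""
        self.orientation = -self.orientation
        if self.cutoff is not None:
            self.cutoff = -self.cutoff

    def to_json(self, path) -> None:
        payload = {
            "genes": list(self.genes),
            "means": np.asarray(self.means).tolist(),
            "sds": np.asarray(self.sds).tolist(),
            "loadings": np.asarray(self.loadings).tolist(),
            "explained_variance_ratio":
                np.asarray(self.explained_variance_ratio).tolist(),
            "orientation": self.orientation,
            "cutoff": self.cutoff,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            genes=d["genes"], means=np.array(d["means"]), sds=np.array(d["sds"]),
            loadings=np.array(d["loadings"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            orientation=d.get("orientation", 1.0), cutoff=d.get("cutoff"),
        )


@dataclass
class ScoreTable:
    """Per-sample m6A score with optional high/low dichotomization."""

    scores: pd.Series
    cutoff: float = None
    group: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.cutoff is not None and self.group is None:
            self.group = pd.Series(
                np.where(self.scores > self.cutoff, "high", "low"),
                index=self.scores.index, name="group",
            )
        if self.group is not None and self.cutoff is not None:
            expect = self.scores > self.cutoff
            if not ((self.group == "high") == expect).all():
                raise ValueError("group must equal (score > cutoff)")

    def to_tsv(self, path) -> None:
        out = self.scores.rename("m6a_score").to_frame()
        if self.group is not None:
            out["group"] = self.group
        if self.cutoff is not None:
            out["cutoff"] = self.cutoff
        out.index.name = "sample"
        out.to_csv(path, sep="\t", float_format="%.10g")


class M6AScorer(BaseEstimator, TransformerMixin):
    """PCA-based m6A scorer (fit on a training cohort, score any cohort).

    ``fit`` z-scores each signature gene on the training cohort and extracts
    the top-2 principal components (deterministic sign convention). The
    score of a sample is the sum of its PC1 and PC2 projections. When
    scoring a new cohort the signature genes are z-scored per cohort and
    projected on the frozen training loadings (``refit_mode="frozen"``,
    default, portable across platforms); ``refit_mode="refit"`` re-runs PCA
    on the new cohort instead.

    Attributes
    ----------
    model_ : SignatureModel
    """

    def __init__(self, min_gene_fraction: float = 0.8, refit_mode: str = "frozen"):
        self.min_gene_fraction = min_gene_fraction
        self.refit_mode = refit_mode

    def fit(self, X, y=None, genes=None):
        """Fit on samples-x-genes ``X`` (DataFrame or array + ``genes``)."""
        if isinstance(X, pd.DataFrame):
            genes = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            genes = list(genes) if genes is not None else list(range(X.shape[1]))
        if X.shape[1] < 2:
            raise ValueError("signature needs at least 2 genes")
        if X.shape[0] < 3:
            raise ValueError("signature fit needs at least 3 samples")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        if (sds <= 0).any():
            bad = [g for g, s in zip(genes, sds) if s <= 0]
            raise ValueError(f"zero-variance signature genes: {bad}")
        Z = (X - means) / sds
        pca = PCA(n_components=2, svd_solver="full")
        pca.fit(Z)
        loadings = pca.components_.copy()
        for i in range(2):
            j = int(np.argmax(np.abs(loadings[i])))
            if loadings[i, j] < 0:
                loadings[i] = -loadings[i]
        self.model_ = SignatureModel(
            genes=genes, means=means, sds=sds, loadings=loadings,
            explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Score samples-x-genes ``X`` (columns must cover >=80% of genes)."""
        model = self.model_
        if isinstance(X, pd.DataFrame):
            present = [g for g in model.genes if g in X.columns]
            frac = len(present) / len(model.genes)
            if frac < self.min_gene_fraction:
                missing = [g for g in model.genes if g not in X.columns]
                raise ValueError(
                    f"only {frac:.0%} of signature genes present; missing: {missing}"
                )
            cols = [model.genes.index(g) for g in present]
            V = X[present].to_numpy(dtype=float)
        else:
            V = np.asarray(X, dtype=float)
            cols = list(range(len(model.genes)))
        if self.refit_mode == "frozen":
            mu = V.mean(axis=0)
            sd = V.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            Z = (V - mu) / sd
            W = model.loadings[:, cols]
            norms = np.linalg.norm(W, axis=1)
            W = W / norms[:, None]  # renormalize over present genes
            proj = Z @ W.T
        elif self.refit_mode == "refit":
            sub = M6AScorer().fit(
                pd.DataFrame(V, columns=[model.genes[c] for c in cols])
            )
            W = sub.model_.loadings
            mu = sub.model_.means
            sd = sub.model_.sds
            proj = ((V - mu) / sd) @ W.T
        else:
            raise ValueError(f"unknown refit_mode {self.refit_mode!r}")
        return model.orientation * (proj[:, 0] + proj[:, 1])

    def transform_training(self, X) -> np.ndarray:
        """Score the training cohort with the training standardization."""
        model = self.model_
        if isinstance(X, pd.DataFrame):
            X = X[model.genes].to_numpy(dtype=float)
        Z = (np.asarray(X, dtype=float) - model.means) / model.sds
        proj = Z @ model.loadings.T
        return model.orientation * (proj[:, 0] + proj[:, 1])


def fit_signature(expr: ExpressionMatrix, genes) -> SignatureModel:
    """Fit the PCA scoring model on signature ``genes`` of a training cohort."""
    sub = expr.subset_genes(genes)
    scorer = M6AScorer()
    scorer.fit(sub.data.T)
    return scorer.model_


def score_samples(expr: ExpressionMatrix, model: SignatureModel,
                  training: bool = False, refit_mode: str = "frozen") -> ScoreTable:
    """Score every sample of ``expr`` with a fitted :class:`SignatureModel`.

    ``training=True`` reuses the frozen training means/SDs (exact training
    scores); otherwise genes are z-scored within the cohort being scored and
    projected on the frozen loadings (or refit when ``refit_mode="refit"``).
    """
    scorer = M6AScorer(refit_mode=refit_mode)
    scorer.model_ = model
    frame = expr.data.T  # samples x genes
    if training:
        values = scorer.transform_training(frame)
    else:
        values = scorer.transform(frame)
    scores = pd.Series(values, index=expr.samples, name="m6a_score")
    return ScoreTable(scores=scores, cutoff=model.cutoff)


# ---------------------------------------------------------------------------
# cutpoint and orientation
# ---------------------------------------------------------------------------

def optimal_cutoff(scores, clinical: ClinicalTable, minprop: float = 0.1) -> float:
    """Maximally selected log-rank cutpoint.

    Every candidate split leaving at least ``minprop`` of the samples on each
    side is evaluated by the standardized two-group log-rank statistic; the
    candidate with the largest |z| wins (the cutoff value is the largest
    score of the low group). Raises when no candidate satisfies ``minprop``
    or fewer than two events exist.
    """
    scores = pd.Series(scores.scores if isinstance(scores, ScoreTable) else scores)
    clin = clinical.aligned_to(scores.index).table
    times = clin["os_time"].to_numpy(float)
    events = clin["os_event"].to_numpy(int)
    if events.sum() < 2:
        raise ValueError("need at least two events for cutpoint selection")
    s = scores.to_numpy(float)
    n = len(s)
    candidates = np.unique(s)[:-1]  # split at score <= c vs > c
    lo_n = np.searchsorted(np.sort(s), candidates, side="right")
    ok = (lo_n >= minprop * n) & (n - lo_n >= minprop * n)
    candidates = candidates[ok]
    if candidates.size == 0:
        raise ValueError("no cutpoint satisfies the minimum group proportion")

    # accumulate O-E and hypergeometric variance of the high group for every
    # candidate at once: at each event time only the counts of at-risk /
    # dying samples with score above each candidate are needed
    O = np.zeros(candidates.size)
    E = np.zeros(candidates.size)
    V = np.zeros(candidates.size)
    for et in np.unique(times[events == 1]):
        risk = times >= et
        dead = (times == et) & (events == 1)
        n_tot = int(risk.sum())
        d_tot = int(dead.sum())
        risk_scores = np.sort(s[risk])
        dead_scores = np.sort(s[dead])
        n_hi = n_tot - np.searchsorted(risk_scores, candidates, side="right")
        d_hi = d_tot - np.searchsorted(dead_scores, candidates, side="right")
        O += d_hi
        frac = n_hi / n_tot
        E += d_tot * frac
        if n_tot > 1:
            V += d_tot * frac * (1 - frac) * (n_tot - d_tot) / (n_tot - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(V > 0, np.abs(O - E) / np.sqrt(V), 0.0)
    return float(candidates[int(np.argmax(z))])


def orient_score(scores: ScoreTable, clinical: ClinicalTable,
                 model: SignatureModel = None) -> ScoreTable:
    """Fix the sign convention: LOW score must mean worse prognosis.

    If on the training data the high-score group survives shorter than the
    low-score group, scores (and the cutoff, and the model's PCs when
    supplied) are negated. Idempotent on already-oriented scores.
    """
    if scores.cutoff is None:
        raise ValueError("orientation needs a dichotomized ScoreTable")
    clin = clinical.aligned_to(scores.scores.index).table
    med = {}
    for grp in ("low", "high"):
        members = scores.group.index[scores.group == grp]
        med[grp] = km_median_or_rmst(
            clin.loc[members, "os_time"], clin.loc[members, "os_event"]
        )
    if med["high"] < med["low"]:
        if model is not None:
            model.flip()
        return ScoreTable(scores=-scores.scores, cutoff=-scores.cutoff)
    return scores
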