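"""Expression/clinical/gene-set I/O and empirical-Bayes batch correction.

The in-memory substrate of the whole pipeline is :class:`ExpressionMatrix`, a
gene-by-sample matrix of log-scale expression (log2 microarray intensities or
log2(FPKM+1)) with a per-sample cohort (batch) annotation, plus a matching
:class:`ClinicalTable` of censored overall-survival data.

Cross-cohort merging uses a parametric location--scale empirical-Bayes
adjustment (the ComBat algorithm): per-gene standardization against the grand
mean and pooled variance, per-batch location/scale estimates shrunk toward
normal / inverse-gamma priors with moment-matched hyperparameters, then
back-transformation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


class DataFormatError(ValueError):
    """Raised for malformed expression, clinical or gene-set files."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log-scale gene-by-sample expression with batch annotations.

    Parameters
    ----------
    data
        DataFrame with unique gene symbols as index and unique sample IDs as
        columns; all values finite floats on a log scale.
    batch
        Per-sample cohort label, indexed like ``data.columns``. A single
        shared label is used when cohort information is absent.
    """

    data: pd.DataFrame
    batch: pd.Series = None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate gene symbols: {dups}")
        if self.data.columns.duplicated().any():
            raise DataFormatError("duplicate sample IDs")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise DataFormatError("expression matrix contains non-finite values")
        if self.batch is None:
            self.batch = pd.Series("batch0", index=self.data.columns)
        self.batch = pd.Series(self.batch, dtype=object).reindex(self.data.columns)
        if self.batch.isna().any():
            missing = self.batch.index[self.batch.isna()].tolist()
            raise DataFormatError(f"samples without batch label: {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order preserved); missing symbols raise."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes].copy(), self.batch.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data[samples].copy(), self.batch.loc[samples].copy())

    def to_tsv(self, path, batch_path=None) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")  # default float repr round-trips exactly
        if batch_path is not None:
            b = self.batch.rename("batch").to_frame()
            b.index.name = "sample"
            b.to_csv(batch_path, sep="\t")


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate table.

    ``table`` is indexed by sample ID with columns ``os_time`` (years, > 0),
    ``os_event`` (0/1) and optionally ``age``, ``stage``, ``ldh``, ``batch``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.table.columns:
                raise DataFormatError(f"clinical table lacks required column '{col}'")
        if self.table.index.duplicated().any():
            raise DataFormatError("duplicate sample IDs in clinical table")
        t = self.table["os_time"].to_numpy(float)
        if not np.isfinite(t).all() or (t <= 0).any():
            raise DataFormatError("os_time must be finite and positive")
        e = self.table["os_event"].to_numpy()
        if not np.isin(e, [0, 1]).all():
            raise DataFormatError("os_event must be 0/1")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def aligned_to(self, samples) -> "ClinicalTable":
        """Reorder to ``samples``; samples without clinical data raise."""
        samples = list(samples)
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise KeyError(f"samples without clinical data: {missing}")
        return ClinicalTable(self.table.loc[samples].copy())

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


@dataclass
class GeneSet:
    """A named set of gene symbols (>= 1 unique member)."""

    name: str
    members: tuple = field(default_factory=tuple)
    description: str = ""

    def __post_init__(self) -> None:
        seen: dict = {}
        for m in self.members:
            seen.setdefault(m, None)
        self.members = tuple(seen)
        if len(self.members) == 0:
            raise DataFormatError(f"gene set '{self.name}' has no members")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, batch_label="batch0") -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene symbol, header sample IDs).

    Duplicate gene symbols are collapsed to the row with the highest mean
    expression (the usual probe-collapse convention for microarrays).
    Non-numeric or missing cells are rejected with their coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataFormatError(f"{path}: empty expression table")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{path}: non-numeric or missing value at gene '{df.index[r]}', "
            f"sample '{df.columns[c]}'"
        )
    numeric = numeric.astype(float)
    if numeric.index.duplicated().any():
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        numeric = numeric.iloc[order]
        numeric = numeric[~numeric.index.duplicated(keep="first")]
    batch = pd.Series(batch_label, index=numeric.columns)
    return ExpressionMatrix(numeric, batch)


def read_clinical(path, batch_label=None) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if batch_label is not None and "batch" not in df.columns:
        df["batch"] = batch_label
    return ClinicalTable(df)


def merge_expression(matrices) -> ExpressionMatrix:
    """Concatenate cohorts on their common genes (inner join on symbols)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to merge")
    common = matrices[0].genes
    for m in matrices[1:]:
        common = common.intersection(m.genes)
    if len(common) == 0:
        raise DataFormatError("cohorts share no gene symbols")
    data = pd.concat([m.data.loc[common] for m in matrices], axis=1)
    batch = pd.concat([m.batch for m in matrices])
    return ExpressionMatrix(data, batch)


def read_gmt(path) -> list:
    """Parse a Broad-dialect GMT file: name <tab> description <tab> members...

    Duplicate members within a set are dropped; a set with an empty member
    list is an error reported with its line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            members = [m for m in fields[2:] if m.strip()]
            if not members:
                raise DataFormatError(f"{path}:{lineno}: gene set '{name}' is empty")
            sets.append(GeneSet(name=name, members=tuple(members), description=desc))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.members]) + "\n")


# ---------------------------------------------------------------------------
# empirical-Bayes batch correction (parametric ComBat)
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted batch-adjustment constants.

    ``gamma_star`` / ``delta_star`` are (n_batches, n_genes) arrays of shrunken
    per-batch location and scale adjustments on the standardized scale;
    ``grand_mean`` and ``pooled_var`` are the per-gene standardization
    constants. Scale adjustments are strictly positive.
    """

    batches: list
    gamma_star: np.ndarray
    delta_star: np.ndarray
    grand_mean: np.ndarray
    pooled_var: np.ndarray

    def __post_init__(self) -> None:
        if (self.delta_star <= 0).any():
            raise ValueError("scale adjustments must be positive")

    def to_json(self, path, genes=None) -> None:
        payload = {
            "batches": list(self.batches),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
        }
        if genes is not None:
            payload["genes"] = list(genes)
        with open(path, "w") as fh:
            json.dump(payload, fh)


class ComBat(BaseEstimator):
    """Parametric empirical-Bayes location--scale batch adjustment.

    Standardizes each gene against its batch-design grand mean and pooled
    variance, estimates per-batch location (``gamma``) and scale (``delta^2``)
    effects, shrinks them toward a normal prior (location) and an
    inverse-gamma prior (scale) with moment-matched hyperparameters, and
    adjusts the data on the original scale. No covariate preservation terms.

    Parameters
    ----------
    conv : float
        Convergence threshold of the iterative posterior solve.

    Attributes
    ----------
    model_ : BatchModel
        Shrunken adjustments and standardization constants.
    """

    def __init__(self, conv: float = 1e-4):
        self.conv = conv

    def fit(self, X, batches):
        """Estimate batch effects from ``X`` (samples x genes) and labels."""
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        labels, inv = np.unique(batches, return_inverse=True)
        n_batches = len(labels)
        n, g = X.shape
        if n_batches < 2:
            warnings.warn("single batch: adjustment is the identity", UserWarning)
        sizes = np.bincount(inv)
        if (sizes < 2).any():
            small = labels[sizes < 2].tolist()
            raise ValueError(f"batches with a single sample cannot be adjusted: {small}")

        # per-gene batch means and design-based grand mean / pooled variance
        batch_means = np.vstack([X[inv == i].mean(axis=0) for i in range(n_batches)])
        grand_mean = (sizes / n) @ batch_means
        fitted = batch_means[inv]
        pooled_var = ((X - fitted) ** 2).sum(axis=0) / n
        pooled_var = np.maximum(pooled_var, 1e-12)

        Z = (X - grand_mean) / np.sqrt(pooled_var)

        gamma_hat = np.vstack([Z[inv == i].mean(axis=0) for i in range(n_batches)])
        delta_hat = np.vstack([Z[inv == i].var(axis=0, ddof=1) for i in range(n_batches)])
        delta_hat = np.maximum(delta_hat, 1e-12)

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(n_batches):
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var(ddof=1) if g > 1 else 1.0
            m = delta_hat[i].mean()
            s2 = delta_hat[i].var(ddof=1) if g > 1 else 1.0
            if s2 <= 1e-12:
                # degenerate scale prior (all per-gene scales identical):
                # no scale shrinkage needed; one-step location posterior
                ni = int(sizes[i])
                gamma_star[i] = (
                    (t2 * ni * gamma_hat[i] + delta_hat[i] * g_bar)
                    / (t2 * ni + delta_hat[i])
                )
                delta_star[i] = delta_hat[i]
                continue
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            gamma_star[i], delta_star[i] = self._it_sol(
                Z[inv == i], gamma_hat[i], delta_hat[i],
                g_bar, t2, a_prior, b_prior,
            )

        self.model_ = BatchModel(
            batches=list(labels),
            gamma_star=gamma_star,
            delta_star=delta_star,
            grand_mean=grand_mean,
            pooled_var=pooled_var,
        )
        return self

    def _it_sol(self, z_batch, g_hat, d_hat, g_bar, t2, a, b):
        """Iterative EB posterior solve for one batch (all genes at once)."""
        n = z_batch.shape[0]
        g_old, d_old = g_hat.copy(), d_hat.copy()
        for _ in range(500):
            g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
            sum2 = ((z_batch - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < self.conv:
                break
        return g_old, np.maximum(d_old, 1e-12)

    def transform(self, X, batches):
        """Apply the fitted adjustment to ``X`` (samples x genes)."""
        m = self.model_
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        lookup = {b: i for i, b in enumerate(m.batches)}
        unknown = sorted({b for b in batches if b not in lookup})
        if unknown:
            raise KeyError(f"batches not seen during fit: {unknown}")
        idx = np.array([lookup[b] for b in batches])
        Z = (X - m.grand_mean) / np.sqrt(m.pooled_var)
        Zadj = (Z - m.gamma_star[idx]) / np.sqrt(m.delta_star[idx])
        return Zadj * np.sqrt(m.pooled_var) + m.grand_mean

    def fit_transform(self, X, batches):
        return self.fit(X, batches).transform(X, batches)


def combat_adjust(expr: ExpressionMatrix, conv: float = 1e-4):
    """Batch-adjust an :class:`ExpressionMatrix`; returns (adjusted, BatchModel).

    A single-batch matrix is returned unchanged with a warning. Each batch
    must contain at least two samples.
    """
    est = ComBat(conv=conv)
    n_batches = expr.batch.nunique()
    if n_batches < 2:
        warnings.warn("single batch: returning input unchanged", UserWarning)
        est.fit(expr.data.to_numpy().T, expr.batch.to_numpy())
        return expr, est.model_
    adjusted = est.fit_transform(expr.data.to_numpy().T, expr.batch.to_numpy())
    out = pd.DataFrame(adjusted.T, index=expr.genes, columns=expr.samples)
    return ExpressionMatrix(out, expr.batch.copy()), est.model_
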