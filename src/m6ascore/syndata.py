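"""Synthetic multi-cohort generators with recorded ground truth.

The generator emulates the statistical structure the analysis assumes:

* two latent patient clusters (A worse, B better) assigned Bernoulli(0.5);
* a continuous per-sample latent severity score centered on the cluster
  means, which drives the expression of the regulator panel and of a block
  of cluster-differential genes;
* log-scale baseline expression ``N(8, 1)`` per gene with unit within-gene
  noise, so effect sizes are in SD units;
* additive per-cohort (batch) offsets;
* exponential survival with cluster-dependent proportional hazards and
  independent exponential censoring;
* for response cohorts, a binary response whose log-odds shift with the
  latent score, plus a neoantigen-burden value correlated with it.

Ground truth (cluster labels, latent scores, true hazard ratio, truly
differential genes) is stored separately from the observables so that no
analysis stage can leak it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataio import ClinicalTable, ExpressionMatrix

#: default m6A regulator panel: 8 writers, 7 readers, 1 eraser
DEFAULT_REGULATORS = (
    "WTAP", "RBM15", "RBM15B", "ZC3H13", "METTL3", "METTL14", "KIAA1429", "CBLL1",
    "HNRNPC", "HNRNPA2B1", "YTHDC1", "YTHDF2", "IGF2BP1", "ELAVL1", "LRPPRC",
    "ALKBH5",
)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the scale of the source study design: three cohorts of
    117 samples (~351 patients), a 16-gene regulator panel, a block of 200
    cluster-differential genes among 2000, a baseline hazard giving a median
    overall survival around 14 years for the better cluster, and a true
    hazard ratio of 2 for cluster A vs B. ``cluster_shift`` and
    ``batch_shift`` are in within-gene SD units.
    """

    n_samples: int = 117          # per cohort
    n_cohorts: int = 3
    n_genes: int = 2000
    n_regulators: int = 16
    n_deg: int = 200
    cluster_shift: float = 2.0
    batch_shift: float = 1.0
    hazard_ratio_true: float = 2.0
    baseline_hazard: float = 0.05  # events / year for cluster B
    censor_rate: float = 0.04      # rate of the exponential censoring time
    response_effect: float = 2.0   # log-odds of response per latent-score SD
    neoantigen_corr: float = -0.4  # sign/strength of burden vs latent score
    latent_sd: float = 0.5         # within-cluster SD of the latent score
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples, "n_cohorts": self.n_cohorts,
            "n_genes": self.n_genes, "n_regulators": self.n_regulators,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_deg < 0:
            raise ValueError("n_deg must be >= 0")
        if self.n_genes < self.n_regulators + self.n_deg:
            raise ValueError("n_genes must cover regulators plus DEG block")
        floats = {
            "cluster_shift": self.cluster_shift, "batch_shift": self.batch_shift,
            "hazard_ratio_true": self.hazard_ratio_true,
            "baseline_hazard": self.baseline_hazard,
            "censor_rate": self.censor_rate,
            "response_effect": self.response_effect,
            "neoantigen_corr": self.neoantigen_corr, "latent_sd": self.latent_sd,
        }
        for name, v in floats.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.cluster_shift < 0:
            raise ValueError("cluster_shift must be >= 0")
        if self.hazard_ratio_true <= 0:
            raise ValueError("hazard_ratio_true must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth stored alongside a synthetic cohort."""

    cluster: pd.Series            # {"A", "B"} per sample
    latent_score: pd.Series       # continuous severity score per sample
    hazard_ratio: float
    differential_genes: list      # genes truly shifted between clusters

    def to_json(self, path) -> None:
        payload = {
            "cluster": self.cluster.to_dict(),
            "latent_score": self.latent_score.astype(float).to_dict(),
            "hazard_ratio": float(self.hazard_ratio),
            "differential_genes": list(self.differential_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: CohortTruth
    config: SimulationConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        s = self.expression.samples
        if not (s.equals(self.clinical.samples) and s.equals(self.truth.cluster.index)):
            raise ValueError("sample identifiers differ between expression/clinical/truth")
        if not set(self.truth.cluster.unique()) <= {"A", "B"}:
            raise ValueError("truth cluster labels must be in {A, B}")

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.expression.to_tsv(
            os.path.join(outdir, "expression.tsv"), os.path.join(outdir, "batch.tsv")
        )
        self.clinical.to_tsv(os.path.join(outdir, "clinical.tsv"))
        self.truth.to_json(os.path.join(outdir, "truth.json"))


def _gene_names(config: SimulationConfig):
    regs = list(DEFAULT_REGULATORS[: config.n_regulators])
    regs += [f"REG{i:03d}" for i in range(len(regs), config.n_regulators)]
    degs = [f"DEG{i:04d}" for i in range(config.n_deg)]
    n_noise = config.n_genes - config.n_regulators - config.n_deg
    noise = [f"GENE{i:05d}" for i in range(n_noise)]
    return regs, degs, noise


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a multi-cohort expression + survival dataset.

    Cluster A samples carry ``cluster_shift`` extra expression on the
    regulator and DEG genes (through the latent score), every cohort after
    the first carries an additive ``batch_shift`` offset on all genes, and
    survival is exponential with hazard
    ``baseline_hazard * hazard_ratio_true ** (cluster == A)`` under
    independent exponential censoring.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_samples * config.n_cohorts
    regs, degs, noise = _gene_names(config)
    genes = regs + degs + noise

    sample_ids = pd.Index([f"S{i:04d}" for i in range(n_total)], name="sample")
    cohorts = np.repeat([f"cohort{i}" for i in range(config.n_cohorts)], config.n_samples)

    is_a = rng.random(n_total) < 0.5
    cluster = pd.Series(np.where(is_a, "A", "B"), index=sample_ids)

    # latent severity: cluster means +/- shift/2 (so the between-cluster mean
    # difference on informative genes equals cluster_shift), continuous
    # within-cluster spread latent_sd
    latent = np.where(is_a, 0.5, -0.5) * config.cluster_shift
    latent = latent + rng.normal(0.0, config.latent_sd, n_total)
    latent_score = pd.Series(latent, index=sample_ids)

    n_inform = config.n_regulators + config.n_deg
    baseline = rng.normal(8.0, 1.0, config.n_genes)
    X = rng.normal(0.0, 1.0, (config.n_genes, n_total)) + baseline[:, None]
    X[:n_inform] += latent[None, :]
    batch_offsets = np.arange(config.n_cohorts) * config.batch_shift
    X += np.repeat(batch_offsets, config.n_samples)[None, :]

    expr = ExpressionMatrix(
        pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=sample_ids),
        pd.Series(cohorts, index=sample_ids),
    )

    hazard = config.baseline_hazard * np.where(is_a, config.hazard_ratio_true, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate, n_total)
    else:
        censor_time = np.full(n_total, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)
    os_time = np.maximum(os_time, 1e-6)

    clinical = ClinicalTable(pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": np.round(rng.normal(58, 10, n_total)).astype(int),
            "stage": rng.choice(["I", "II", "III", "IV"], n_total),
            "ldh": rng.choice(["normal", "high"], n_total, p=[0.7, 0.3]),
            "batch": cohorts,
        },
        index=sample_ids,
    ))

    truth = CohortTruth(
        cluster=cluster,
        latent_score=latent_score,
        hazard_ratio=config.hazard_ratio_true,
        differential_genes=genes[:n_inform],
    )
    return SyntheticCohort(expr, clinical, truth, config)


def generate_response_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate an immunotherapy cohort with binary response labels.

    On top of :func:`generate_cohort`, each sample gets a binary ``response``
    with ``P(response) = logistic(intercept + response_effect * z)`` where
    ``z`` is the standardized latent score, and a ``neoantigen_burden`` value
    correlated with the latent score with sign/strength ``neoantigen_corr``.
    The intercept is set for a ~25% marginal response rate at zero effect.
    """
    cohort = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    latent = cohort.truth.latent_score.to_numpy()
    sd = latent.std() if latent.std() > 0 else 1.0
    z = (latent - latent.mean()) / sd
    intercept = math.log(0.25 / 0.75)
    p = 1.0 / (1.0 + np.exp(-(intercept + config.response_effect * z)))
    response = (rng.random(len(z)) < p).astype(int)
    rho = float(np.clip(config.neoantigen_corr, -0.99, 0.99))
    burden_latent = rho * z + math.sqrt(1 - rho**2) * rng.normal(0, 1, len(z))
    burden = np.exp(1.0 + 0.8 * burden_latent)  # log-normal, positive scale

    clin = cohort.clinical.table.copy()
    clin["response"] = response
    clin["neoantigen_burden"] = burden
    return SyntheticCohort(
        cohort.expression, ClinicalTable(clin), cohort.truth, config
    )


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f for f in SimulationConfig.__dataclass_fields__}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown simulation parameters: {sorted(extra)}")
    return SimulationConfig(**d)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
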