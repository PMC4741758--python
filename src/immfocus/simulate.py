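"""Seeded tumor/immune mixture cohorts for end-to-end testing.

The generator mirrors the statistical model the normalization assumes:
each biopsy s carries a latent immune fraction phi_s (how much of the
sampled tissue is immune cells) and a latent immune activity a_s (the
biologically meaningful state of those cells).  Gene abundance is

    X(g, s) = m_g * w(g, s) * eps(g, s)

with per-gene baseline means m_g (lognormal), multiplicative lognormal
measurement noise eps of mean 1 and a configurable CV, and a weight w that
encodes the gene's class:

* ``anchor`` and ``immune`` genes:       w = phi_s
* ``prognostic_immune`` genes:           w = phi_s * exp(gamma_g * a_s)
* ``tumor`` genes:                       w = 1

Survival times are exponential with log-hazard beta * a_s, independently
right-censored (uniform censoring times calibrated to a target censoring
fraction).  Because hazard depends only on a_s while raw immune-gene
expression mixes phi_s and a_s, raw expression is confounded by biopsy
composition — exactly the nuisance the normalization is meant to remove.
Half of the prognostic effect sizes gamma_g are negative (protective
immune programs) and half positive, as seen in real cohorts.

Clinical age and gender are drawn independently; pathological stage can
optionally be linked to a_s through a logit model to emulate
stage-association analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

ANCHOR_GENE = "PTPRC"


@dataclass
class SimulationConfig:
    """Cohort-generation parameters; defaults emulate a 480-patient study."""

    seed: int
    n_samples: int = 480
    n_genes: int = 2000
    immune_block_size: int = 150          # immune genes tracking phi (anchor extra)
    prognostic_immune_count: int = 20     # immune genes also carrying a_s
    phi_alpha: float = 2.0                # Beta(a, b) immune fraction
    phi_beta: float = 5.0
    activity_sd: float = 1.0              # sd of latent immune activity a_s
    noise_cv: float = 0.15                # lognormal measurement-noise CV
    baseline_log_mean: float = math.log(500.0)   # lognormal per-gene means m_g
    baseline_log_sd: float = 1.5
    gamma: float = 0.5                    # |effect| of a_s on prognostic genes
    beta: float = 0.8                     # log-hazard coefficient on a_s
    baseline_hazard: float = math.log(2) / 1200.0   # per day; median OS ~3.3 y
    censoring_rate: float = 0.5
    stage_link: float = 0.0               # logit coefficient of a_s on late stage
    stage_late_fraction: float = 0.42

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_samples < 6:
            raise ValueError("need at least 6 samples")
        if self.n_genes < self.immune_block_size + self.prognostic_immune_count + 1:
            raise ValueError("n_genes too small for the configured gene blocks")
        for name in ("phi_alpha", "phi_beta", "activity_sd", "baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort."""

    phi: pd.Series                  # per-sample immune fraction
    activity: pd.Series             # per-sample latent immune activity
    gene_class: pd.Series           # gene -> anchor/immune/prognostic_immune/tumor
    gamma: pd.Series                # per prognostic-immune gene effect size
    config: SimulationConfig = field(repr=False, default=None)

    def genes_of(self, *classes: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class.isin(classes)])

    @property
    def immune_block(self) -> list[str]:
        """All genes whose abundance scales with the immune fraction."""
        return self.genes_of("anchor", "immune", "prognostic_immune")

    @property
    def tumor_block(self) -> list[str]:
        return self.genes_of("tumor")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-1 lognormal with the requested CV (scale-free noise)."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


def _censoring_horizon(hazards: np.ndarray, rate: float) -> float:
    """Uniform-censoring upper bound u with mean censored fraction ~= rate.

    With C ~ U(0, u) and T ~ Exp(lam), P(C < T) = (1 - exp(-lam u)) / (lam u).
    """
    def mean_censored(u):
        x = hazards * u
        return float(np.mean((1.0 - np.exp(-x)) / x)) - rate

    lo, hi = 1e-9, 1e12
    return float(optimize.brentq(mean_censored, lo, hi))


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Draw one cohort: expression matrix, clinical table, ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    n_imm = config.immune_block_size
    n_prg = config.prognostic_immune_count
    n_tum = config.n_genes - n_imm - n_prg - 1
    genes = ([ANCHOR_GENE]
             + [f"IMM{i:04d}" for i in range(1, n_imm + 1)]
             + [f"PRG{i:04d}" for i in range(1, n_prg + 1)]
             + [f"TUM{i:04d}" for i in range(1, n_tum + 1)])
    classes = (["anchor"] + ["immune"] * n_imm
               + ["prognostic_immune"] * n_prg + ["tumor"] * n_tum)

    phi = rng.beta(config.phi_alpha, config.phi_beta, size=config.n_samples)
    activity = rng.normal(0.0, config.activity_sd, size=config.n_samples)
    m = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                      size=config.n_genes)

    signs = np.ones(n_prg)
    signs[1::2] = -1.0          # alternate protective/deleterious programs
    gammas = config.gamma * signs

    w = np.ones((config.n_genes, config.n_samples))
    is_phi = np.array([c in ("anchor", "immune", "prognostic_immune")
                       for c in classes])
    w[is_phi] = phi[None, :]
    prg_rows = np.array([c == "prognostic_immune" for c in classes])
    if n_prg:
        w[prg_rows] *= np.exp(gammas[:, None] * activity[None, :])

    eps = _lognormal_noise(rng, config.noise_cv,
                           (config.n_genes, config.n_samples))
    X = m[:, None] * w * eps
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene_id"),
                        columns=samples)

    hazards = config.baseline_hazard * np.exp(config.beta * activity)
    death_times = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        horizon = _censoring_horizon(hazards, config.censoring_rate)
        censor_times = rng.uniform(0.0, horizon, size=config.n_samples)
        os_time = np.minimum(death_times, censor_times)
        event = (death_times <= censor_times).astype(int)
    else:
        os_time = death_times
        event = np.ones(config.n_samples, dtype=int)

    age = rng.normal(60.0, 10.0, size=config.n_samples)
    gender = np.where(rng.random(config.n_samples) < 0.6, "male", "female")
    late_base = math.log(config.stage_late_fraction
                         / (1.0 - config.stage_late_fraction))
    p_late = 1.0 / (1.0 + np.exp(-(late_base + config.stage_link * activity)))
    late = rng.random(config.n_samples) < p_late
    # split early between I/II and late between III/IV with fixed odds
    sub = rng.random(config.n_samples)
    stage = np.where(late, np.where(sub < 0.5, "III", "IV"),
                     np.where(sub < 0.8, "I", "II"))

    clin = pd.DataFrame({
        "os_time": os_time, "event": event, "age": age,
        "gender": gender, "stage": stage,
    }, index=pd.Index(samples, name="sample_id"))

    truth = SimulationTruth(
        phi=pd.Series(phi, index=samples, name="phi"),
        activity=pd.Series(activity, index=samples, name="activity"),
        gene_class=pd.Series(classes, index=genes, name="gene_class"),
        gamma=pd.Series(gammas, index=[g for g, c in zip(genes, classes)
                                       if c == "prognostic_immune"],
                        name="gamma"),
        config=config,
    )
    return expr, clin, truth


def write_truth(truth: SimulationTruth, prefix: str) -> None:
    """Write the ground truth as plain TSV files next to the cohort tables."""
    per_sample = pd.DataFrame({"phi": truth.phi, "activity": truth.activity})
    per_sample.to_csv(f"{prefix}truth_samples.tsv", sep="\t",
                      index_label="sample_id")
    per_gene = truth.gene_class.to_frame()
    per_gene["gamma"] = truth.gamma.reindex(per_gene.index)
    per_gene.to_csv(f"{prefix}truth_genes.tsv", sep="\t", index_label="gene_id")
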