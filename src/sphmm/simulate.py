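"""Synthetic case-control GWAS summary statistics.

Generates per-SNP log-odds-ratio estimates with the statistical structure
the mixture model assumes: a fraction ``pi_true`` of SNPs carries a true
effect drawn from a chosen distribution (by default normal with SD 0.03),
the rest are null, and sampling noise reflects a balanced case-control
study of given size.  Two noise mechanisms are provided:

* ``"asymptotic"`` -- draw y ~ N(beta, v) with the Wald variance of a 2x2
  allele-count table, v = 1/(2 n_case pt qt) + 1/(2 n_control p q), where
  the case-side derived allele frequency pt = p e^beta / (1 - p + p e^beta)
  is the logistic shift of the population frequency p;
* ``"genotype"`` -- draw allele counts binomially in cases (frequency pt)
  and controls (frequency p) and compute the empirical Wald log-odds ratio
  and its 1/a + 1/b + 1/c + 1/d variance, with a 0.5 continuity correction
  when a cell is empty.

Disease prevalence never enters: case-control sampling is conditional on
status.  It matters only for the liability-scale conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .em import FitConfig, FitResult, fit

__all__ = [
    "NormalEffects",
    "PointMassEffects",
    "UniformEffects",
    "UniformFreq",
    "SimConfig",
    "SimOutput",
    "simulate_dataset",
    "validation_experiment",
    "ValidationResult",
]


@dataclass(frozen=True)
class NormalEffects:
    """Non-null effects beta ~ N(0, sd^2) on the log-odds-ratio scale."""

    sd: float = 0.03

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(0.0, self.sd, size=n)


@dataclass(frozen=True)
class PointMassEffects:
    """Discrete non-null effect distribution."""

    values: Sequence[float]
    weights: Optional[Sequence[float]] = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        vals = np.asarray(self.values, dtype=float)
        w = None if self.weights is None else np.asarray(self.weights, dtype=float)
        if w is not None:
            w = w / w.sum()
        return rng.choice(vals, size=n, p=w)


@dataclass(frozen=True)
class UniformEffects:
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=n)


@dataclass(frozen=True)
class UniformFreq:
    """Derived allele frequencies uniform on (lo, hi); common-variant panel."""

    lo: float = 0.05
    hi: float = 0.95

    def __post_init__(self):
        if not (0.0 < self.lo < self.hi < 1.0):
            raise ValueError("frequency bounds must satisfy 0 < lo < hi < 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=n)


EffectDist = Union[NormalEffects, PointMassEffects, UniformEffects]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated GWAS.

    Defaults mirror the validation design: 10% of SNPs associated, effects
    N(0, 0.03^2), balanced case-control sampling, common-variant DAFs.
    """

    m: int = 100_000
    pi_true: float = 0.1
    effect_dist: EffectDist = field(default_factory=NormalEffects)
    n_case: int = 100_000
    n_control: int = 100_000
    freq_dist: UniformFreq = field(default_factory=UniformFreq)
    mode: str = "asymptotic"
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n_case < 1 or self.n_control < 1:
            raise ValueError("m and sample sizes must be >= 1")
        if not (0.0 <= self.pi_true <= 1.0):
            raise ValueError("pi_true must lie in [0, 1]")
        if self.mode not in ("asymptotic", "genotype"):
            raise ValueError("mode must be 'asymptotic' or 'genotype'")


@dataclass(frozen=True)
class SimOutput:
    """Simulated summary statistics plus the hidden per-SNP truth."""

    frame: pd.DataFrame  # snp_id, beta, var, daf
    truth: pd.DataFrame  # snp_id, is_nonnull, beta_true
    config: SimConfig

    @property
    def n_nonnull(self) -> int:
        return int(self.truth["is_nonnull"].sum())


def _case_freq(p: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Derived allele frequency among cases under an allele-level logistic shift."""
    eb = np.exp(beta)
    return p * eb / (1.0 - p + p * eb)


def simulate_dataset(config: SimConfig) -> SimOutput:
    """Draw one dataset of m SNPs under the two-group generative model."""
    rng = np.random.default_rng(config.seed)
    m = config.m
    p = config.freq_dist.sample(rng, m)
    is_nonnull = rng.random(m) < config.pi_true
    beta = np.zeros(m)
    k = int(is_nonnull.sum())
    if k:
        beta[is_nonnull] = config.effect_dist.sample(rng, k)

    pt = _case_freq(p, beta)
    if config.mode == "asymptotic":
        v = 1.0 / (2.0 * config.n_case * pt * (1.0 - pt)) + 1.0 / (
            2.0 * config.n_control * p * (1.0 - p)
        )
        y = rng.normal(beta, np.sqrt(v))
    else:
        n_ca = 2 * config.n_case
        n_co = 2 * config.n_control
        a = rng.binomial(n_ca, pt).astype(float)  # derived alleles in cases
        c = rng.binomial(n_co, p).astype(float)  # derived alleles in controls
        # redraw monomorphic tables (both margins collapse); bounded retries
        for _ in range(10):
            bad = ((a == 0) & (c == 0)) | ((a == n_ca) & (c == n_co))
            if not bad.any():
                break
            idx = np.flatnonzero(bad)
            a[idx] = rng.binomial(n_ca, pt[idx])
            c[idx] = rng.binomial(n_co, p[idx])
        b = n_ca - a
        d = n_co - c
        cells = np.stack([a, b, c, d])
        zero = (cells == 0).any(axis=0)
        cells[:, zero] += 0.5  # Haldane-Anscombe continuity correction
        a, b, c, d = cells
        y = np.log(a * d / (b * c))
        v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d

    ids = np.array([f"snp{i:07d}" for i in range(m)])
    frame = pd.DataFrame({"snp_id": ids, "beta": y, "var": v, "daf": p})
    truth = pd.DataFrame(
        {"snp_id": ids, "is_nonnull": is_nonnull, "beta_true": beta}
    )
    return SimOutput(frame=frame, truth=truth, config=config)


@dataclass(frozen=True)
class ValidationResult:
    """Validation sweep over sample sizes: per-replicate and per-n summaries."""

    table: pd.DataFrame  # n, rep, seed, pi_hat, loglik
    summary: pd.DataFrame  # n, mean_pi_hat, sd_pi_hat, n_reps
    g_curves: dict  # n -> averaged fitted masses (aligned with grid)
    grid_points: np.ndarray


def validation_experiment(
    n_values: Sequence[int],
    m: int,
    reps: int,
    seed: int = 0,
    pi_true: float = 0.1,
    effect_dist: Optional[EffectDist] = None,
    fit_config: Optional[FitConfig] = None,
) -> ValidationResult:
    """Replicated simulate-and-fit sweep across case-control sample sizes.

    For each n in ``n_values`` and each replicate: simulate m SNPs with
    ``pi_true`` associated and effects from ``effect_dist`` (default
    N(0, 0.03^2)), fit the mixture, and record the estimated non-null
    proportion; averaged fitted mass curves are returned per n.
    """
    effect_dist = effect_dist or NormalEffects()
    fit_config = fit_config or FitConfig()
    ss = np.random.SeedSequence(seed)
    sub_seeds = ss.generate_state(len(n_values) * reps) % (2**31)
    rows = []
    g_curves = {}
    grid_points = fit_config.make_grid().points
    i = 0
    for n in n_values:
        masses_acc = np.zeros_like(grid_points)
        for rep in range(reps):
            s = int(sub_seeds[i])
            i += 1
            sim = simulate_dataset(
                SimConfig(
                    m=m,
                    pi_true=pi_true,
                    effect_dist=effect_dist,
                    n_case=n,
                    n_control=n,
                    seed=s,
                )
            )
            res = fit(sim.frame, fit_config)
            masses_acc += res.prior.masses
            rows.append(
                {
                    "n": n,
                    "rep": rep,
                    "seed": s,
                    "pi_hat": res.prior.pi,
                    "loglik": res.loglik(),
                }
            )
        g_curves[n] = masses_acc / reps
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("n", sort=False)["pi_hat"]
        .agg(mean_pi_hat="mean", sd_pi_hat="std", n_reps="count")
        .reset_index()
    )
    return ValidationResult(
        table=table, summary=summary, g_curves=g_curves, grid_points=grid_points
    )
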