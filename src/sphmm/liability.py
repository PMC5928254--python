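"""Liability-scale variance explained by SNPs under the threshold model.

A SNP's log-odds ratio beta, its derived allele frequency p, and the
disease prevalence K determine the variance it explains on the latent
liability scale.  Genotype penetrances follow an additive allele-dosage
logistic model phi_x = 1/(1 + exp(-alpha - beta x)), with alpha pinned by
the prevalence constraint sum_x h_x phi_x = K over Hardy-Weinberg genotype
frequencies h_x.  Each genotype's liability distribution has unit residual
variance and mean mu_x recovered from its penetrance via the threshold T:
Phi^-1(1 - phi_x) = T - mu_x.  The between-genotype variance
v* = sum_x h_x (mu_x - mu_all)^2 is then rescaled to the standard
unit-total-variance liability scale as v = v* / (1 + v*).

Under a fitted two-group prior, the per-SNP variance is
v_hat_j = pi_hat * sum_b p_hat_b * v(b, p_j, K), and the SNP-set
heritability V_hat is the simple sum of v_hat_j over the (pruned) set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .model import EffectGrid, MixturePrior, as_frame

__all__ = [
    "genotype_frequencies",
    "solve_alpha",
    "liability_variance",
    "snp_variance_from_prior",
    "total_variance",
    "family_heritability_fraction",
    "fold_enrichment",
    "VarianceReport",
]


def genotype_frequencies(p):
    """Hardy-Weinberg genotype frequencies (h0, h1, h2) for allele frequency p."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    q = 1.0 - p
    return q * q, 2.0 * p * q, p * p


def _prevalence(alpha, beta, h0, h1, h2):
    return (
        h0 * expit(alpha) + h1 * expit(alpha + beta) + h2 * expit(alpha + 2.0 * beta)
    )


def solve_alpha(beta, p, K):
    """Intercept alpha satisfying the prevalence constraint.

    Solves sum_x h_x / (1 + exp(-alpha - beta x)) = K; the left side is
    strictly increasing in alpha so the root is unique.  Accepts scalars or
    broadcastable arrays; the prevalence residual is below 1e-10.
    """
    beta = np.asarray(beta, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any(np.asarray(K) <= 0) or np.any(np.asarray(K) >= 1):
        raise ValueError("prevalence K must lie strictly in (0, 1)")
    h0, h1, h2 = genotype_frequencies(p_arr)
    beta, h0, h1, h2 = np.broadcast_arrays(beta, h0, h1, h2)
    shape = beta.shape
    beta = beta.ravel()
    h0, h1, h2 = h0.ravel(), h1.ravel(), h2.ravel()

    # safeguarded Newton: keep a sign-bracketing interval, bisect on overshoot
    lo = logit(K) - 2.0 * np.abs(beta) - 1.0
    hi = logit(K) + 2.0 * np.abs(beta) + 1.0
    alpha = np.full_like(beta, logit(K))
    for _ in range(100):
        f = _prevalence(alpha, beta, h0, h1, h2) - K
        below = f < 0
        lo = np.where(below, alpha, lo)
        hi = np.where(below, hi, alpha)
        s0 = expit(alpha)
        s1 = expit(alpha + beta)
        s2 = expit(alpha + 2.0 * beta)
        df = h0 * s0 * (1 - s0) + h1 * s1 * (1 - s1) + h2 * s2 * (1 - s2)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(df > 0, f / df, 0.0)
        new = alpha - step
        out = (new <= lo) | (new >= hi) | ~np.isfinite(new)
        new = np.where(out, 0.5 * (lo + hi), new)
        done = np.abs(new - alpha) < 1e-13
        alpha = new
        if done.all():
            break
    # polish any stragglers with bracketed root finding
    resid = np.abs(_prevalence(alpha, beta, h0, h1, h2) - K)
    for i in np.flatnonzero(resid > 1e-11):
        alpha[i] = brentq(
            lambda a: _prevalence(a, beta[i], h0[i], h1[i], h2[i]) - K,
            lo[i],
            hi[i],
            xtol=1e-14,
        )
    alpha = alpha.reshape(shape)
    return float(alpha) if alpha.ndim == 0 else alpha


def liability_variance(beta, p, K):
    """Liability-scale variance v(beta, p, K) in [0, 1) explained by one SNP.

    The genotype liability means are anchored at T = Phi^-1(1 - K) (the
    population threshold); the variance is invariant to this arbitrary
    location choice.  Vectorised over broadcastable beta and p.
    """
    beta = np.asarray(beta, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    alpha = solve_alpha(beta, p_arr, K)
    h0, h1, h2 = genotype_frequencies(p_arr)
    beta_b, h0, h1, h2 = np.broadcast_arrays(beta, h0, h1, h2)
    T = norm.isf(K)
    mu0 = T - norm.isf(expit(alpha))
    mu1 = T - norm.isf(expit(alpha + beta_b))
    mu2 = T - norm.isf(expit(alpha + 2.0 * beta_b))
    mu_all = h0 * mu0 + h1 * mu1 + h2 * mu2
    v_star = (
        h0 * (mu0 - mu_all) ** 2 + h1 * (mu1 - mu_all) ** 2 + h2 * (mu2 - mu_all) ** 2
    )
    v = v_star / (1.0 + v_star)
    return float(v) if v.ndim == 0 else v


def snp_variance_from_prior(prior: MixturePrior, grid: EffectGrid, p_j, K) -> float:
    """Per-SNP liability variance under the fitted prior.

    v_hat_j = pi_hat * sum_b p_hat_b * v(b, p_j, K): the non-null
    probability times the prior-mean variance of a non-null effect.
    """
    v_grid = liability_variance(grid.points, p_j, K)
    out = prior.pi * (prior.masses * v_grid).sum(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class VarianceReport:
    """Per-SNP liability-scale variances and their total V_hat."""

    per_snp: pd.DataFrame  # snp_id, daf, v_hat
    V_hat: float
    n_used: int
    n_skipped: int
    K: float
    se_V: Optional[float] = None

    def totals_dict(self) -> dict:
        d = {
            "V_hat": self.V_hat,
            "n_used": self.n_used,
            "n_skipped": self.n_skipped,
            "K": self.K,
        }
        if self.se_V is not None:
            d["se_V"] = self.se_V
        return d


def total_variance(data, prior: MixturePrior, grid: EffectGrid, K) -> VarianceReport:
    """SNP-set heritability V_hat = sum_j v_hat_j over SNPs with frequencies.

    SNPs lacking a derived allele frequency are skipped with a warning and
    counted in the report.
    """
    frame = as_frame(data)
    if "daf" not in frame.columns:
        raise ValueError("no derived allele frequencies available")
    daf = pd.to_numeric(frame["daf"], errors="coerce")
    ok = daf.notna() & (daf > 0) & (daf < 1)
    n_skipped = int((~ok).sum())
    if ok.sum() == 0:
        raise ValueError("no SNP has a usable derived allele frequency")
    if n_skipped:
        warnings.warn(f"{n_skipped} SNPs lack a frequency and were skipped")
    p_used = daf[ok].to_numpy(dtype=float)
    # one root-solve per (grid point, SNP) pair, vectorised
    v_grid = liability_variance(
        grid.points[None, :], p_used[:, None], K
    )  # (n_used, B)
    v_hat = prior.pi * (v_grid @ prior.masses)
    per_snp = pd.DataFrame(
        {
            "snp_id": frame.loc[ok, "snp_id"].to_numpy(),
            "daf": p_used,
            "v_hat": v_hat,
        }
    )
    return VarianceReport(
        per_snp=per_snp,
        V_hat=float(v_hat.sum()),
        n_used=int(ok.sum()),
        n_skipped=n_skipped,
        K=float(K),
    )


def family_heritability_fraction(V_hat: float, extra: float, h2_family: float) -> float:
    """Fraction of family-based heritability accounted for: (V_hat + extra) / h2_family.

    ``extra`` is variance explained by regions excluded from the SNP set
    (e.g. the MHC).  Reporting arithmetic only; all three numbers are
    supplied by the caller.
    """
    if h2_family <= 0:
        raise ValueError("family heritability must be positive")
    return (V_hat + extra) / h2_family


def fold_enrichment(mean_v_stratum: float, mean_v_reference: float) -> float:
    """Ratio of per-SNP mean liability variances between two SNP sets."""
    if mean_v_reference <= 0:
        raise ValueError("reference per-SNP variance must be positive")
    return mean_v_stratum / mean_v_reference
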