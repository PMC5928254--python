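"""Two-group semi-parametric mixture model for GWAS summary statistics.

Each SNP contributes an estimated log-odds ratio ``y_j`` (derived vs
ancestral allele) with sampling variance ``v_j``.  Marginally,

    f_j(y_j) = (1 - pi) N(y_j; 0, v_j) + pi * sum_b p_b N(y_j; b_b, v_j),

where ``pi`` is the prior probability that a SNP is disease-associated
(non-null) and the non-null effect-size distribution ``g`` is represented
nonparametrically by probability masses ``p`` on a fixed grid of nonzero
points ``b``.  This module defines the data types and evaluates the null,
non-null and marginal densities and the total log-likelihood; estimation
lives in :mod:`sphmm.em`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "SummaryStat",
    "EffectGrid",
    "MixturePrior",
    "Responsibilities",
    "MixtureKernel",
    "null_density",
    "nonnull_density",
    "marginal_loglik",
    "as_arrays",
    "as_frame",
]


@dataclass(frozen=True)
class SummaryStat:
    """One SNP's summary statistic.

    Parameters
    ----------
    snp_id : str
        SNP identifier.
    y : float
        Estimated log-odds ratio of the derived allele (natural-log scale).
    v : float
        Sampling variance of the estimate (squared standard error).
    daf : float, optional
        Derived allele frequency, strictly inside (0, 1).
    p_ref : float, optional
        Association P-value in a reference GWAS (used for P-value pruning).
    stratum : str, optional
        Stratum label, e.g. ``"eQTL"`` or ``"DAF_bin_1"``.
    """

    snp_id: str
    y: float
    v: float
    daf: Optional[float] = None
    p_ref: Optional[float] = None
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise ValueError(f"{self.snp_id}: effect estimate must be finite")
        if not (self.v > 0 and math.isfinite(self.v)):
            raise ValueError(f"{self.snp_id}: variance must be positive and finite")
        if self.daf is not None and not (0.0 < self.daf < 1.0):
            raise ValueError(f"{self.snp_id}: derived allele frequency must lie in (0, 1)")
        if self.p_ref is not None and not (0.0 <= self.p_ref <= 1.0):
            raise ValueError(f"{self.snp_id}: reference P-value must lie in [0, 1]")


@dataclass(frozen=True)
class EffectGrid:
    """Ordered nonzero mass-point support for the nonparametric prior g.

    Points are on the log-odds-ratio scale, strictly increasing, and never
    include zero (zero effects belong to the null component).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least two points")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(pts == 0.0):
            raise ValueError("zero is reserved for the null component")

    @classmethod
    def from_range(cls, lo: float = -0.3, hi: float = 0.3, step: float = 0.005) -> "EffectGrid":
        """Evenly spaced grid over [lo, hi] with zero removed.

        The default (-0.3, 0.3, 0.005) yields 120 points
        (-0.300, -0.295, ..., -0.005, 0.005, ..., 0.300), covering odds
        ratios from about 0.74 to 1.35.
        """
        n = int(round((hi - lo) / step))
        pts = lo + step * np.arange(n + 1)
        # drop the zero point (up to float fuzz); zero belongs to the null
        keep = np.abs(pts) > step * 1e-8
        pts = np.where(np.abs(pts - np.round(pts / step) * step) < step * 1e-8,
                       np.round(pts / step) * step, pts)
        return cls(pts[keep])

    @classmethod
    def default(cls) -> "EffectGrid":
        return cls.from_range()

    def __len__(self) -> int:
        return int(self.points.size)


@dataclass(frozen=True)
class MixturePrior:
    """Prior ``(pi, p)``: non-null probability plus grid masses."""

    pi: float
    masses: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", m)
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError("pi must lie in [0, 1]")
        if np.any(m < 0):
            raise ValueError("masses must be nonnegative")
        if abs(m.sum() - 1.0) > 1e-10:
            raise ValueError("masses must sum to 1 within 1e-10")

    @classmethod
    def uniform(cls, n_points: int, pi: float) -> "MixturePrior":
        return cls(pi=pi, masses=np.full(n_points, 1.0 / n_points))


@dataclass(frozen=True)
class Responsibilities:
    """E-step posteriors: per SNP, null probability r0 and grid weights r.

    For each SNP j, ``r0[j] + r[j, :].sum() == 1``.
    """

    r0: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        r0 = np.asarray(self.r0, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r0", r0)
        object.__setattr__(self, "r", r)
        if r.shape[0] != r0.shape[0]:
            raise ValueError("r and r0 must cover the same SNPs")
        total = r0 + r.sum(axis=1)
        if np.any(np.abs(total - 1.0) > 1e-10):
            raise ValueError("responsibilities must sum to 1 per SNP")
        if np.any(r0 < -1e-15) or np.any(r < -1e-15):
            raise ValueError("responsibilities must be nonnegative")


def null_density(y, v):
    """Density of the null component N(0, v) at y.

    Underflow-safe: far-tail values evaluate to 0.0 rather than raising.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("variance must be positive")
    out = np.exp(-0.5 * (_LOG_2PI + np.log(v) + y * y / v))
    return float(out) if out.ndim == 0 else out


def nonnull_density(y, v, prior_masses, grid: EffectGrid):
    """Grid-mixture density sum_b p_b N(y; b, v) of the non-null component."""
    p = np.asarray(prior_masses, dtype=float)
    b = grid.points
    if p.shape != b.shape:
        raise ValueError("prior masses and grid are misaligned")
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("variance must be positive")
    z = y[..., None] - b
    dens = np.exp(-0.5 * (_LOG_2PI + np.log(v)[..., None] + z * z / v[..., None]))
    out = dens @ p
    return float(out) if out.ndim == 0 else out


def as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    """Extract (y, v) arrays from a DataFrame, SummaryStat sequence, or pair."""
    if isinstance(data, pd.DataFrame):
        y = data["beta"].to_numpy(dtype=float)
        v = data["var"].to_numpy(dtype=float)
    elif isinstance(data, tuple) and len(data) == 2:
        y = np.asarray(data[0], dtype=float)
        v = np.asarray(data[1], dtype=float)
    else:
        y = np.array([s.y for s in data], dtype=float)
        v = np.array([s.v for s in data], dtype=float)
    if y.size == 0:
        raise ValueError("no SNPs supplied")
    if np.any(v <= 0) or not np.all(np.isfinite(v)) or not np.all(np.isfinite(y)):
        raise ValueError("all effect estimates must be finite with positive variance")
    return y, v


def as_frame(data) -> pd.DataFrame:
    """Normalise input to the canonical summary-statistic DataFrame."""
    if isinstance(data, pd.DataFrame):
        return data
    rows = [
        {
            "snp_id": s.snp_id,
            "beta": s.y,
            "var": s.v,
            "daf": s.daf,
            "p_ref": s.p_ref,
            "stratum": s.stratum,
        }
        for s in data
    ]
    return pd.DataFrame(rows)


class MixtureKernel:
    """Cached per-dataset likelihood kernel.

    Precomputes the m x B matrix of log N(y_j; b, v_j) together with the
    null log-densities, both row-rescaled by their maximum so that mixture
    sums stay in range even when v_j ~ 1e-4 puts tail densities far below
    the double-precision underflow threshold.  All evaluations are exactly
    equivalent to direct (uncached) density computation.
    """

    def __init__(self, y, v, grid: EffectGrid):
        y = np.asarray(y, dtype=float)
        v = np.asarray(v, dtype=float)
        if y.ndim != 1 or y.shape != v.shape:
            raise ValueError("y and v must be matching 1-D arrays")
        if np.any(v <= 0):
            raise ValueError("variance must be positive")
        self.y = y
        self.v = v
        self.grid = grid
        b = grid.points
        log_norm = -0.5 * (_LOG_2PI + np.log(v))
        self.log_f0 = log_norm - 0.5 * y * y / v
        z = y[:, None] - b[None, :]
        self.log_k = log_norm[:, None] - 0.5 * z * z / v[:, None]
        # row scaling constant: the largest log-density among all components
        self._c = np.maximum(self.log_k.max(axis=1), self.log_f0)
        self._f0s = np.exp(self.log_f0 - self._c)
        self._ks = np.exp(self.log_k - self._c[:, None])

    @property
    def n_snps(self) -> int:
        return self.y.size

    def _check(self, prior: MixturePrior) -> None:
        if prior.masses.size != len(self.grid):
            raise ValueError("prior masses and grid are misaligned")

    def _scaled_marginal(self, pi: float, masses: np.ndarray) -> np.ndarray:
        return (1.0 - pi) * self._f0s + pi * (self._ks @ masses)

    def loglik_rows(self, prior: MixturePrior) -> np.ndarray:
        """log f_j(y_j) for every SNP, never -inf for finite inputs."""
        self._check(prior)
        fs = self._scaled_marginal(prior.pi, prior.masses)
        out = np.empty_like(fs)
        ok = fs > 0
        out[ok] = np.log(fs[ok]) + self._c[ok]
        if not ok.all():
            # all scaled components with nonzero weight underflowed for these
            # rows; redo them in log space with weight masking
            bad = np.flatnonzero(~ok)
            with np.errstate(divide="ignore"):
                lw0 = np.log1p(-prior.pi) if prior.pi < 1 else -np.inf
                lwb = (np.log(prior.pi) if prior.pi > 0 else -np.inf) + np.log(prior.masses)
            terms = np.concatenate(
                [self.log_f0[bad, None] + lw0, self.log_k[bad, :] + lwb[None, :]], axis=1
            )
            from scipy.special import logsumexp

            out[bad] = logsumexp(terms, axis=1)
        return out

    def loglik(self, prior: MixturePrior) -> float:
        return float(self.loglik_rows(prior).sum())

    def responsibilities(self, prior: MixturePrior) -> Responsibilities:
        """Posterior component probabilities for every SNP (E-step)."""
        self._check(prior)
        pi, p = prior.pi, prior.masses
        fs = self._scaled_marginal(pi, p)
        fs = np.where(fs > 0, fs, np.finfo(float).tiny)
        r0 = (1.0 - pi) * self._f0s / fs
        r = pi * p[None, :] * self._ks / fs[:, None]
        # renormalise away rounding so invariants hold exactly
        total = r0 + r.sum(axis=1)
        r0 = r0 / total
        r = r / total[:, None]
        return Responsibilities(r0=r0, r=r)

    def em_sums(self, prior: MixturePrior) -> tuple[float, np.ndarray, float]:
        """Sufficient statistics of one E-step without materialising r.

        Returns ``(loglik_at_prior, t, nonnull_total)`` where
        ``t[b] = sum_j r_jb`` and ``nonnull_total = sum_j (1 - r0_j)``.
        """
        self._check(prior)
        pi, p = prior.pi, prior.masses
        fs = self._scaled_marginal(pi, p)
        pos = fs > 0
        if pos.all():
            ll = float((np.log(fs) + self._c).sum())
        else:
            ll = float(self.loglik_rows(prior).sum())
            fs = np.where(pos, fs, np.finfo(float).tiny)
        w = 1.0 / fs
        t = pi * p * (self._ks.T @ w)
        return ll, t, float(t.sum())


def marginal_loglik(data, prior: MixturePrior, grid: EffectGrid) -> float:
    """Total mixture log-likelihood sum_j log f_j(y_j).

    SNPs are treated as independent, which is reasonable for an LD-pruned
    panel.  Computed with log-sum-exp protection so finite inputs never
    produce -inf.
    """
    y, v = as_arrays(data)
    return MixtureKernel(y, v, grid).loglik(prior)
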