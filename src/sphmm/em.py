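"""Empirical Bayes estimation of (pi, g) by a three-stage EM schedule.

The nonparametric mixing distribution g is estimated by EM on a fixed grid
(the smoothing-and-roughening scheme: iteration caps, not penalties, control
the roughness of the estimate).  The schedule is

1. candidate sweep -- for each starting value pi in {0.1, ..., 0.9}, run a
   fixed number of full EM iterations from a uniform g and keep the run
   with the highest log-likelihood; its final pi becomes ``pi_init``;
2. g warm-up -- reset g to uniform, freeze pi at ``pi_init``, and iterate
   the mass updates until the log-likelihood stabilises;
3. final EM -- from (pi_init, g_init), update both parameters until the
   relative change of pi per iteration drops below tolerance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    EffectGrid,
    MixtureKernel,
    MixturePrior,
    Responsibilities,
    as_arrays,
)

__all__ = ["FitConfig", "EMRun", "FitResult", "e_step", "m_step", "run_em", "fit"]

_PI_EPS = 1e-12  # keep pi off the boundary so relative changes stay defined


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the three-stage EM schedule.

    Defaults: grid (-0.3, 0.3, 0.005); candidate starts 0.1..0.9; 200
    iterations per stage-1 candidate; stages 2 and 3 stop on a relative
    change below 5e-5 (0.005%) of the log-likelihood and of pi
    respectively, or at 200 / 2000 iterations.
    """

    grid_lo: float = -0.3
    grid_hi: float = 0.3
    grid_step: float = 0.005
    candidate_pis: Sequence[float] = tuple(np.round(np.arange(1, 10) * 0.1, 1))
    stage1_iters: int = 200
    stage2_max_iters: int = 200
    stage2_rel_tol: Optional[float] = 5e-5
    final_max_iters: int = 2000
    final_rel_tol: float = 5e-5

    def __post_init__(self) -> None:
        if self.stage1_iters < 1 or self.stage2_max_iters < 1 or self.final_max_iters < 1:
            raise ValueError("iteration caps must be >= 1")
        if self.final_rel_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.stage2_rel_tol is not None and self.stage2_rel_tol <= 0:
            raise ValueError("tolerances must be positive")

    def make_grid(self) -> EffectGrid:
        return EffectGrid.from_range(self.grid_lo, self.grid_hi, self.grid_step)


@dataclass(frozen=True)
class EMRun:
    """Result of a single EM stage."""

    prior: MixturePrior
    loglik_trace: np.ndarray  # loglik before each update, plus final value
    n_iters: int
    converged: bool
    degenerate: bool = False  # all-null M-step encountered


@dataclass(frozen=True)
class FitResult:
    """Full three-stage fit: prior, diagnostics, and initialisation record."""

    prior: MixturePrior
    grid: EffectGrid
    loglik_trace: np.ndarray
    n_iters: int
    converged: bool
    stage1_table: list  # per candidate: {pi_start, pi_after, loglik}
    pi_init: float
    g_init: np.ndarray

    @property
    def pi(self) -> float:
        return self.prior.pi

    @property
    def masses(self) -> np.ndarray:
        return self.prior.masses

    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def to_dict(self) -> dict:
        return {
            "pi": self.prior.pi,
            "grid": self.grid.points.tolist(),
            "masses": self.prior.masses.tolist(),
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "n_iters": self.n_iters,
            "converged": bool(self.converged),
            "stage1_table": self.stage1_table,
            "pi_init": self.pi_init,
            "g_init": np.asarray(self.g_init).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            prior=MixturePrior(pi=d["pi"], masses=np.asarray(d["masses"])),
            grid=EffectGrid(np.asarray(d["grid"])),
            loglik_trace=np.asarray(d["loglik_trace"]),
            n_iters=d["n_iters"],
            converged=d["converged"],
            stage1_table=d["stage1_table"],
            pi_init=d["pi_init"],
            g_init=np.asarray(d["g_init"]),
        )


def _kernel(data, grid: EffectGrid) -> MixtureKernel:
    if isinstance(data, MixtureKernel):
        return data
    y, v = as_arrays(data)
    return MixtureKernel(y, v, grid)


def e_step(data, prior: MixturePrior, grid: EffectGrid) -> Responsibilities:
    """Posterior component probabilities under the current prior.

    r0_j = (1-pi) f0j / fj and r_jb = pi p_b N(y_j; b, v_j) / fj.
    """
    return _kernel(data, grid).responsibilities(prior)


def m_step(resp: Responsibilities, prev: Optional[MixturePrior] = None) -> MixturePrior:
    """Maximise the expected complete-data log-likelihood.

    pi <- mean_j (1 - r0_j); p_b <- sum_j r_jb / sum_j (1 - r0_j).
    If no posterior mass is non-null the masses cannot be updated: they are
    kept at their previous values (uniform if unknown) with pi = 0 and a
    warning, not an exception.
    """
    m = resp.r0.size
    t = resp.r.sum(axis=0)
    nonnull = float(t.sum())
    pi = nonnull / m
    if nonnull <= 0:
        warnings.warn("all-null responsibilities: masses left unchanged, pi set to 0")
        if prev is not None:
            masses = prev.masses
        else:
            masses = np.full(resp.r.shape[1], 1.0 / resp.r.shape[1])
        return MixturePrior(pi=0.0, masses=masses)
    masses = t / nonnull
    masses = masses / masses.sum()  # absorb rounding
    return MixturePrior(pi=min(pi, 1.0), masses=masses)


def run_em(
    data,
    start_prior: MixturePrior,
    grid: EffectGrid,
    max_iters: int,
    rel_tol: Optional[float] = None,
    update_pi: bool = True,
    update_masses: bool = True,
) -> EMRun:
    """Iterate E/M steps from ``start_prior`` honouring the update flags.

    Stops when the relative per-iteration change of pi (or of the
    log-likelihood, when pi is frozen) falls below ``rel_tol``, or at
    ``max_iters``.  ``rel_tol=None`` runs exactly ``max_iters`` iterations.
    The log-likelihood trace is non-decreasing (EM guarantee).
    """
    kern = _kernel(data, grid)
    pi = float(np.clip(start_prior.pi, _PI_EPS, 1.0 - _PI_EPS))
    p = start_prior.masses.copy()
    trace = []
    converged = False
    degenerate = False
    n_done = 0
    for _ in range(max_iters):
        prior = MixturePrior(pi=pi, masses=p)
        ll, t, nonnull = kern.em_sums(prior)
        trace.append(ll)
        m = kern.n_snps
        new_pi = nonnull / m if update_pi else pi
        if update_masses:
            if nonnull > 0:
                new_p = t / nonnull
                new_p = new_p / new_p.sum()
            else:
                degenerate = True
                new_p = p
        else:
            new_p = p
        new_pi = float(np.clip(new_pi, _PI_EPS, 1.0 - _PI_EPS))
        n_done += 1
        if rel_tol is not None:
            if update_pi:
                rel = abs(new_pi - pi) / max(pi, _PI_EPS)
            else:
                prev_ll = trace[-2] if len(trace) > 1 else None
                rel = (
                    abs(ll - prev_ll) / max(abs(prev_ll), _PI_EPS)
                    if prev_ll is not None
                    else np.inf
                )
            if rel < rel_tol:
                pi, p = new_pi, new_p
                converged = True
                break
        pi, p = new_pi, new_p
    final = MixturePrior(pi=pi, masses=p)
    trace.append(kern.loglik(final))
    return EMRun(
        prior=final,
        loglik_trace=np.asarray(trace),
        n_iters=n_done,
        converged=converged,
        degenerate=degenerate,
    )


def fit(data, config: Optional[FitConfig] = None) -> FitResult:
    """Estimate (pi, g) with the full three-stage EM schedule.

    Deterministic: identical inputs and config give identical results.
    """
    config = config or FitConfig()
    grid = config.make_grid()
    kern = _kernel(data, grid)
    if kern.n_snps < 100:
        warnings.warn(
            f"only {kern.n_snps} SNPs: mixture estimates are unstable below ~100 SNPs"
        )
    B = len(grid)

    # stage 1: candidate-pi sweep from uniform g, full updates, fixed length
    stage1_table = []
    best = None
    for pi0 in config.candidate_pis:
        run = run_em(
            kern,
            MixturePrior.uniform(B, pi0),
            grid,
            max_iters=config.stage1_iters,
            rel_tol=None,
        )
        ll = float(run.loglik_trace[-1])
        stage1_table.append(
            {"pi_start": float(pi0), "pi_after": run.prior.pi, "loglik": ll}
        )
        # strict > keeps the smaller candidate on ties (candidates ascend)
        if best is None or ll > best[0]:
            best = (ll, run.prior.pi)
    pi_init = best[1]

    # stage 2: g warm-up at frozen pi, uniform restart for the masses
    run2 = run_em(
        kern,
        MixturePrior.uniform(B, pi_init),
        grid,
        max_iters=config.stage2_max_iters,
        rel_tol=config.stage2_rel_tol,
        update_pi=False,
    )
    g_init = run2.prior.masses

    # stage 3: full EM from (pi_init, g_init)
    run3 = run_em(
        kern,
        MixturePrior(pi=pi_init, masses=g_init),
        grid,
        max_iters=config.final_max_iters,
        rel_tol=config.final_rel_tol,
    )
    return FitResult(
        prior=run3.prior,
        grid=grid,
        loglik_trace=run3.loglik_trace,
        n_iters=run3.n_iters,
        converged=run3.converged,
        stage1_table=stage1_table,
        pi_init=pi_init,
        g_init=g_init,
    )
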