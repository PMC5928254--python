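"""Parametric bootstrap standard errors for the fitted mixture.

Each replicate redraws every SNP from the fitted model -- non-null with
probability pi_hat, effect from g_hat, observation y* ~ N(beta, v_j) with
the observed sampling variance -- and refits with the full three-stage
schedule, so the spread of replicate estimates includes initialisation
effects.  Standard errors are the sample standard deviations across
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .em import FitConfig, FitResult, fit
from .liability import total_variance
from .model import as_frame

__all__ = ["BootstrapResult", "parametric_bootstrap"]


@dataclass(frozen=True)
class BootstrapResult:
    n_boot: int
    replicate_pis: np.ndarray
    se_pi: float
    seed: int
    replicate_Vs: Optional[np.ndarray] = None
    se_V: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "n_boot": self.n_boot,
            "replicate_pis": np.asarray(self.replicate_pis).tolist(),
            "se_pi": self.se_pi,
            "seed": self.seed,
        }
        if self.replicate_Vs is not None:
            d["replicate_Vs"] = np.asarray(self.replicate_Vs).tolist()
            d["se_V"] = self.se_V
        return d


def parametric_bootstrap(
    data,
    fitted: FitResult,
    n_boot: int = 100,
    seed: int = 0,
    config: Optional[FitConfig] = None,
    prevalence: Optional[float] = None,
) -> BootstrapResult:
    """Bootstrap SE of pi_hat (and of V_hat when ``prevalence`` is given).

    Replicate RNG streams are spawned from the master seed, so results do
    not depend on execution order.  When ``prevalence`` is supplied and the
    data carry derived allele frequencies, each replicate's refit is also
    pushed through the liability transform to give an SE for V_hat.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    frame = as_frame(data)
    v = frame["var"].to_numpy(dtype=float)
    m = v.size
    pi_hat = fitted.prior.pi
    masses = fitted.prior.masses
    b = fitted.grid.points
    config = config or FitConfig()

    streams = np.random.SeedSequence(seed).spawn(n_boot)
    pis = np.empty(n_boot)
    Vs = np.empty(n_boot) if prevalence is not None else None
    for r in range(n_boot):
        rng = np.random.default_rng(streams[r])
        beta = np.where(
            rng.random(m) < pi_hat, rng.choice(b, size=m, p=masses), 0.0
        )
        y_star = rng.normal(beta, np.sqrt(v))
        rep = frame.copy()
        rep["beta"] = y_star
        refit = fit(rep, config)
        pis[r] = refit.prior.pi
        if Vs is not None:
            Vs[r] = total_variance(rep, refit.prior, refit.grid, prevalence).V_hat
    se_pi = float(np.std(pis, ddof=1))
    se_V = float(np.std(Vs, ddof=1)) if Vs is not None else None
    return BootstrapResult(
        n_boot=n_boot,
        replicate_pis=pis,
        se_pi=se_pi,
        seed=seed,
        replicate_Vs=Vs,
        se_V=se_V,
    )
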