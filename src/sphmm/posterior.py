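"""Per-SNP empirical Bayes posterior summaries under the fitted prior.

With the estimated architecture (pi_hat, g_hat) as prior, each SNP gets a
posterior probability of being disease-associated and a posterior mean
effect size.  Posterior means are shrunken towards zero, which makes them
winner's-curse-adjusted estimates suitable for ranking top SNPs.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .em import e_step
from .model import EffectGrid, MixtureKernel, MixturePrior, SummaryStat, as_frame

__all__ = ["posterior_summary", "posterior_table", "rank_snps"]


def posterior_summary(
    stat: Union[SummaryStat, tuple], prior: MixturePrior, grid: EffectGrid
):
    """Posterior summaries for a single SNP.

    Returns ``(p_nonnull, post_mean, post_masses)`` where ``p_nonnull`` is
    the posterior non-null probability 1 - r0, ``post_mean`` is
    sum_b b * r_b (the null component contributes zero), and
    ``post_masses`` is the posterior over grid points given non-null.
    """
    if isinstance(stat, SummaryStat):
        y, v = stat.y, stat.v
    else:
        y, v = stat
    kern = MixtureKernel(np.array([y], float), np.array([v], float), grid)
    resp = kern.responsibilities(prior)
    r0 = float(resp.r0[0])
    r = resp.r[0]
    p_nonnull = 1.0 - r0
    post_mean = float(grid.points @ r)
    post_masses = r / p_nonnull if p_nonnull > 0 else np.zeros_like(r)
    return p_nonnull, post_mean, post_masses


def posterior_table(data, prior: MixturePrior, grid: EffectGrid) -> pd.DataFrame:
    """Posterior non-null probability and mean effect for every SNP."""
    frame = as_frame(data)
    resp = e_step(frame, prior, grid)
    post_mean = resp.r @ grid.points
    return pd.DataFrame(
        {
            "snp_id": frame["snp_id"].to_numpy(),
            "y": frame["beta"].to_numpy(dtype=float),
            "v": frame["var"].to_numpy(dtype=float),
            "p_nonnull": 1.0 - resp.r0,
            "post_mean": post_mean,
            "post_mean_OR": np.exp(post_mean),
        }
    )


def rank_snps(
    data, prior: MixturePrior, grid: EffectGrid, threshold_abs_beta: float = 0.05
) -> pd.DataFrame:
    """SNPs whose posterior mean effect exceeds the threshold in magnitude.

    Sorted by |post_mean| descending; ties broken by snp_id so the order
    is deterministic.
    """
    tab = posterior_table(data, prior, grid)
    tab = tab[np.abs(tab["post_mean"]) > threshold_abs_beta].copy()
    tab["_abs"] = np.abs(tab["post_mean"])
    tab = tab.sort_values(["_abs", "snp_id"], ascending=[False, True], kind="mergesort")
    return tab.drop(columns="_abs").reset_index(drop=True)
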