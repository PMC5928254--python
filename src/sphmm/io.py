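"""File formats, LD pruning, and stratified analyses.

Summary statistics travel as tab-delimited text with a header:
``snp_id  beta  se`` (or ``var``) plus optional ``daf``, ``p_ref`` and
``stratum`` columns; '.' marks a missing value.  LD is supplied as a
three-column ``SNP_A  SNP_B  R2`` table (PLINK-style); pairs below the
pruning threshold may be omitted by the producer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .em import FitConfig, FitResult, fit
from .liability import liability_variance, snp_variance_from_prior
from .model import EffectGrid, MixturePrior

logger = logging.getLogger(__name__)

__all__ = [
    "read_summary_table",
    "write_summary_table",
    "read_ld_pairs",
    "pvalue_prune",
    "random_prune",
    "daf_bins",
    "stratified_fit",
    "StratifiedResult",
]

_OPTIONAL_COLS = ("daf", "p_ref", "stratum")


def read_summary_table(path) -> pd.DataFrame:
    """Read per-SNP summary statistics from tab-delimited text.

    Requires ``snp_id``, ``beta`` and either ``se`` or ``var``; the
    variance is stored internally (se is squared).  Rows with malformed or
    non-positive uncertainty are rejected with a warning naming their line
    numbers; duplicate SNP ids raise.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=True)
    cols = set(raw.columns)
    if "snp_id" not in cols or "beta" not in cols:
        raise ValueError("summary table must declare snp_id and beta columns")
    if "se" in cols and "var" in cols:
        raise ValueError("declare either se or var, not both")
    if "se" not in cols and "var" not in cols:
        raise ValueError("summary table must declare an se or var column")
    unc_col = "se" if "se" in cols else "var"

    beta = pd.to_numeric(raw["beta"], errors="coerce")
    unc = pd.to_numeric(raw[unc_col], errors="coerce")
    var = unc**2 if unc_col == "se" else unc
    bad = beta.isna() | ~np.isfinite(beta) | var.isna() | (var <= 0)
    if bad.any():
        # +2: one for the header, one for 1-based numbering
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        warnings.warn(
            f"rejected {bad.sum()} malformed rows (lines {lines}): "
            f"beta/{unc_col} missing, non-numeric or non-positive"
        )
    frame = pd.DataFrame(
        {
            "snp_id": raw.loc[~bad, "snp_id"].to_numpy(),
            "beta": beta[~bad].to_numpy(dtype=float),
            "var": var[~bad].to_numpy(dtype=float),
        }
    )
    if frame["snp_id"].duplicated().any():
        dups = frame.loc[frame["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate SNP ids: {dups[:5]}")
    for col in _OPTIONAL_COLS:
        if col in cols:
            vals = raw.loc[~bad, col]
            if col == "stratum":
                frame[col] = vals.to_numpy()
            else:
                frame[col] = pd.to_numeric(vals, errors="coerce").to_numpy(dtype=float)
    if "daf" in frame.columns:
        out = frame["daf"].notna() & ((frame["daf"] <= 0) | (frame["daf"] >= 1))
        if out.any():
            raise ValueError("derived allele frequencies must lie strictly in (0, 1)")
    return frame


def write_summary_table(frame: pd.DataFrame, path, use_se: bool = False) -> None:
    """Write the canonical summary-statistic TSV ('.' for missing values)."""
    out = frame.copy()
    if use_se:
        out["se"] = np.sqrt(out.pop("var"))
        lead = ["snp_id", "beta", "se"]
    else:
        lead = ["snp_id", "beta", "var"]
    cols = lead + [c for c in _OPTIONAL_COLS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False, na_rep=".")


def read_ld_pairs(path) -> pd.DataFrame:
    """Read a SNP_A / SNP_B / R2 pairwise LD table."""
    tab = pd.read_csv(path, sep="\t")
    need = {"SNP_A", "SNP_B", "R2"}
    if not need.issubset(tab.columns):
        raise ValueError("LD table must declare SNP_A, SNP_B and R2 columns")
    tab["R2"] = pd.to_numeric(tab["R2"], errors="raise")
    return tab[["SNP_A", "SNP_B", "R2"]]


def _adjacency(ld_pairs, r2_threshold: float) -> dict:
    adj: dict = {}
    if ld_pairs is None or len(ld_pairs) == 0:
        return adj
    if isinstance(ld_pairs, pd.DataFrame):
        it = zip(ld_pairs["SNP_A"], ld_pairs["SNP_B"], ld_pairs["R2"])
    else:
        it = iter(ld_pairs)
    for a, b, r2 in it:
        if r2 > r2_threshold and a != b:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    return adj


def _greedy_prune(order: Sequence[str], adj: Mapping[str, set]) -> list:
    selected = []
    removed = set()
    for snp in order:
        if snp in removed:
            continue
        selected.append(snp)
        removed.update(adj.get(snp, ()))
    return selected


def pvalue_prune(
    snps,
    ref_pvalues: Optional[Mapping[str, float]] = None,
    ld_pairs=None,
    r2_threshold: float = 0.1,
) -> list:
    """Greedy P-value-based LD pruning.

    Repeatedly selects the remaining SNP with the smallest reference
    P-value and removes every remaining SNP in LD (r2 > threshold) with
    it, until none remain.  Returns the selected ids in selection order.
    SNPs absent from the LD table are treated as unlinked; SNPs without a
    reference P-value are excluded with a warning.  Ties are broken
    lexicographically by snp_id.
    """
    if isinstance(snps, pd.DataFrame):
        ids = snps["snp_id"].tolist()
        if ref_pvalues is None:
            if "p_ref" not in snps.columns:
                raise ValueError("no reference P-values available")
            ref_pvalues = dict(zip(ids, snps["p_ref"]))
    else:
        ids = list(snps)
        if ref_pvalues is None:
            raise ValueError("no reference P-values available")
    have_p = [s for s in ids if ref_pvalues.get(s) is not None
              and np.isfinite(ref_pvalues[s])]
    if len(have_p) < len(ids):
        warnings.warn(
            f"{len(ids) - len(have_p)} SNPs lack a reference P-value and were excluded"
        )
    order = sorted(have_p, key=lambda s: (ref_pvalues[s], s))
    return _greedy_prune(order, _adjacency(ld_pairs, r2_threshold))


def random_prune(snps, ld_pairs=None, r2_threshold: float = 0.1, seed: int = 0) -> list:
    """LD pruning with uniform-random selection order (seeded)."""
    ids = snps["snp_id"].tolist() if isinstance(snps, pd.DataFrame) else list(snps)
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return _greedy_prune(order, _adjacency(ld_pairs, r2_threshold))


def daf_bins(snps, n_bins: int = 5) -> pd.Series:
    """Assign SNPs to equal-width derived-allele-frequency bins.

    Bin k (1-based) covers ((k-1)/n_bins, k/n_bins]; edges are
    right-closed, so with five bins daf = 0.2 falls in bin 1 ("DAF <= 0.2")
    and daf > 0.8 in bin 5.  SNPs without a frequency are left unassigned
    (NaN) with a warning.
    """
    frame = snps if isinstance(snps, pd.DataFrame) else pd.DataFrame({"daf": snps})
    daf = pd.to_numeric(frame["daf"], errors="coerce")
    missing = daf.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} SNPs lack a frequency and were not binned")
    # guard the right-closed edges against float fuzz in daf * n_bins
    k = np.ceil(np.round(daf.to_numpy(dtype=float) * n_bins, 9))
    k = np.clip(k, 1, n_bins)
    k[missing.to_numpy()] = np.nan
    return pd.Series(k, index=frame.index, name="daf_bin")


@dataclass(frozen=True)
class StratifiedResult:
    """Independent mixture fits per stratum plus a comparison table."""

    fits: dict  # stratum -> FitResult
    summary: pd.DataFrame  # stratum, n_snps, pi_hat, mean_v_hat (if K given)
    skipped: list


def stratified_fit(
    data: pd.DataFrame,
    strata: Optional[pd.Series] = None,
    config: Optional[FitConfig] = None,
    prevalence: Optional[float] = None,
    min_snps: int = 100,
) -> StratifiedResult:
    """Fit the mixture independently within each stratum.

    ``strata`` defaults to the data's ``stratum`` column.  Strata below
    ``min_snps`` SNPs are skipped with a warning.  When ``prevalence`` is
    given and frequencies are present, the per-SNP mean liability variance
    is reported per stratum; the ratio of two strata's means is their
    fold-enrichment.
    """
    config = config or FitConfig()
    if strata is None:
        if "stratum" not in data.columns:
            raise ValueError("no stratum labels available")
        strata = data["stratum"]
    strata = pd.Series(np.asarray(strata), index=data.index)
    fits = {}
    rows = []
    skipped = []
    for label in pd.unique(strata.dropna()):
        sub = data[strata == label]
        if len(sub) < min_snps:
            warnings.warn(
                f"stratum {label!r} has {len(sub)} SNPs (< {min_snps}); skipped"
            )
            skipped.append(str(label))
            continue
        res = fit(sub, config)
        fits[str(label)] = res
        row = {"stratum": str(label), "n_snps": len(sub), "pi_hat": res.prior.pi}
        if prevalence is not None and "daf" in sub.columns:
            daf = pd.to_numeric(sub["daf"], errors="coerce")
            p_ok = daf[(daf > 0) & (daf < 1)].to_numpy(dtype=float)
            if p_ok.size:
                v_grid = liability_variance(
                    res.grid.points[None, :], p_ok[:, None], prevalence
                )
                row["mean_v_hat"] = float(
                    (res.prior.pi * (v_grid @ res.prior.masses)).mean()
                )
        rows.append(row)
    return StratifiedResult(fits=fits, summary=pd.DataFrame(rows), skipped=skipped)
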