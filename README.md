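# sphmm

Polygenic architecture estimation from GWAS summary statistics with a
semi-parametric hierarchical mixture model (SP-HMM).

Given per-SNP estimated log-odds ratios and their standard errors from a
case-control GWAS, `sphmm` estimates

* **π** — the proportion of SNPs truly associated with the disease,
* **g** — the effect-size distribution of the associated SNPs, estimated
  nonparametrically,
* per-SNP **posterior effect sizes** (shrunken, winner's-curse-adjusted) and
  posterior probabilities of association, and
* **V** — the liability-scale variance explained by the SNP set
  (SNP heritability), via the liability threshold model.

It is aimed at statistical geneticists who have summary statistics from a
large case-control GWAS (no individual-level genotypes needed) and want a
compact description of the trait's polygenic architecture.

## Model

For an LD-pruned panel of m approximately independent SNPs, the observed
log-odds ratio `y_j` of the derived allele has the two-group marginal density

```
f_j(y_j) = (1 − π) N(y_j; 0, v_j) + π ∫ N(y_j; β, v_j) g(β) dβ
```

where `v_j` is the SNP's empirical sampling variance and g is supported on a
fixed grid of 120 nonzero points b = (−0.300, −0.295, …, −0.005, 0.005, …,
0.300) with estimated masses p. The pair (π, p) is estimated by maximum
marginal likelihood with an EM algorithm of the smoothing-and-roughening
type, in three stages: a candidate-π sweep (π₀ = 0.1, …, 0.9; 200 EM
iterations each; best likelihood wins), a warm-up of the masses at frozen π,
and a final full EM stopped when π changes by less than 0.005% per
iteration. Standard errors come from a parametric bootstrap of the fitted
model. With the fitted prior, each SNP's log-odds-ratio effect is converted
to liability-scale variance using its derived allele frequency and the
disease prevalence K, and the SNP-set heritability is the sum of the per-SNP
values.

See `docs/methods.md` for assumptions, parameter choices, and limitations.

## Worked example

Simulate a study with 10% associated SNPs, effects N(0, 0.03²), and 100,000
cases and controls, then fit:

```python
import numpy as np
from sphmm import fit, total_variance, rank_snps
from sphmm.simulate import SimConfig, simulate_dataset

sim = simulate_dataset(SimConfig(m=10_000, pi_true=0.1, seed=7))
res = fit(sim.frame)
print(f"pi_hat = {res.prior.pi:.4f}  (true 0.1)")
in_3sd = res.prior.masses[np.abs(res.grid.points) <= 0.09].sum()
print(f"fitted g mass within |beta| <= 0.09: {in_3sd:.3f}")
rep = total_variance(sim.frame, res.prior, res.grid, K=0.01)
print(f"V_hat = {rep.V_hat:.4f} over {rep.n_used} SNPs (K = 0.01)")
top = rank_snps(sim.frame, res.prior, res.grid, threshold_abs_beta=0.05)
print(top.head(3).to_string(index=False))
```

prints

```
pi_hat = 0.0910  (true 0.1)
fitted g mass within |beta| <= 0.09: 0.998
V_hat = 0.0404 over 10000 SNPs (K = 0.01)
    snp_id         y        v  p_nonnull  post_mean  post_mean_OR
snp0000790  0.106175 0.000110        1.0   0.098599      1.103624
snp0009475  0.095200 0.000057        1.0   0.096976      1.101834
snp0005291 -0.085663 0.000043        1.0  -0.076676      0.926190
```

The fitted π recovers the simulated 10%; essentially all fitted effect-size
mass lies within three true SDs (|β| ≤ 0.09); and the top-ranked SNPs'
posterior mean effects are shrunken relative to their raw estimates `y`.
At a 1% prevalence this panel explains about 4% of liability variance.

The same pipeline is available from a shell:

```sh
sphmm simulate --m 10000 --pi 0.1 --seed 7 --out sim.tsv
sphmm fit sim.tsv --out fit.json
sphmm heritability sim.tsv --fit-json fit.json --prevalence 0.01 --out V.json
sphmm posterior sim.tsv --fit-json fit.json --threshold 0.05 --out top.tsv
```

plus `prune` (P-value-based or random LD pruning at r² > 0.1), `bootstrap`
(parametric bootstrap SEs) and `stratify` (per-stratum or DAF-bin fits).

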