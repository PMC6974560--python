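# cuephylo

Carbon use efficiency (CUE) of cultured soil bacteria: estimation from
growth/respiration curves, temperature sensitivity, phylogenetic comparative
analysis, and genomic marker discovery.

Heterotrophic bacteria split the carbon they consume between new biomass and
respired CO2.  The fraction retained as biomass — the carbon use efficiency

```
CUE = mu / (mu + R)
```

— links microbial physiology to soil carbon storage: mu is the intrinsic
growth rate (slope of ln biomass-C vs time in the exponential phase, h^-1)
and R the mass-specific respiration rate over the same window.  This package
implements the full computational chain of a culture-based CUE study for
microbial ecologists and comparative genomicists:

* **`growth_cue`** — CUE per replicate from OD600 and headspace CO2 time
  series: exponential-window detection (3-10 points maximising the
  ln-biomass slope), OLS rate fits with slope F-tests, discard rules
  (either slope p > 0.05; fewer than 2 surviving replicates per condition).
* **`temp_response`** — Q10 = (CUE_2/CUE_1)^(10/dT) per isolate x substrate
  with an all-replicate-pairs SE and a bootstrap 95% CI; a condition is
  *temperature sensitive* when the CI excludes 1.
* **`phylocomp`** — Blomberg's K (permutation test), Pagel's lambda by ML
  (LRT), Brownian-motion reference intervals on the observed tree,
  leave-one-out prediction of unsampled tips on the lambda-rescaled tree,
  and PGLS regression with lambda profiled by ML.
* **`markers`** — explore/validate discovery of genomic markers of CUE:
  per-KO PGLS on an exploration taxon set, confirmation on the full glucose
  set, validation in >= 2 of 3 other substrates or in community (microcosm)
  data by Spearman correlation, rare-function removal, and residual
  phylogenetic-signal diagnostics.
* **`exoenzyme_cost`** — theoretical CUE of exoenzyme production from
  protein composition: per-residue ATP biosynthesis costs + 4.2 ATP per
  peptide bond, 26 ATP per 6 glucose C respired, expression-weighted by
  codon adaptation (CAI) against a highly expressed reference gene set.
* **`stats`** — self-contained repeated-measures correlation and Hartigan's
  dip test (exact statistic, Monte-Carlo p against the uniform null).
* **`synthetic_data`** — generators for every input (growth assays, trees,
  lambda-BM traits, KO tables with planted causal effects, communities,
  codon-biased CDS) with recorded ground truth.
* **`cuephylo` CLI / `pipeline`** — one-command end-to-end runs with a YAML
  config and a hash-recorded manifest.

## Worked example

Estimate CUE for one isolate assayed at two temperatures (three replicates
each, simulated here so the truth is known: CUE 0.62 at 15 C, 0.50 at 25 C),
then its Q10, then phylogenetic signal of a CUE-like trait on a 24-tip tree:

```python
import pandas as pd
from cuephylo import synthetic_data as sd, growth_cue as gc
from cuephylo import temp_response as tr, phylocomp as pc

consts = gc.AssayConstants()           # 130 ug C OD^-1 ml^-1, 10 ml culture
rows = []
for temp, mu, cue in [(15.0, 0.30, 0.62), (25.0, 0.42, 0.50)]:
    p = sd.GrowthSimParams(mu_true=mu, cue_true=cue, temperature_c=temp,
                           seed=int(temp))
    curves, _ = sd.simulate_growth_experiment(p, 3, isolate="iso1")
    rows.append(gc.estimate_cue_table(curves, consts))
table = gc.qc_filter(pd.concat(rows, ignore_index=True))

lo = table.loc[table.temperature_c == 15, "cue"]
hi = table.loc[table.temperature_c == 25, "cue"]
est = tr.bootstrap_q10(lo, hi, 15, 25, seed=1)
print(f"Q10 = {est.q10:.3f}  95% CI [{est.ci_low:.3f}, {est.ci_high:.3f}]")

tree = sd.simulate_tree(sd.TreeSimParams(n_tips=24, seed=5))
trait = sd.simulate_trait_bm(tree, sd.TraitSimParams(
    sigma2=0.004, lambda_sim=0.8, root_value=0.55, seed=6))
sig = pc.phylo_signal(tree, trait, n_perm=999, seed=7)
print(f"K = {sig.k:.3f} (p = {sig.k_p:.3f}), "
      f"lambda = {sig.lambda_hat:.3f} (LRT p = {sig.lambda_p:.4f})")
```

This prints:

```
Q10 = 0.802  95% CI [0.789, 0.814]
K = 0.582 (p = 0.029), lambda = 1.000 (LRT p = 0.5184)
```

The recovered replicate CUEs are 0.628-0.632 at 15 C and 0.500-0.508 at
25 C (truth 0.62/0.50); the CI excluding 1 classifies this isolate's CUE as
temperature sensitive (it declines by ~20% per 10 C).  The clustered trait
shows significant signal by the permutation test (p = 0.029) with the ML
lambda at the Brownian-motion boundary.

The same analyses run from the shell (`cuephylo simulate | cue | q10 |
phylosig | predict-tips | pgls | markers | enzyme-cost | rmcorr | diptest |
run | report`); `cuephylo run examples/config.yaml` executes an end-to-end
study into a manifest-tracked run directory.

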