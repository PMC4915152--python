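# omicsfill

Ensemble imputation of missing values in multi-omics data.

## The problem

Omics matrices (mRNA, miRNA, DNA methylation, proteomics, …) measured on
the same subjects almost always contain missing entries — detection
limits, contaminated array regions, incomplete peptide coverage — and
integrative analyses require complete matrices. Classical imputers (KNN,
SVD, BPCA, LLS, iLLS) use only the damaged matrix itself. `omicsfill`
additionally borrows strength from the *other* layers: features across
omics layers are correlated through shared biology, so a missing miRNA
value can be predicted from correlated mRNAs as well as from neighbouring
miRNAs.

## The method

For a target layer G1 with missing entries and complete (or currently
filled) layers G2…Gm:

1. **Basic models.** Self-imputation of G1, plus one cross-imputation per
   other layer: each target feature g_t is stacked on its significantly
   correlated (Pearson p < 0.05) features of the source layer to form an
   augmented matrix H, which a single-omics engine imputes on a z-scored
   scale. Each model is re-run B times on feature subsamples for
   diversity; a prior edge list (e.g. STRING scores > 0.9) can force
   source features into the LLS/iLLS regression.
2. **Simplex weights.** Observed entries are hidden at random ("faking
   missing", truth known) and the truth is regressed on the basic models'
   predictions there under β ≥ 0, Σβ = 1 — non-negativity handles the
   strong collinearity between models and prunes non-contributors.
   Weights are averaged over T bootstrap rounds.
3. **Combination.** Each true missing entry is the β-weighted average of
   the basic models' estimates.
4. **Iterative extension.** When several layers are incomplete, all are
   first self-imputed, then cyclically re-imputed by steps 1–3 using the
   current filled state of the other layers (smallest missing-feature
   count first), until the summed squared change at the missing locations,
   δ_h, normalised per entry and by scale, drops below τ.

Accuracy is reported as NRMSE = sqrt(mean((true − imputed)²) / var(true))
at the masked locations: 0 is perfect, ≈ 1 is as bad as predicting the
mean. See `docs/methods.md` for the full model description, parameter
defaults, and numerical choices.

## Worked example

```python
import numpy as np
from omicsfill import (SimulationConfig, generate_multiomics, inject_mcar,
                       ImputerConfig, EnsembleConfig, impute,
                       multi_omics_impute, nrmse)

# TCGA-like synthetic set: mRNA 300x50, miRNA 60x50, methylation 250x50,
# correlated through rank-3 latent factors, noise sd 0.3
truth = generate_multiomics(SimulationConfig(seed=7))
mirna, loc = inject_mcar(truth[1], rate=0.10, seed=7)   # 10% MCAR

base = ImputerConfig(method="lls", k_lls=10)
self_only = impute(mirna, base)
result = multi_omics_impute(mirna, [truth[0], truth[2]],
                            EnsembleConfig(B=2, T=10, base=base, seed=7))

print(f"self-only NRMSE : {nrmse([truth[1]], [self_only], loc):.4f}")
print(f"multi-omics NRMSE: {nrmse([truth[1]], [result.matrix], loc):.4f}")
print("weight per source:", {k: round(v, 3)
                             for k, v in result.report['weights_by_source'].items()})
```

Output:

```
self-only NRMSE : 0.3281
multi-omics NRMSE: 0.2186
weight per source: {'self': 0.16, 'mRNA': 0.287, 'methylation': 0.553}
```

The ensemble cuts the imputation error of the small miRNA layer by about
a third relative to self-imputation, and the fitted weights show most of
the signal coming from the two larger correlated layers.

The same pipeline is scriptable from the shell:

```bash
omicsfill simulate --n-samples 50 --features 300,60,250 --missing-rate 0.1 \
    --seed 7 --out sim/
omicsfill impute-multi --target sim/omics2.tsv \
    --others sim/omics1.tsv --others sim/omics3.tsv \
    --method lls --k-lls 10 --seed 7 --out out/
omicsfill impute-iterative --matrices g1.tsv --matrices g2.tsv \
    --method lls --tau 1e-4 --max-iter 10 --out iter/
```

Every run writes a `manifest.json` (resolved config, seed, version,
timings, warnings) sufficient to reproduce it.

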