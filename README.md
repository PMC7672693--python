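# dynherit

Bayesian Gaussian-process estimation of **dynamic variance components and
SNP-heritability** from longitudinal phenotypes and a genomic relationship
matrix (GRM).

The joint model places Matérn-1.5 GP priors on the log genetic and log
environmental variance curves and samples them with a whitened MCMC scheme:
elliptical slice sampling for the whitened curve coordinates and adaptive
random-walk Metropolis–Hastings (target acceptance 0.44) for the GP length
scales, whose log-normal hyperprior is solved from the time grid so the
method has no tuning parameters. The likelihood is factorized over time
points through the eigendecomposition of the GRM, so no NT×NT matrix is ever
formed. A two-stage baseline (independent per-time-point fits followed by GP
smoothing of the logarithmized posterior summaries) is included for
uncertainty-width comparisons, along with posterior breeding values, SNP
effect back-transformation, and synthetic-data generators for longitudinal
polygenic and twin designs.

## Package layout

| module | contents |
|---|---|
| `dynherit.grm` | genotype matrix type, mean imputation, allele frequencies, VanRaden GRM, SNP-effect back-transformation |
| `dynherit.gpcov` | Matérn-1.5 kernel, covariance matrices, PSD matrix square roots, length-scale hyperprior solve |
| `dynherit.likelihood` | phenotype panel, center/scale to mean total variance 2, GRM eigendecomposition, factorized log-likelihood |
| `dynherit.samplers` | elliptical slice sampling, adaptive random-walk MH |
| `dynherit.joint_model` | whitened joint MCMC, posterior summaries, breeding values |
| `dynherit.two_stage` | per-time-point stage-one fits, GP smoothing stage two |
| `dynherit.simdata` | longitudinal and twin-design simulators with known truth curves |
| `dynherit.cli_io` | TSV/JSON readers and writers, run configuration, CLI |

## Command line

```bash
# simulate a dataset (phenotype.tsv, grm.tsv, truth.tsv)
dynherit simulate --n 300 --t 20 --seed 1 --out sim/

# joint estimation (either --grm FILE or --geno FILE to build the VanRaden GRM)
dynherit joint --pheno sim/phenotype.tsv --grm sim/grm.tsv \
    --iters 20000 --thin 10 --seed 1 --out run_joint/

# two-stage baseline
dynherit twostage --pheno sim/phenotype.tsv --grm sim/grm.tsv \
    --iters 4000 --seed 2 --out run_twostage/

# re-summarize stored draws
dynherit summarize --draws run_joint/ --out resummary/
```

Each run directory contains curve summaries
(`summary_{sigma2_G,sigma2_E,h2}.tsv` with columns time/mean/lower95/upper95),
full thinned draws as TSV, `metadata.json` echoing the configuration and seed
(re-running with the echoed configuration reproduces the draws bitwise), and
`run.log`. A `--config FILE` (YAML/JSON) can override the flags.

File formats are plain TSV: phenotypes with numeric time labels in the header
and individual IDs in the first column (no missing values); genotypes coded
−1/0/1 with `NA` or empty for missing; relationship matrices with IDs in both
header and first column.

## Python API sketch

```python
import numpy as np
from dynherit import (TimeGrid, default_truth_curves, simulate_longitudinal,
                      run_joint_mcmc, summarize)

grid = TimeGrid(np.arange(1.0, 21.0))
sg, se = default_truth_curves(grid)
panel, truth = simulate_longitudinal(300, grid, sg, se, seed=101)
draws = run_joint_mcmc(panel, truth.G_true, iterations=20000, seed=1)
sigma2_G, sigma2_E, h2 = summarize(draws)
```

Draws are stored on the analysis scale (data rescaled so the mean total
variance over time points is 2); `draws.meta["scale_factor"]` maps variance
components back to the original phenotype scale, and h² is scale-free.

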