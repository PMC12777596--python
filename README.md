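# sparsespect

Sparse-view SPECT simulation, OSEM reconstruction, edge-preserving
denoising and image-quality evaluation for ⁹⁹ᵐTc-PSMA pelvic imaging.

Conventional SPECT acquires many angular views over 360°, which keeps
patients on the table for 15–20 minutes.  Acquiring fewer views cuts scan
time proportionally, at the cost of noise and angular-aliasing artifacts.
This package reproduces that trade-off end to end for prostate
(⁹⁹ᵐTc-PSMA) imaging: it simulates pelvic activity phantoms, generates
Poisson projection data at 60 views over 360°, decimates to 30/15/10
views, reconstructs with ordered-subsets expectation maximization, applies
Gaussian or nonlocal-means (NLM) post-filters, and scores everything with
an ROI-based metric suite.  It is aimed at medical-physics researchers
studying acquisition protocols and post-reconstruction filtering.

## The model in brief

Projection counts are independent Poisson draws with means p = A x, where
a_ij is the exact ray/pixel intersection length of a parallel-beam
geometry.  OSEM maximises the Poisson log-likelihood
ℓ(x) = Σᵢ (yᵢ ln p̂ᵢ − p̂ᵢ) by cycling multiplicative updates over
interleaved view subsets:

    x_j ← x_j · [Σ_{i∈S_b} a_ij y_i / p̂_i] / [Σ_{i∈S_b} a_ij]

(default 9 iterations × 5 subsets).  The NLM filter replaces each voxel by
a patch-similarity-weighted average,

    out(j) = Σ_{i∈N_j} w(j,i) x(i),   w(j,i) ∝ exp(−‖x(ν_j) − x(ν_i)‖²_{2,α} / h²),

with a Gaussian-weighted patch distance and automatic bandwidth h tied to
a robust noise-SD estimate.  Reduced-view reconstructions are compared
against the unfiltered 60-view reconstruction using MAPE (ROI-mean
percentage error), NRMSE, PSNR, normalized bias (NB), percent change
between filter conditions, and the intraclass correlation coefficient
(ICC) for reader agreement.  See `docs/methods.md` for conventions and
assumptions.

## Worked example

The package ships the ten-patient evaluation tables of the accompanying
study as fixtures.  Aggregating the 30-view table and the reader scores:

```python
from sparsespect import report
from sparsespect.datasets import load_filter_study, load_reader_scores

print(report(load_filter_study(30), load_reader_scores()))
```

prints (excerpt):

```
| views | ROI | filter | mean MAPE |
|---|---|---|---|
| 30 | ROI1 | nlm | 5.05 |
| 30 | ROI1 | none | 6.96 |
...
| metric | views | comparison | max |PC| % | case |
| nrmse | 30 | gaussian → nlm | 27.11 | 2 |
| nrmse | 30 | none → nlm | 39.34 | 2 |
| psnr | 30 | none → nlm | 4.52 | 2 |
...
| ROI1 | 30 | gaussian → nlm | 2.24 | 2 |
| ROI1 | 30 | none → nlm | 4.47 | 6 |
```

Reading: halving the acquisition to 30 views leaves the lesion-ROI mean
within ~7% of the full-view reference on average before filtering; NLM
post-filtering reduces whole-image NRMSE by up to 39% relative to no
filter (27% relative to Gaussian) with the strongest response in
patient 2, and trims lesion MAPE by up to 4.47 percentage points.

A fully synthetic experiment (phantom → projection → Poisson sampling →
decimation → OSEM → filters → metrics) runs in under a minute:

```python
from sparsespect import RunConfig, run_experiment

table = run_experiment(RunConfig(n_cases=10, seed=1))
print(table.groupby(["n_views", "filter"])["mape_roi1"].mean().round(2))
```

```
n_views  filter
10       gaussian    38.90
         nlm         21.20
         none        21.20
15       gaussian    30.88
         nlm          4.16
         none         4.16
30       gaussian    30.64
         nlm          3.81
         none         3.81
```

The lesion-ROI error is small at 30 views, similar at 15, and collapses
at 10 views where angular undersampling folds structure over itself —
the same ordering the clinical study reports (10-view imaging is flagged
not recommended in the generated report).

The same pipeline is scriptable from the shell:

```bash
sparsespect run --cases 10 --seed 1 --outdir results/run1
sparsespect report results/run1/metrics.csv
```

plus stage-by-stage subcommands (`phantom`, `project`, `decimate`,
`reconstruct`, `filter`, `evaluate`) operating on NIfTI volumes with JSON
sidecars.

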