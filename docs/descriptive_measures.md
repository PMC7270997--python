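# Recomputed descriptive measures of the NE-W distribution

All values below are computed by `nexdist.describe` — adaptive quadrature
against the NE-W density g(x; θ, α, γ), with central moments integrated
directly.  Skewness Sk = μ₃/μ₂^(3/2) and kurtosis Kur = μ₄/μ₂² (not excess).
Regenerate with `python scripts/make_descriptive_tables.py`.

## Grid 1 — α = 0.9, γ = 1, θ varying

| θ | Mean | Variance | Sk | Kur | published Mean | published Variance |
|---|---|---|---|---|---|---|
| 0.9 | 1.8430 | 2.3185 | 1.8586 | 8.5964 | 5.4664 | 130.8709 |
| 1.3 | 1.1532 | 0.9435 | 1.9666 | 9.2735 | 3.7934 | 51.8976 |
| 1.7 | 0.8032 | 0.4569 | 2.0550 | 10.0151 | 2.4670 | 20.6752 |
| 2.1 | 0.5999 | 0.2477 | 2.0955 | 10.5227 | 1.5690 | 9.5649 |
| 2.4 | 0.4982 | 0.1657 | 2.0948 | 10.6905 | 1.3409 | 4.5409 |
| 2.8 | 0.4022 | 0.1032 | 2.0616 | 10.6462 | 0.9675 | 2.0987 |


## Grid 2 — θ = 0.5, γ = 1, α varying

| α | Mean | Variance | Sk | Kur | published Mean | published Variance |
|---|---|---|---|---|---|---|
| 0.7 | 5.7583 | 36.7515 | 2.7494 | 16.2436 | 9.9876 | 311.9087 |
| 1.1 | 2.7440 | 3.1670 | 1.3591 | 5.9802 | 8.2354 | 236.9876 |
| 1.5 | 2.0152 | 0.9277 | 0.8180 | 4.0250 | 7.0488 | 155.2345 |
| 2.5 | 1.4803 | 0.1893 | 0.2340 | 3.0699 | 5.7539 | 45.5309 |
| 4.5 | 1.2296 | 0.0428 | -0.1853 | 3.1126 | 3.9876 | 30.0965 |


## Discrepancy against previously published values

Published descriptive-measure tables for this distribution (the "published"
columns above) are **inconsistent with the distribution's own density**: at
(α = 0.9, γ = 1, θ = 0.9) they report mean 5.4664 and variance 130.8709,
whereas direct quadrature of x·g(x) under the same density gives
1.8430 and 2.3185.  The independent
series representation of the moments and the sampler agree with quadrature
(see the test suite), so the recomputed values are the consistent ones.
The published α-grid also lists two different rows for the same α = 4.5;
only one α = 4.5 entry can be meaningful, so the grid here keeps a single
α = 4.5 row.

Directional claims partly survive the recomputation: the mean and variance
do decrease as θ increases (grid 1).  Skewness and kurtosis increase with θ
only up to θ ≈ 2.4 and then level off slightly, rather than increasing
monotonically as the published grid suggests.
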