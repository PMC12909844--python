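# latentniche

Tools for uncovering **hidden niche axes** of a regional community from
presence/absence detections — the kind of species-by-site matrix produced by
eDNA metabarcoding surveys along a coastline — and for asking what those axes
imply about biogeographic boundaries and the response diversity of local
communities.

## Who this is for

Community ecologists and biostatisticians with a detection matrix (read
counts or presence/absence of hundreds of species at hundreds of sites), site
coordinates, and a few measured environmental covariates, who want to model
species co-occurrence jointly rather than species-by-species.

## The model

The core is a Bernoulli generalised linear latent variable model (GLLVM)
with spatially autocorrelated latent variables. For species *j* at site *i*:

```
y_ij ~ Bernoulli(p_ij)
logit(p_ij) = β_j0 + x_i' β_j + u_i' γ_j + α_i
```

- `x_i` — measured covariates (e.g. temperature, salinity), with
  species-specific responses `β_j`;
- `u_i` — a small number of latent variables with species-specific loadings
  `γ_j`. Each latent field has a Matérn Gaussian-process prior over space,
  represented by a sparse nearest-neighbour GMRF precision, so residual
  co-occurrence is decomposed into a few smooth spatial "niche axes";
- `α_i` — site random effects absorbing site-level detectability (total eDNA
  concentration);
- loadings are identified by the standard constraint (upper triangle zero,
  positive diagonal).

Estimation maximises the penalized joint log-likelihood by L-BFGS, with the
spatial ranges profiled and the site-effect variance updated between passes.
Around the model sit: preprocessing (rarefaction of read counts, removal of
species-complex taxa, of rare taxa and of sites with missing covariates),
five-fold cross-validated selection among candidate models (covariate sets ×
latent dimensions), variance partitioning, niche-space analysis (kernel
density niche centres, zero-value boundary lines of the interpolated latent
fields) and expected response diversity (mean IQR of loadings over
communities simulated from the fitted probabilities, with spectral clustering
and log-log richness regressions). A synthetic-data module generates coastal
communities from exactly this generative model, with full ground truth, for
validation.

## Worked example

```python
import numpy as np
from latentniche import (SyntheticConfig, generate_communities, SpatialGLLVM,
                         variance_partition)
from scipy.linalg import orthogonal_procrustes

cfg = SyntheticConfig(n_sites=200, n_species=60, n_latent=2,
                      matern_ranges=(0.3, 0.6), seed=11)
truth, detections, sites = generate_communities(cfg)
Y = detections.data.to_numpy().T.astype(float)

model = SpatialGLLVM(n_latent=2).fit(Y, truth.coords, truth.covariates)

R, _ = orthogonal_procrustes(model.latent_fields_, truth.latent_fields)
aligned = model.latent_fields_ @ R
for k in range(2):
    print(f"LV{k+1} recovery r = "
          f"{np.corrcoef(aligned[:, k], truth.latent_fields[:, k])[0, 1]:.3f}")
print(variance_partition(model, covariate_names=['temperature', 'salinity']))
```

Output:

```
LV1 recovery r = 0.880
LV2 recovery r = 0.934
temperature    0.207946
salinity       0.186697
latent_1       0.312608
latent_2       0.292749
Name: variance_fraction, dtype: float64
```

The two fitted latent fields correlate 0.88 and 0.93 with the generating
fields after Procrustes alignment (latent axes are only identified up to
rotation and sign), and the variance partition attributes ~61% of the
across-site variance in the linear predictor to the two latent axes versus
~39% to the two measured covariates.

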