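# Methods

## Model

Detections are modelled as `y_ij ~ Bernoulli(p_ij)` with

```
logit(p_ij) = β_j0 + x_i' β_j + u_i' γ_j + α_i .
```

The latent variables `u` (up to five) are zero-mean Gaussian fields over the
site set with Matérn covariance

```
C(d) = σ_u² · 2^{1−ν}/Γ(ν) · (κd)^ν K_ν(κd),   κ = √(8ν)/ρ,
```

so that the *practical range* ρ is the distance at which correlation falls
to ≈ 0.14. Supported smoothness values are ν ∈ {0.5, 1, 1.5} (default 1.5).
The marginal sd σ_u is fixed at 1: the field scale is absorbed by the
loadings, and downstream analyses use sd-scaled fields regardless. Distances
are Euclidean for synthetic planar coordinates and haversine kilometres for
longitude/latitude data; the convention is declared on the site table.

For fitting, each field's dense covariance is replaced by a sparse GMRF
precision built by nearest-neighbour (Vecchia) conditioning: sites ordered
along the first coordinate, each conditioned on its `m = 10` nearest
predecessors. With full conditioning (`m = n − 1`) the precision is exactly
the inverse of the dense covariance, which is how it is tested.

Loadings follow the standard GLLVM identifiability constraint: the
`n_latent × n_species` matrix Γ has zeros above the diagonal and a positive
diagonal (parametrised on the log scale), removing rotation and sign
indeterminacy up to the usual residual reflection — recovery comparisons
against ground truth therefore always align by orthogonal Procrustes first.

## Estimation

The penalized joint log-likelihood — Bernoulli likelihood plus the GMRF
prior on each latent field, the `N(0, σ_α²)` prior on site effects, and a
`N(0, σ_γ²)` prior on loadings (default σ_γ = 1) — is maximised with L-BFGS
over all parameters jointly (a posterior-mode / Laplace-mode approximation).
Between passes two hyperparameters are updated (3 outer passes by default):

- **ranges ρ_k**: 1-D profile of the GMRF log-density of the current field
  over a 10-point log grid from twice the median nearest-neighbour spacing
  to the domain diameter. Because the profile treats the posterior-mode
  field as observed, fitted ranges are biased upward (mode fields are
  smoother than draws); this has little effect on recovery or kriging.
- **σ_α**: Laplace-EM update `σ_α² ← mean(α_i² + 1/h_i)` with `h_i` the
  Hessian diagonal of the site-effect block.

The loading prior is not cosmetic: under joint-mode estimation the
likelihood is invariant to `U → cU, Γ → Γ/c`, and the field prior alone
drives `c → 0` (fields collapse, loadings explode). The `N(0, σ_γ²)` prior
pins the scale at the generative one. A tiny ridge (`1e−6`) on intercepts
and covariate coefficients guards against separation for very sparse
species. Initialisation: intercepts at `logit(prevalence)` (clipped),
latent fields and loadings from an SVD of the centred detection matrix with
diagonal signs flipped to satisfy the constraint. The objective value at
each accepted L-BFGS iterate is recorded and is non-increasing; hitting the
iteration cap raises a warning and sets `converged_ = False`, never a silent
return.

## Prediction and cross-validation

Latent fields at new sites are kriged: `E[u*|u] = C(new,train) C⁻¹ u`, which
reproduces training values exactly and decays to the prior mean far from all
sites. Site effects of unseen sites are set to their prior mean 0 (fitted
values are reused when coordinates match a training site exactly).
`predict_proba(..., marginal=True)` additionally integrates over the
predictive uncertainty of `u*` and `α` with the logistic-normal probit
approximation `E[expit(η)] ≈ expit(η/√(1 + πs²/8))`; the plug-in conditional
mode is the default.

Model selection uses 5-fold cross-validation on sites: one seeded random
permutation defines folds shared by all candidates; each candidate is fitted
on 4/5 of the sites and scored by the mean per-cell negative log-likelihood
of the held-out sites using the *marginal* predictive probabilities. The
moderation matters: plug-in probabilities at held-out sites are
overconfident, which systematically favours smaller latent dimensions. The
candidate grid helper enumerates covariate sets × latent dimensions 0–5
(three sets give 18 candidates).

## Variance partitioning

Per species, the across-site variance of each linear-predictor component is
computed (`x_ic β_cj` per covariate, `u_ik γ_kj` per latent dimension);
intercepts and site effects are excluded. By default component variances are
pooled over species and normalized once. The alternative
(`species_weights="equal"`) normalizes within species first and averages;
it gives every species equal weight but has a noise floor — species with
weak signal contribute pure noise ratios — so it does not converge to zero
covariate share under null covariate effects. The pooled version does, in
identifiable designs.

**Limitation — spatial confounding.** When covariates are themselves smooth
spatial gradients along the coastline (as the synthetic generator makes
them, mimicking temperature/salinity), they are nearly within the span of
the latent fields and the likelihood cannot attribute shared smooth
variation; fitted covariate shares of 5–15% arise even when true covariate
effects are zero, regardless of aggregation or coefficient priors. Variance
fractions for strongly spatially structured covariates should be read as
model-conditional descriptions, not causal attributions.

## Niche space and boundaries

Site positions in niche space are the latent fields divided by their
across-site sd (loadings multiplied accordingly — a model-invariant
rescaling). A species' niche centre is the argmax, on a 200×200 grid
covering the positions with a 10% margin, of a Gaussian KDE over the
positions of its occupied sites; bandwidth is Silverman's rule per axis
(overridable), ties break to the lowest flat grid index. Region
classification assigns centres to sign quadrants of (LV1, LV2); the
quadrant→name mapping is a declared convention since latent signs are
arbitrary, and a centre exactly on a zero line counts as positive.

Geographic latent surfaces are kriged on a rectilinear grid and zero-value
boundary lines extracted by marching squares at level 0; chains shorter than
3 vertices are dropped. If ≥ 20% of grid cells have |value| < 0.1·sd the
surface is declared a broad zero-value area and reported as *no boundary*
(near-zero fields everywhere indicate no community turnover line, not many).
A constant surface yields an empty set with a note.

## Response diversity

For each site, 100 communities (default) are drawn with
`y_j ~ Bernoulli(p_ij)`; each community's response diversity to a latent
axis is the IQR — linear-interpolation quantiles — of the (signed) loadings
of the species present, with communities of fewer than two species
contributing 0; the replicates are averaged. An exact enumeration oracle
over all `2^S` communities (S ≤ 20) verifies the sampler. The IQR is exactly
invariant to shifting loadings by a constant and scales linearly under
positive scaling.

Sites are split into high/low groups by spectral clustering (2 clusters,
RBF affinity) on standardized (log richness, log rd) — the same variables
as the subsequent regression, since no other feature space is implied by the
analysis. Clustering is restarted 100 times; each restart is scored by the
summed Gaussian log-likelihood of the residuals of per-cluster
`log(rd) ~ log(richness)` OLS fits, and the best restart is kept; "high" is
the cluster with larger mean log rd. Sites with zero richness or rd are
excluded from regressions and counted in a report.

The sign of the richness–response-diversity association is
regime-dependent: with i.i.d. loadings and moderate prevalence it is
positive (richer sites sample more of the loading distribution), but in
realisations where richness peaks at extreme latent values — where present
species share aligned loadings — it can be negative. The pipeline reports
the Spearman correlation rather than assuming a sign.

## Synthetic data

The generator emulates a coastal eDNA survey: sites near-evenly spaced by
arc length along a half-ellipse coastline (semi-axes 1 and 0.5) with small
jitter; two standardized covariate gradients (a latitudinal trend and an
along-shore trend, both with noise); latent Matérn fields drawn by dense
Cholesky; parameters drawn from the configured distributions. Defaults are
a mid-sized survey: 200 sites, 60 species, two latent axes with practical
ranges 0.3 and 0.6 (unit-coastline units) and unit sd, covariate effects
`N(0, 0.5²)`, intercepts `N(−1, 1)` (typical sub-50% prevalence), loadings
`N(0, 1)`, site-effect sd 0.25. The optional read-count layer draws Poisson
reads (configurable mean) in occupied cells, at least 1, zero elsewhere —
minimal but sufficient to exercise rarefaction.

What it does **not** emulate: sequence-level error, taxonomic
mis-assignment, spatially structured detectability, covariate measurement
error, or abundance-dependent detection. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Problem sizes and numerical choices

Recovery tests run at 200 sites × 60 species (fit ≈ 5 s); the
cross-validation study uses 10 replicates of 100 sites × 40 species over
latent dimensions 0–3 (≈ 90 s) — sizes chosen to make the Monte-Carlo
checks tight while keeping the suite quick. Matérn matrices get a `1e−10`
diagonal jitter before Cholesky; conditional variances in the Vecchia
construction are floored at `1e−12 σ²`; rarefaction keeps sites whose total
is below the target depth unchanged (with a warning) rather than dropping
them; a Jaccard distance between two empty sites is 0 by convention;
occupancy filtering is a single pass, not iterated.
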