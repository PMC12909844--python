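"""Bernoulli GLLVM with spatially autocorrelated latent variables.

The model for species j at site i is

    y_ij ~ Bernoulli(p_ij)
    logit(p_ij) = beta_j0 + x_i' beta_j + u_i' gamma_j + alpha_i

with environmental covariates ``x_i``, latent fields ``u_i`` given a Matérn
Gaussian-process prior (represented by a sparse GMRF precision), species
loadings ``gamma_j`` and site random effects ``alpha_i ~ N(0, sigma_alpha^2)``
absorbing site-level detectability differences (e.g. total eDNA
concentration).  Estimation maximises the penalized joint log-likelihood
(a MAP / Laplace-mode approximation) by L-BFGS over fixed effects, loadings,
latent fields and site effects, with outer updates of the spatial ranges
(1-D profile of the GMRF density of the current fields) and of
``sigma_alpha`` (Laplace EM).

Identifiability of the loading matrix Gamma (n_latent x n_species) follows
the standard GLLVM convention: entries above the diagonal are fixed at zero
and diagonal entries are positive (parametrised on the log scale), which
removes rotation and sign indeterminacy of the latent axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .community import DetectionMatrix, SiteTable
from .spatial import (
    SUPPORTED_SMOOTHNESS,
    gmrf_log_density,
    gmrf_precision,
    krige_field,
    pairwise_distances,
)

__all__ = [
    "SpatialGLLVM",
    "ModelSpec",
    "CVResult",
    "candidate_model_grid",
    "linear_predictor",
    "log_likelihood",
    "fit_gllvm",
    "variance_partition",
    "cross_validate_select",
]


def linear_predictor(intercepts, coefs, loadings, x, u, site_effects=None):
    """Linear predictor eta_ij and occurrence probability p_ij.

    ``eta = beta0 + x B + u Gamma + alpha``; ``p = expit(eta)`` (overflow-safe,
    no clamping).  Shapes: intercepts (m,), coefs (p, m), loadings (L, m),
    x (n, p), u (n, L), site_effects (n,).
    """
    beta0 = np.asarray(intercepts, dtype=float)
    B = np.atleast_2d(np.asarray(coefs, dtype=float))
    G = np.atleast_2d(np.asarray(loadings, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    m = beta0.shape[0]
    if B.size and (B.shape[1] != m or x.shape[1] != B.shape[0]):
        raise ValueError("covariate coefficient dimensions do not match")
    if G.size and (G.shape[1] != m or u.shape[1] != G.shape[0]):
        raise ValueError("loading dimensions do not match")
    eta = np.broadcast_to(beta0, (x.shape[0], m)).copy()
    if B.size:
        eta += x @ B
    if G.size:
        eta += u @ G
    if site_effects is not None:
        eta += np.asarray(site_effects, dtype=float)[:, None]
    return eta, expit(eta)


def log_likelihood(y, p):
    """Bernoulli log-likelihood sum_ij [y log p + (1-y) log(1-p)].

    Finite when all p are interior; a degenerate p in {0, 1} contradicting y
    yields -inf explicitly (never NaN).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y == 1, np.log(p), np.log1p(-p))
    if np.isnan(term).any():
        raise ValueError("p outside [0, 1]")
    if np.isneginf(term).any():
        return -np.inf
    return float(term.sum())


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a covariate set, a latent dimension, site effects."""

    name: str
    covariate_cols: tuple
    n_latent: int
    include_site_effects: bool = True

    def __post_init__(self):
        if not (0 <= self.n_latent <= 5):
            raise ValueError("n_latent must be in [0, 5]")


def candidate_model_grid(covariate_sets, n_latent_values=range(0, 6)):
    """Enumerate the candidate-model grid: covariate sets x latent dimensions.

    With the survey's three covariate sets (field-measured, satellite, both)
    and 0-5 latent variables this yields the 18 candidate models.
    """
    specs = []
    for set_name, cols in covariate_sets.items():
        for L in n_latent_values:
            specs.append(ModelSpec(name=f"{set_name}_L{L}", covariate_cols=tuple(cols),
                                   n_latent=int(L)))
    return specs


class SpatialGLLVM(BaseEstimator):
    """Bernoulli generalised linear latent variable model with spatial latent fields.

    Parameters
    ----------
    n_latent : int
        Number of latent variables (0-5).
    include_site_effects : bool
        Whether to include site random effects alpha_i.
    smoothness : float
        Matérn smoothness nu (0.5, 1 or 1.5).
    spatial_ranges : "estimate" or sequence of float
        Practical range per latent dimension; "estimate" profiles each range
        on a log grid between outer iterations.
    sigma_u : float
        Marginal sd of the latent-field prior.  Fixed at 1 by default; the
        field scale is absorbed by the loadings and downstream analyses use
        sd-scaled fields anyway.
    sigma_alpha : "estimate" or float
        Site-effect sd; "estimate" applies Laplace-EM updates.
    n_neighbors : int
        Neighbours in the Vecchia/GMRF construction of the spatial precision.
    ridge : float
        Tiny L2 penalty on intercepts, coefficients and loadings guarding
        against separation for sparse species.
    max_iter, n_outer, gtol, ftol : optimisation controls (inner L-BFGS
        iterations, outer hyperparameter updates, tolerances).

    Attributes
    ----------
    intercepts_ : (n_species,) species intercepts beta_j0.
    coefs_ : (n_cov, n_species) covariate coefficients.
    loadings_ : (n_latent, n_species) loading matrix, upper triangle zero,
        positive diagonal.
    latent_fields_ : (n_sites, n_latent) latent field posterior modes.
    site_effects_ : (n_sites,) site effect posterior modes.
    ranges_ : (n_latent,) fitted practical ranges.
    sigma_alpha_ : fitted site-effect sd.
    objective_trace_ : penalized negative log-likelihood per accepted L-BFGS
        iterate of the final inner solve (non-increasing).
    converged_ : bool; False (with a warning) when L-BFGS hit max_iter.
    """

    def __init__(self, n_latent=2, include_site_effects=True, smoothness=1.5,
                 spatial_ranges="estimate", sigma_u=1.0, sigma_alpha="estimate",
                 loading_prior_sd=1.0, n_neighbors=10, distance_convention="euclidean",
                 ridge=1e-6, max_iter=2000, n_outer=3, gtol=1e-6, ftol=1e-11,
                 random_state=0):
        self.n_latent = n_latent
        self.include_site_effects = include_site_effects
        self.smoothness = smoothness
        self.spatial_ranges = spatial_ranges
        self.sigma_u = sigma_u
        self.sigma_alpha = sigma_alpha
        self.loading_prior_sd = loading_prior_sd
        self.n_neighbors = n_neighbors
        self.distance_convention = distance_convention
        self.ridge = ridge
        self.max_iter = max_iter
        self.n_outer = n_outer
        self.gtol = gtol
        self.ftol = ftol
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _validate(self, Y, coords, X):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise ValueError("Y must be (n_sites, n_species)")
        if not np.isin(Y, (0.0, 1.0)).all():
            raise ValueError("Y must be binary presence/absence")
        coords = np.asarray(coords, dtype=float)
        if coords.shape[0] != Y.shape[0]:
            raise ValueError("coords and Y disagree on n_sites")
        if X is None:
            X = np.zeros((Y.shape[0], 0))
        X = np.asarray(X, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y disagree on n_sites")
        if not np.isfinite(X).all():
            raise ValueError("X contains missing values; filter sites first")
        if not (0 <= self.n_latent <= 5):
            raise ValueError("n_latent must be in [0, 5]")
        if self.smoothness not in SUPPORTED_SMOOTHNESS:
            raise ValueError(f"smoothness must be one of {SUPPORTED_SMOOTHNESS}")
        return Y, coords, X

    def _gamma_free_index(self, m):
        """(row, col, is_diag) for free entries of the L x m loading matrix."""
        rows, cols, is_diag = [], [], []
        for k in range(self.n_latent):
            for j in range(k, m):
                rows.append(k)
                cols.append(j)
                is_diag.append(j == k)
        return np.array(rows, dtype=int), np.array(cols, dtype=int), np.array(is_diag, dtype=bool)

    def _unpack(self, theta, n, m, p):
        L = self.n_latent
        n_g = self._n_gfree
        i = 0
        beta0 = theta[i:i + m]; i += m
        B = theta[i:i + p * m].reshape(p, m); i += p * m
        gfree = theta[i:i + n_g]; i += n_g
        U = theta[i:i + n * L].reshape(n, L); i += n * L
        alpha = theta[i:i + n] if self.include_site_effects else np.zeros(n)
        G = np.zeros((L, m))
        if n_g:
            vals = gfree.copy()
            vals[self._g_isdiag] = np.exp(vals[self._g_isdiag])
            G[self._g_rows, self._g_cols] = vals
        return beta0, B, gfree, G, U, alpha

    def _objective(self, theta, Y, X, Q_list, sa2):
        n, m = Y.shape
        p = X.shape[1]
        beta0, B, gfree, G, U, alpha = self._unpack(theta, n, m, p)
        eta = beta0[None, :] + (X @ B if p else 0.0) + (U @ G if self.n_latent else 0.0)
        if self.include_site_effects:
            eta = eta + alpha[:, None]
        # -loglik = sum log(1 + e^eta) - y eta, evaluated stably
        nll = float(np.logaddexp(0.0, eta).sum() - (Y * eta).sum())
        pen = 0.0
        Qu = np.zeros_like(U)
        for k, Q in enumerate(Q_list):
            Qu[:, k] = Q @ U[:, k]
            pen += 0.5 * float(U[:, k] @ Qu[:, k])
        if self.include_site_effects:
            pen += 0.5 * float(alpha @ alpha) / sa2
        # Gaussian prior on loadings: pins the U-vs-Gamma scale that the
        # field prior alone leaves unidentified under joint-mode estimation
        g_prec = 1.0 / self.loading_prior_sd**2 + self.ridge
        pen += 0.5 * g_prec * float((G * G).sum())
        pen += 0.5 * self.ridge * (float(beta0 @ beta0) + float((B * B).sum()))
        f = nll + pen

        P = expit(eta)
        R = P - Y
        g_beta0 = R.sum(axis=0) + self.ridge * beta0
        g_B = (X.T @ R + self.ridge * B).ravel() if p else np.zeros(0)
        if self.n_latent:
            dG = U.T @ R + g_prec * G
            g_vals = dG[self._g_rows, self._g_cols]
            diag_vals = G[self._g_rows[self._g_isdiag], self._g_cols[self._g_isdiag]]
            g_vals[self._g_isdiag] *= diag_vals  # chain rule for log-diagonal
            g_U = (R @ G.T + Qu).ravel()
        else:
            g_vals = np.zeros(0)
            g_U = np.zeros(0)
        parts = [g_beta0, g_B, g_vals, g_U]
        if self.include_site_effects:
            parts.append(R.sum(axis=1) + alpha / sa2)
        return f, np.concatenate(parts)

    def _initial_theta(self, Y, X):
        n, m = Y.shape
        p = X.shape[1]
        L = self.n_latent
        prev = np.clip(Y.mean(axis=0), 0.5 / n, 1.0 - 0.5 / n)
        beta0 = logit(prev)
        theta = [beta0, np.zeros(p * m)]
        if L:
            Z = Y - prev[None, :]
            Usvd, S, Vt = np.linalg.svd(Z, full_matrices=False)
            U0 = Usvd[:, :L] * np.sqrt(n)
            G0 = 4.0 * (S[:L, None] * Vt[:L]) / np.sqrt(n)
            for k in range(L):
                if G0[k, k] < 0:
                    G0[k, :] *= -1.0
                    U0[:, k] *= -1.0
            gfree = G0[self._g_rows, self._g_cols].copy()
            gfree[self._g_isdiag] = np.log(np.maximum(np.abs(gfree[self._g_isdiag]), 0.1))
            theta.extend([gfree, U0.ravel()])
        else:
            theta.append(np.zeros(0))
            theta.append(np.zeros(0))
        if self.include_site_effects:
            theta.append(np.zeros(n))
        return np.concatenate(theta)

    def _range_grid(self, coords):
        d = pairwise_distances(coords, self.distance_convention)
        diam = float(d.max())
        nn = np.where(d > 0, d, np.inf).min(axis=1)
        lo = max(2.0 * float(np.median(nn)), diam / 200.0)
        return np.geomspace(lo, diam, 10)

    def fit(self, Y, coords, X=None):
        """Fit by penalized maximum likelihood.

        Parameters: Y (n_sites, n_species) binary detections; coords
        (n_sites, 2) under the declared distance convention; X optional
        (n_sites, n_cov) covariates (no missing values).
        """
        Y, coords, X = self._validate(Y, coords, X)
        n, m = Y.shape
        p = X.shape[1]
        L = self.n_latent
        self._g_rows, self._g_cols, self._g_isdiag = self._gamma_free_index(m)
        self._n_gfree = len(self._g_rows)
        n_nb = min(self.n_neighbors, n - 1)

        if isinstance(self.spatial_ranges, str) and self.spatial_ranges == "estimate":
            grid = self._range_grid(coords) if L else np.array([])
            ranges = np.full(L, float(np.median(grid))) if L else np.zeros(0)
            estimate_ranges = L > 0
        else:
            ranges = np.asarray(self.spatial_ranges, dtype=float)
            if ranges.shape[0] != L:
                raise ValueError("spatial_ranges length must equal n_latent")
            estimate_ranges = False
        if isinstance(self.sigma_alpha, str) and self.sigma_alpha == "estimate":
            sa = 0.5
            estimate_sa = self.include_site_effects
        else:
            sa = float(self.sigma_alpha)
            if sa <= 0 and self.include_site_effects:
                raise ValueError("sigma_alpha must be positive")
            estimate_sa = False

        n_outer = self.n_outer if (estimate_ranges or estimate_sa) else 1
        theta = self._initial_theta(Y, X)
        trace = []
        res = None
        for outer in range(n_outer):
            Q_list = [gmrf_precision(coords, ranges[k], self.sigma_u, self.smoothness,
                                     n_nb, self.distance_convention) for k in range(L)]
            sa2 = sa**2 if self.include_site_effects else 1.0
            trace = []
            last_f = [np.inf]

            def fun(th):
                f, g = self._objective(th, Y, X, Q_list, sa2)
                last_f[0] = f
                return f, g

            def cb(xk):
                # L-BFGS-B's final line-search evaluation is the accepted point
                trace.append(last_f[0])

            res = optimize.minimize(
                fun, theta, method="L-BFGS-B", jac=True, callback=cb,
                options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": self.ftol})
            theta = res.x
            if outer == n_outer - 1:
                break
            beta0, B, gfree, G, U, alpha = self._unpack(theta, n, m, p)
            if estimate_ranges and L:
                for k in range(L):
                    lls = [gmrf_log_density(U[:, k], coords, r, self.sigma_u,
                                            self.smoothness, n_nb, self.distance_convention)
                           for r in grid]
                    ranges[k] = grid[int(np.argmax(lls))]
            if estimate_sa and self.include_site_effects:
                eta = beta0[None, :] + (X @ B if p else 0.0) + (U @ G if L else 0.0) + alpha[:, None]
                w = expit(eta) * (1.0 - expit(eta))
                h = w.sum(axis=1) + 1.0 / sa**2
                sa = float(np.sqrt(np.mean(alpha**2 + 1.0 / h)))
                sa = max(sa, 1e-3)

        beta0, B, gfree, G, U, alpha = self._unpack(theta, n, m, p)
        self.intercepts_ = beta0
        self.coefs_ = B
        self.loadings_ = G
        self.latent_fields_ = U
        self.site_effects_ = alpha if self.include_site_effects else np.zeros(n)
        self.ranges_ = ranges
        self.sigma_alpha_ = sa if self.include_site_effects else 0.0
        self.objective_ = float(res.fun)
        self.objective_trace_ = np.asarray(trace)
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.coords_ = coords
        self.X_ = X
        self.n_features_in_ = p
        self.n_sites_ = n
        self.n_species_ = m
        if not self.converged_:
            warnings.warn("L-BFGS did not report convergence "
                          f"(status {res.status}: {res.message})", stacklevel=2)
        return self

    # -------------------------------------------------------------- predict

    def _match_training_sites(self, coords_new):
        """Indices of training sites exactly matching each new site (-1 if none)."""
        match = np.full(coords_new.shape[0], -1, dtype=int)
        for i, c in enumerate(coords_new):
            d = np.abs(self.coords_ - c).sum(axis=1)
            j = int(np.argmin(d))
            if d[j] < 1e-12:
                match[i] = j
        return match

    def predict_latent(self, coords_new, return_var=False):
        """Kriged (GMRF/GP conditional mean) latent fields at new locations."""
        check_is_fitted(self, "latent_fields_")
        coords_new = np.atleast_2d(np.asarray(coords_new, dtype=float))
        L = self.n_latent
        out = np.zeros((coords_new.shape[0], L))
        var = np.zeros((coords_new.shape[0], L))
        for k in range(L):
            res = krige_field(self.latent_fields_[:, k], self.coords_, coords_new,
                              self.ranges_[k], self.sigma_u, self.smoothness,
                              self.distance_convention, return_var=return_var)
            if return_var:
                out[:, k], var[:, k] = res
            else:
                out[:, k] = res
        return (out, var) if return_var else out

    def predict_proba(self, coords_new, X_new=None, marginal=False):
        """Occurrence probabilities at new sites.

        Latent fields are kriged from the fitted fields; site effects are 0
        (the prior mean) for unseen sites and the fitted value for sites whose
        coordinates exactly match a training site.

        With ``marginal=True`` the probability is integrated over the
        predictive uncertainty of the latent fields and (for unmatched sites)
        the site effect, using the logistic-normal probit approximation
        ``E[expit(eta)] ~ expit(eta / sqrt(1 + pi s^2 / 8))``.  This moderates
        overconfident plug-in probabilities and is what the cross-validation
        loss uses; at a training site the predictive variance is zero, so both
        modes reproduce the training probabilities exactly.
        """
        check_is_fitted(self, "intercepts_")
        coords_new = np.atleast_2d(np.asarray(coords_new, dtype=float))
        if X_new is None:
            if self.n_features_in_ > 0:
                raise ValueError("model was fitted with covariates; X_new required")
            X_new = np.zeros((coords_new.shape[0], 0))
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape != (coords_new.shape[0], self.n_features_in_):
            raise ValueError("X_new has wrong shape")
        if not np.isfinite(X_new).all():
            raise ValueError("X_new contains missing values")
        n_new = coords_new.shape[0]
        if self.n_latent:
            U_new, V_new = self.predict_latent(coords_new, return_var=True)
        else:
            U_new, V_new = np.zeros((n_new, 0)), np.zeros((n_new, 0))
        match = self._match_training_sites(coords_new)
        alpha_new = np.where(match >= 0, self.site_effects_[np.maximum(match, 0)], 0.0)
        eta, P = linear_predictor(self.intercepts_, self.coefs_, self.loadings_,
                                  X_new, U_new, alpha_new)
        if not marginal:
            return P
        s2 = V_new @ self.loadings_**2 if self.n_latent else np.zeros((n_new, self.n_species_))
        if self.include_site_effects:
            s2 = s2 + np.where(match >= 0, 0.0, self.sigma_alpha_**2)[:, None]
        return expit(eta / np.sqrt(1.0 + np.pi * s2 / 8.0))

    def score(self, Y, coords, X=None):
        """Mean per-cell Bernoulli log-likelihood at the given sites."""
        Y = np.asarray(Y, dtype=float)
        P = self.predict_proba(coords, X)
        return log_likelihood(Y, P) / Y.size

    # ------------------------------------------------------------- analysis

    def scaled_latent_fields(self):
        """Latent fields divided by their across-site sd (the reported scale).

        The matching loadings are multiplied by the same sd so the linear
        predictor is unchanged; returns (fields_scaled, loadings_scaled, sds).
        """
        check_is_fitted(self, "latent_fields_")
        if self.n_latent == 0:
            raise ValueError("model has no latent variables")
        sds = self.latent_fields_.std(axis=0)
        if np.any(sds == 0):
            raise ValueError("degenerate latent field with zero variance")
        return self.latent_fields_ / sds, self.loadings_ * sds[:, None], sds


def fit_gllvm(data: DetectionMatrix, sites: SiteTable, spec: ModelSpec, **options) -> SpatialGLLVM:
    """Fit a :class:`SpatialGLLVM` from a detection matrix and site table."""
    Y = data.to_presence().data.to_numpy().T.astype(float)
    if list(data.site_ids) != list(sites.site_ids):
        raise ValueError("detection matrix and site table site ids do not align")
    X = sites.covariate_matrix(spec.covariate_cols) if spec.covariate_cols else None
    model = SpatialGLLVM(n_latent=spec.n_latent,
                         include_site_effects=spec.include_site_effects,
                         distance_convention=sites.distance_convention, **options)
    return model.fit(Y, sites.coords(), X)


def variance_partition(fit: SpatialGLLVM, covariate_names=None, species_weights="pooled"):
    """Across-site variance fractions of the linear-predictor components.

    For each species j the across-site variance of each component is computed
    (``x_ic * beta_cj`` per covariate c, ``u_ik * gamma_kj`` per latent
    dimension k).  With ``species_weights="pooled"`` (default) component
    variances are summed over species and normalized once — species
    contribute in proportion to their signal, and the covariate share
    converges to zero under null covariate effects.  With
    ``species_weights="equal"`` each species' fractions are normalized to one
    first and then averaged, giving every species the same weight (weak-signal
    species then contribute noisy ratios).  Intercepts and site effects are
    excluded from the decomposition.
    """
    check_is_fitted(fit, "intercepts_")
    p = fit.n_features_in_
    L = fit.n_latent
    if p + L == 0:
        raise ValueError("model has no covariates or latent variables to partition")
    names = (list(covariate_names) if covariate_names is not None
             else [f"covariate_{c}" for c in range(p)])
    names = names + [f"latent_{k + 1}" for k in range(L)]
    m = fit.n_species_
    comp_var = np.zeros((p + L, m))
    for c in range(p):
        comp_var[c] = np.var(fit.X_[:, c][:, None] * fit.coefs_[c][None, :], axis=0)
    for k in range(L):
        comp_var[p + k] = np.var(fit.latent_fields_[:, k][:, None]
                                 * fit.loadings_[k][None, :], axis=0)
    totals = comp_var.sum(axis=0)
    ok = totals > 0
    if not ok.any():
        raise ValueError("all-zero linear predictor; variance partition undefined")
    if species_weights == "pooled":
        fracs = comp_var.sum(axis=1) / comp_var.sum()
    elif species_weights == "equal":
        if not ok.all():
            warnings.warn(f"{int((~ok).sum())} species with all-zero predictor excluded "
                          "from variance partition", stacklevel=2)
        fracs = (comp_var[:, ok] / totals[ok]).mean(axis=1)
    else:
        raise ValueError("species_weights must be 'pooled' or 'equal'")
    return pd.Series(fracs, index=names, name="variance_fraction")


@dataclass
class CVResult:
    """Cross-validation outcome over a set of candidate models."""

    table: pd.DataFrame                 # index spec name; fold columns + mean
    fold_assignment: pd.Series          # site id -> fold index
    specs: list = field(repr=False, default_factory=list)
    selected: ModelSpec = None

    @property
    def selected_name(self):
        return self.selected.name if self.selected is not None else None


def cross_validate_select(data: DetectionMatrix, sites: SiteTable, specs, k=5,
                          seed=0, **options) -> CVResult:
    """k-fold cross-validation over candidate models, selecting by held-out NLL.

    Sites are partitioned into k folds by a seeded random permutation (the
    same folds for every candidate).  Each candidate is fitted on k-1 folds
    and scored by the mean per-cell negative log-likelihood of the held-out
    sites, with latent fields kriged and site effects at their prior mean.
    The candidate minimising the mean validation loss is selected.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be nonempty")
    if list(data.site_ids) != list(sites.site_ids):
        raise ValueError("detection matrix and site table site ids do not align")
    n = data.n_sites
    if n < k:
        raise ValueError("need at least k sites")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(perm, k)):
        fold_of[idx] = f
    fold_assignment = pd.Series(fold_of, index=data.site_ids, name="fold")

    Y_all = data.to_presence().data.to_numpy().T.astype(float)
    coords = sites.coords()
    losses = np.zeros((len(specs), k))
    for s_i, spec in enumerate(specs):
        X_all = (sites.covariate_matrix(spec.covariate_cols)
                 if spec.covariate_cols else np.zeros((n, 0)))
        for f in range(k):
            tr = fold_of != f
            va = ~tr
            model = SpatialGLLVM(n_latent=spec.n_latent,
                                 include_site_effects=spec.include_site_effects,
                                 distance_convention=sites.distance_convention,
                                 **options)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Y_all[tr], coords[tr], X_all[tr] if X_all.shape[1] else None)
            P = model.predict_proba(coords[va], X_all[va] if X_all.shape[1] else None,
                                    marginal=True)
            P = np.clip(P, 1e-12, 1.0 - 1e-12)
            Yv = Y_all[va]
            losses[s_i, f] = float(-(Yv * np.log(P) + (1 - Yv) * np.log1p(-P)).mean())
    table = pd.DataFrame(losses, index=[s.name for s in specs],
                         columns=[f"fold{f}" for f in range(k)])
    table["mean_nll"] = table.mean(axis=1)
    best = int(np.argmin(table["mean_nll"].to_numpy()))
    return CVResult(table=table, fold_assignment=fold_assignment,
                    specs=specs, selected=specs[best])
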