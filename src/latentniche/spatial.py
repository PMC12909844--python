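"""Spatial covariance machinery: Matérn kernels, GMRF precisions, kriging.

The latent niche axes are modelled as zero-mean Gaussian processes over the
sampling sites with a Matérn covariance

    C(d) = sigma^2 * 2^(1-nu) / Gamma(nu) * (kappa d)^nu * K_nu(kappa d),

where ``kappa = sqrt(8 nu) / rho`` so that ``rho`` is the distance at which
the correlation has dropped to roughly 0.14 (the usual "practical range"
convention).  For fitting, the dense covariance is replaced by a sparse
Gaussian-Markov-random-field precision built by nearest-neighbour
conditioning (a Vecchia approximation): with full conditioning the precision
is exactly the inverse of the dense covariance, which is what the tests pin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn
from scipy.special import kv

_EARTH_RADIUS_KM = 6371.0088

#: smoothness values with closed-form or stable Bessel evaluation
SUPPORTED_SMOOTHNESS = (0.5, 1.0, 1.5)


@dataclass(frozen=True)
class SpatialPrior:
    """Hyperparameters of the Matérn / GMRF prior on one set of latent fields.

    Parameters
    ----------
    ranges : tuple of float
        Practical range per latent dimension, in the site table's distance
        units (km for haversine data, arbitrary units for synthetic data).
    sds : tuple of float
        Marginal standard deviation per latent dimension.
    smoothness : float
        Matérn smoothness nu; one of 0.5, 1.0, 1.5.
    construction : str
        ``"dense"`` or ``"sparse-gmrf"``; how precision matrices are built.
    """

    ranges: tuple
    sds: tuple
    smoothness: float = 1.5
    construction: str = "sparse-gmrf"

    def __post_init__(self):
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")
        if any(r <= 0 for r in self.ranges):
            raise ValueError("ranges must be positive")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")
        if len(self.ranges) != len(self.sds):
            raise ValueError("ranges and sds must have equal length")


def pairwise_distances(coords, convention: str = "euclidean"):
    """Pairwise site distances.

    ``convention`` is ``"euclidean"`` (synthetic planar coordinates) or
    ``"haversine-km"`` (columns are longitude, latitude in decimal degrees;
    output in kilometres).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be 2-D (n_sites, 2)")
    if convention == "euclidean":
        return cdist(coords, coords)
    if convention == "haversine-km":
        lon = np.radians(coords[:, 0])
        lat = np.radians(coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
        return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    raise ValueError(f"unknown distance convention: {convention!r}")


def matern_correlation(d, range_, smoothness=1.5):
    """Matérn correlation at distances ``d`` under the practical-range convention."""
    if range_ <= 0:
        raise ValueError("range must be positive")
    if smoothness not in SUPPORTED_SMOOTHNESS:
        raise ValueError(f"smoothness must be one of {SUPPORTED_SMOOTHNESS}, got {smoothness}")
    d = np.asarray(d, dtype=float)
    kappa = np.sqrt(8.0 * smoothness) / range_
    kd = kappa * d
    if smoothness == 0.5:
        return np.exp(-kd)
    if smoothness == 1.5:
        return (1.0 + kd) * np.exp(-kd)
    # nu = 1: use the Bessel form, patching the d -> 0 limit (correlation 1)
    out = np.ones_like(kd)
    pos = kd > 0
    out[pos] = kd[pos] * kv(1.0, kd[pos]) * 2.0 ** (1.0 - smoothness) / gamma_fn(smoothness)
    return out


def matern_covariance(coords, range_, sd, smoothness=1.5, convention="euclidean"):
    """Dense Matérn covariance matrix over a site set.

    ``C(0) = sd**2``; symmetric positive semidefinite by construction.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    d = pairwise_distances(coords, convention)
    return sd**2 * matern_correlation(d, range_, smoothness)


def matern_cross_covariance(coords_a, coords_b, range_, sd, smoothness=1.5, convention="euclidean"):
    """Cross-covariance between two coordinate sets (used for kriging)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if convention == "euclidean":
        d = cdist(a, b)
    elif convention == "haversine-km":
        n_a = a.shape[0]
        both = np.vstack([a, b])
        d = pairwise_distances(both, convention)[:n_a, n_a:]
    else:
        raise ValueError(f"unknown distance convention: {convention!r}")
    return sd**2 * matern_correlation(d, range_, smoothness)


def gmrf_precision(coords, range_, sd, smoothness=1.5, n_neighbors=10, convention="euclidean"):
    """Sparse GMRF precision approximating the Matérn covariance on a site set.

    Nearest-neighbour (Vecchia) construction: sites are ordered along the
    first coordinate, and each site is conditioned on at most ``n_neighbors``
    nearest *previous* sites.  The factorisation is

        Q = (I - A)' D^{-1} (I - A)

    with A the conditional-regression weights and D the conditional
    variances.  With ``n_neighbors = n - 1`` (full conditioning) Q is exactly
    the inverse of the dense Matérn covariance.

    Returns a ``scipy.sparse.csc_matrix`` in the *original* site order.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if n == 0:
        raise ValueError("coords must be nonempty")
    if sd <= 0 or range_ <= 0:
        raise ValueError("range and sd must be positive")
    if n == 1:
        return sparse.csc_matrix(np.array([[1.0 / sd**2]]))
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be < n_sites")

    order = np.argsort(coords[:, 0], kind="stable")
    c_ord = coords[order]
    dmat = pairwise_distances(c_ord, convention)
    corr = matern_correlation(dmat, range_, smoothness)

    rows_A, cols_A, vals_A = [], [], []
    d_cond = np.empty(n)
    d_cond[0] = sd**2
    for i in range(1, n):
        m = min(n_neighbors, i)
        prev = np.arange(i)
        if i > m:
            nearest = np.argpartition(dmat[i, :i], m - 1)[:m]
            prev = np.sort(prev[nearest])
        c_nn = sd**2 * corr[np.ix_(prev, prev)]
        c_in = sd**2 * corr[i, prev]
        b = np.linalg.solve(c_nn + 1e-12 * sd**2 * np.eye(m), c_in)
        d_cond[i] = max(sd**2 - b @ c_in, 1e-12 * sd**2)
        rows_A.extend([i] * m)
        cols_A.extend(prev.tolist())
        vals_A.extend(b.tolist())

    A = sparse.csc_matrix((vals_A, (rows_A, cols_A)), shape=(n, n))
    ImA = sparse.eye(n, format="csc") - A
    Dinv = sparse.diags(1.0 / d_cond)
    Q_ord = (ImA.T @ Dinv @ ImA).tocsc()

    # permute back to original site order
    P = sparse.csc_matrix((np.ones(n), (order, np.arange(n))), shape=(n, n))
    return (P @ Q_ord @ P.T).tocsc()


def gmrf_log_density(u, coords, range_, sd, smoothness=1.5, n_neighbors=10, convention="euclidean"):
    """Log density of a field ``u`` under the GMRF prior (used to profile the range).

    The Vecchia factorisation makes the log-determinant a sum of conditional
    variances, so no sparse Cholesky is needed.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    u = np.asarray(u, dtype=float)
    Q = gmrf_precision(coords, range_, sd, smoothness, n_neighbors, convention)
    quad = float(u @ (Q @ u))
    # log|Q|: recompute conditional variances (cheap relative to fitting)
    order = np.argsort(coords[:, 0], kind="stable")
    c_ord = coords[order]
    dmat = pairwise_distances(c_ord, convention)
    corr = matern_correlation(dmat, range_, smoothness)
    logdet = -np.log(sd**2)
    for i in range(1, n):
        m = min(n_neighbors, i)
        prev = np.arange(i)
        if i > m:
            nearest = np.argpartition(dmat[i, :i], m - 1)[:m]
            prev = np.sort(prev[nearest])
        c_nn = sd**2 * corr[np.ix_(prev, prev)]
        c_in = sd**2 * corr[i, prev]
        b = np.linalg.solve(c_nn + 1e-12 * sd**2 * np.eye(m), c_in)
        logdet -= np.log(max(sd**2 - b @ c_in, 1e-12 * sd**2))
    return 0.5 * (logdet - quad - n * np.log(2.0 * np.pi))


def krige_field(u, coords_train, coords_new, range_, sd, smoothness=1.5, convention="euclidean",
                jitter=1e-10, return_var=False):
    """Conditional (kriging) mean of a Gaussian field at new locations.

    ``E[u* | u] = C(new, train) C(train, train)^{-1} u``.  At a training
    location this reproduces the training value exactly; far from all
    training sites it shrinks to the prior mean 0.  With ``return_var`` the
    conditional variance ``C(0) - c' C^{-1} c`` per new location is also
    returned.
    """
    c_tt = matern_covariance(coords_train, range_, sd, smoothness, convention)
    c_tt[np.diag_indices_from(c_tt)] += jitter * sd**2
    c_nt = matern_cross_covariance(coords_new, coords_train, range_, sd, smoothness, convention)
    sol = np.linalg.solve(c_tt, np.vstack([np.asarray(u, dtype=float), c_nt]).T)
    mean = c_nt @ sol[:, 0]
    if not return_var:
        return mean
    var = np.maximum(sd**2 - np.sum(c_nt * sol[:, 1:].T, axis=1), 0.0)
    return mean, var
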