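"""Expected response diversity of local communities to each latent niche axis.

A community's response diversity to a latent variable is the spread — the
interquartile range, robust to outlying loading estimates — of the loadings
gamma_j of the species present.  Because species presence is probabilistic,
the statistic is an expectation over communities sampled from the estimated
occurrence probabilities: communities are drawn with ``y_ij ~ Bernoulli(p_ij)``
and the IQRs averaged (100 draws by default).  An exact enumeration oracle
over all 2^S communities is provided for small species pools.

Sites are then split into high and low response-diversity groups by spectral
clustering on (log richness, log response diversity), the clustering restart
with the highest Gaussian regression log-likelihood is kept, and a log-log
regression of response diversity on richness is fitted per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import SpectralClustering
from sklearn.metrics.pairwise import rbf_kernel


def expected_richness(p):
    """Expected species richness of one site: sum_j p_ij."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p.sum())


def _iqr(values):
    """Interquartile range with linear-interpolation quantiles; <2 values -> 0."""
    if values.size < 2:
        return 0.0
    q1, q3 = np.percentile(values, [25.0, 75.0])
    return float(q3 - q1)


def _iqr_rows(present, gamma):
    """Per-row IQR of ``gamma`` over the present species (vectorised).

    ``present`` is a boolean (n_rep, S) matrix; rows with fewer than two
    present species get IQR 0, matching the per-community convention.
    """
    vals = np.where(present, gamma[None, :], np.nan)
    n_present = present.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-nan rows
        q1, q3 = np.nanpercentile(vals, [25.0, 75.0], axis=1)
    iqr = q3 - q1
    iqr[n_present < 2] = 0.0
    return iqr


def expected_response_diversity(p, gamma, n_rep=100, seed=0):
    """Monte-Carlo expected IQR of loadings over communities drawn from ``p``.

    For each replicate, species presence is drawn independently as
    Bernoulli(p_j); the IQR of the (signed) loadings of the present species
    is computed (communities with fewer than two species contribute 0) and
    the replicates are averaged.  Deterministic per seed.
    """
    p = np.asarray(p, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if p.shape != gamma.shape:
        raise ValueError("p and gamma must have the same length")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random((n_rep, p.size)) < p[None, :]
    return float(_iqr_rows(draws, gamma).mean())


def exact_response_diversity(p, gamma):
    """Exact expected IQR by enumeration over all 2^S communities (S <= 20)."""
    p = np.asarray(p, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if p.shape != gamma.shape:
        raise ValueError("p and gamma must have the same length")
    S = p.size
    if S > 20:
        raise ValueError("enumeration limited to <= 20 species")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    # enumerate all 2^S communities as a boolean matrix
    masks = np.array(list(product((False, True), repeat=S)), dtype=bool)
    probs = np.prod(np.where(masks, p[None, :], 1.0 - p[None, :]), axis=1)
    return float(probs @ _iqr_rows(masks, gamma))


def site_response_diversity(P, loadings, n_rep=100, seed=0) -> pd.DataFrame:
    """Expected richness and per-LV expected response diversity for every site.

    ``P`` is (n_sites, n_species) occurrence probabilities; ``loadings`` is
    (n_latent, n_species).  One independent seeded stream per site/LV pair.
    """
    P = np.asarray(P, dtype=float)
    G = np.atleast_2d(np.asarray(loadings, dtype=float))
    if P.shape[1] != G.shape[1]:
        raise ValueError("P and loadings disagree on n_species")
    n, L = P.shape[0], G.shape[0]
    rng = np.random.default_rng(seed)
    out = {"expected_richness": [expected_richness(P[i]) for i in range(n)]}
    # shared community draws across LVs at each site (one community, L responses)
    for k in range(L):
        out[f"rd_LV{k + 1}"] = np.zeros(n)
    for i in range(n):
        site_rng = np.random.default_rng(rng.integers(2**31))
        draws = site_rng.random((n_rep, P.shape[1])) < P[i][None, :]
        for k in range(L):
            out[f"rd_LV{k + 1}"][i] = float(_iqr_rows(draws, G[k]).mean())
    return pd.DataFrame(out)


@dataclass
class ClusterResult:
    labels: np.ndarray               # "high" / "low" per site
    best_restart: int
    best_loglik: float
    n_restarts: int


def _regression_loglik(logx, logy, labels):
    """Summed Gaussian log-likelihood of per-cluster log-log OLS residuals."""
    total = 0.0
    for lab in np.unique(labels):
        m = labels == lab
        if m.sum() < 3:
            return -np.inf
        X = sm.add_constant(logx[m])
        res = sm.OLS(logy[m], X).fit()
        sigma2 = float(np.mean(res.resid**2))
        if sigma2 <= 0:
            sigma2 = 1e-12
        nn = int(m.sum())
        total += -0.5 * nn * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return total


def cluster_sites(richness, rd, n_restarts=100, seed=0, gamma_rbf=1.0) -> ClusterResult:
    """Split sites into high/low response-diversity groups by spectral clustering.

    Clustering (2 clusters, RBF affinity) acts on the standardized
    (log richness, log rd) points — the same variables as the subsequent
    regression.  It is restarted ``n_restarts`` times; each restart is scored
    by the summed Gaussian log-likelihood of the residuals of per-cluster
    log-log regressions and the best restart is kept.  "high" is the cluster
    with the larger mean log rd.
    """
    richness = np.asarray(richness, dtype=float)
    rd = np.asarray(rd, dtype=float)
    ok = (richness > 0) & (rd > 0)
    if ok.sum() < 4:
        raise ValueError("need at least 4 sites with positive richness and rd")
    logx = np.log(richness[ok])
    logy = np.log(rd[ok])
    pts = np.column_stack([logx, logy])
    if np.unique(pts, axis=0).shape[0] < 2:
        raise ValueError("fewer than 2 distinct points")
    std = pts.std(axis=0)
    std[std == 0] = 1.0
    pts_std = (pts - pts.mean(axis=0)) / std
    affinity = rbf_kernel(pts_std, gamma=gamma_rbf)

    best = (-np.inf, None, -1)
    for r in range(n_restarts):
        sc = SpectralClustering(n_clusters=2, affinity="precomputed",
                                random_state=seed + r, n_init=1, assign_labels="kmeans")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lab = sc.fit_predict(affinity)
        if len(np.unique(lab)) < 2:
            continue
        ll = _regression_loglik(logx, logy, lab)
        if ll > best[0]:
            best = (ll, lab, r)
    if best[1] is None:
        raise ValueError("spectral clustering failed to produce two clusters")
    ll, lab, r = best
    mean_logy = [logy[lab == g].mean() for g in (0, 1)]
    high = int(np.argmax(mean_logy))
    names = np.where(lab == high, "high", "low")
    labels = np.full(richness.shape[0], "excluded", dtype=object)
    labels[ok] = names
    return ClusterResult(labels=labels, best_restart=r, best_loglik=float(ll),
                         n_restarts=n_restarts)


@dataclass
class LogLogFit:
    slope: float
    intercept: float
    resid_sd: float
    slope_se: float
    n: int


def fit_loglog_regression(richness, rd, labels):
    """Per-cluster OLS of log(rd) on log(richness).

    Sites with rd == 0 or richness == 0 are excluded and counted in the
    report.  Raises when a cluster has fewer than 3 usable sites.
    Returns ({label: LogLogFit}, report).
    """
    richness = np.asarray(richness, dtype=float)
    rd = np.asarray(rd, dtype=float)
    labels = np.asarray(labels)
    usable = (richness > 0) & (rd > 0)
    report = {"n_excluded_zero": int(((~usable) & (labels != "excluded")).sum())}
    fits = {}
    cluster_names = [l for l in pd.unique(labels) if l != "excluded"]
    for lab in cluster_names:
        m = (labels == lab) & usable
        if m.sum() < 3:
            raise ValueError(f"cluster {lab!r} has fewer than 3 usable sites")
        X = sm.add_constant(np.log(richness[m]))
        res = sm.OLS(np.log(rd[m]), X).fit()
        fits[lab] = LogLogFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                              resid_sd=float(np.sqrt(np.mean(res.resid**2))),
                              slope_se=float(res.bse[1]), n=int(m.sum()))
    return fits, report
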