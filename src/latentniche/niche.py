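"""Niche space on the latent axes: species niche centres, zero-value boundaries.

Sites are placed in a "niche space" whose axes are the sd-scaled latent
variables.  A species' niche centre is the mode of a Gaussian kernel density
over the positions of the sites where it was detected — the position of
highest occurrence probability in niche space.  Interpolating each latent
field over geography and extracting its zero-level contour yields
hypothetical biogeographic boundaries: community composition turns over
where a latent field changes sign.  A field whose values hug zero over a
large share of the map ("broad zero-value areas") is reported as having no
boundary rather than a meaningless contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from sklearn.utils.validation import check_is_fitted

from .gllvm import SpatialGLLVM
from .spatial import krige_field


@dataclass
class NicheSpace:
    """Site positions on the scaled latent axes plus the density-evaluation grid."""

    positions: pd.DataFrame          # sites x latent axes (scaled)
    grid_x: np.ndarray
    grid_y: np.ndarray

    @property
    def axes(self):
        return list(self.positions.columns)


@dataclass
class BoundarySet:
    """Zero-level polylines per latent variable in geographic coordinates."""

    polylines: list                  # list of (n_vertices, 2) arrays
    latent_index: int
    grid_shape: tuple
    no_boundary: bool = False        # broad zero-value area detected
    note: str = ""


def site_niche_positions(fit: SpatialGLLVM, site_ids=None) -> pd.DataFrame:
    """Per-site positions on the sd-scaled latent axes (site order preserved)."""
    check_is_fitted(fit, "latent_fields_")
    if fit.n_latent == 0:
        raise ValueError("model has no latent variables")
    scaled, _, _ = fit.scaled_latent_fields()
    idx = list(site_ids) if site_ids is not None else list(range(scaled.shape[0]))
    cols = [f"LV{k + 1}" for k in range(fit.n_latent)]
    return pd.DataFrame(scaled, index=idx, columns=cols)


def build_niche_grid(positions, n_grid=200, margin=0.1):
    """Rectilinear evaluation grid covering the positions with a margin."""
    pos = np.asarray(positions, dtype=float)
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    gx = np.linspace(lo[0] - margin * span[0], hi[0] + margin * span[0], n_grid)
    gy = np.linspace(lo[1] - margin * span[1], hi[1] + margin * span[1], n_grid)
    return gx, gy


def _silverman_bandwidths(pos):
    """Per-axis Silverman rule-of-thumb bandwidths."""
    n = pos.shape[0]
    sd = pos.std(axis=0, ddof=1) if n > 1 else np.zeros(pos.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    return sd * (4.0 / ((pos.shape[1] + 2.0) * n)) ** (1.0 / (pos.shape[1] + 4.0))


def species_niche_centre(positions, occupied_mask, bandwidth=None, grid=None, n_grid=200):
    """Niche centre: mode of the Gaussian KDE of occupied sites' positions.

    ``positions`` is (n_sites, 2) on the first two latent axes;
    ``occupied_mask`` flags sites where the species was detected.  The
    density is evaluated on the niche grid and the centre is the argmax grid
    point (ties broken by lowest flat grid index).  Bandwidth defaults to
    Silverman's rule per axis.
    """
    pos = np.asarray(positions, dtype=float)[:, :2]
    mask = np.asarray(occupied_mask, dtype=bool)
    if mask.shape[0] != pos.shape[0]:
        raise ValueError("mask length must equal number of sites")
    occ = pos[mask]
    if occ.shape[0] == 0:
        raise ValueError("species occupies no sites")
    if grid is None:
        gx, gy = build_niche_grid(pos, n_grid=n_grid)
    else:
        gx, gy = grid
    if bandwidth is None:
        bw = _silverman_bandwidths(occ)
    else:
        bw = np.broadcast_to(np.asarray(bandwidth, dtype=float), (2,)).copy()
    bw = np.maximum(bw, 1e-9)
    # separable Gaussian kernels: density(gx, gy) up to a constant factor
    kx = np.exp(-0.5 * ((gx[:, None] - occ[None, :, 0]) / bw[0]) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - occ[None, :, 1]) / bw[1]) ** 2)
    dens = kx @ ky.T  # (n_gx, n_gy): sum over occupied sites of product kernels
    flat = int(np.argmax(dens))   # argmax returns the lowest flat index on ties
    ix, iy = np.unravel_index(flat, dens.shape)
    return np.array([gx[ix], gy[iy]])


def all_niche_centres(positions, detections, bandwidth=None, n_grid=200) -> pd.DataFrame:
    """Niche centres for every species of a (species x site) presence table."""
    pres = detections.to_presence().data
    pos = np.asarray(positions, dtype=float)[:, :2]
    grid = build_niche_grid(pos, n_grid=n_grid)
    rows = {}
    for sp in pres.index:
        mask = pres.loc[sp].to_numpy() > 0
        if not mask.any():
            continue
        rows[sp] = species_niche_centre(pos, mask, bandwidth=bandwidth, grid=grid)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["LV1", "LV2"])


def classify_niche_regions(centres, convention=None):
    """Assign each species to a sign quadrant of the (LV1, LV2) zero lines.

    Latent signs are arbitrary up to reflection, so the quadrant -> region
    name mapping is a declared convention (default: plain quadrant labels
    Q++, Q+-, Q-+, Q--).  A centre exactly on a zero line counts as positive
    (>= 0).  Returns (labels, proportions); proportions sum to 1.
    """
    centres = pd.DataFrame(centres)
    conv = convention or {"++": "Q++", "+-": "Q+-", "-+": "Q-+", "--": "Q--"}
    sgn = lambda v: "+" if v >= 0 else "-"
    labels = pd.Series(
        [conv[sgn(r[0]) + sgn(r[1])] for r in centres.to_numpy()[:, :2]],
        index=centres.index, name="region")
    proportions = labels.value_counts(normalize=True)
    return labels, proportions


def interpolate_latent_surface(fit: SpatialGLLVM, grid_x, grid_y, scaled=True):
    """Conditional mean of each latent field on a geographic grid.

    Same GP/GMRF conditional (kriging) as occurrence prediction; values at a
    site location equal the fitted field there, far-field values shrink to 0.
    Returns an array (n_latent, len(grid_x), len(grid_y)).
    """
    check_is_fitted(fit, "latent_fields_")
    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    if gx.size == 0 or gy.size == 0:
        raise ValueError("grid must be nonempty")
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    fields = fit.latent_fields_
    if scaled and fit.n_latent:
        fields, _, _ = fit.scaled_latent_fields()
    out = np.empty((fit.n_latent, gx.size, gy.size))
    for k in range(fit.n_latent):
        # chunked to keep the cross-covariance memory bounded
        vals = np.empty(pts.shape[0])
        step = 20000
        for s in range(0, pts.shape[0], step):
            vals[s:s + step] = krige_field(fields[:, k], fit.coords_, pts[s:s + step],
                                           fit.ranges_[k], fit.sigma_u, fit.smoothness,
                                           fit.distance_convention)
        out[k] = vals.reshape(gx.size, gy.size)
    return out


def extract_zero_boundaries(surface, grid_x, grid_y, latent_index=0, min_vertices=3,
                            broad_zero_frac=0.2, broad_zero_tol=0.1) -> BoundarySet:
    """Zero-level contours of a latent surface as boundary polylines.

    Marching-squares contours at level 0; chains shorter than
    ``min_vertices`` are discarded.  If at least ``broad_zero_frac`` of grid
    cells satisfy ``|value| < broad_zero_tol * sd(surface)`` the surface is
    flagged as a broad zero-value area and reported with no boundary —
    near-zero fields everywhere indicate no community turnover line.
    A constant surface yields an empty set with a note.
    """
    z = np.asarray(surface, dtype=float)
    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    if z.shape != (gx.size, gy.size):
        raise ValueError("surface shape must match the grid")
    if np.ptp(z) == 0:
        return BoundarySet([], latent_index, z.shape, no_boundary=True,
                           note="constant surface")
    sd = z.std()
    near_zero = np.mean(np.abs(z) < broad_zero_tol * sd)
    if near_zero >= broad_zero_frac:
        return BoundarySet([], latent_index, z.shape, no_boundary=True,
                           note=f"broad zero-value area ({near_zero:.0%} of grid)")
    polylines = []
    for contour in measure.find_contours(z, 0.0):
        if contour.shape[0] < min_vertices:
            continue
        # index space -> grid coordinates
        xs = np.interp(contour[:, 0], np.arange(gx.size), gx)
        ys = np.interp(contour[:, 1], np.arange(gy.size), gy)
        polylines.append(np.column_stack([xs, ys]))
    return BoundarySet(polylines, latent_index, z.shape)


def boundaries_to_geojson(bsets, path):
    """Write boundary polylines as GeoJSON LineString features."""
    import json

    features = []
    for bs in bsets:
        for line in bs.polylines:
            features.append({
                "type": "Feature",
                "properties": {"latent": bs.latent_index + 1},
                "geometry": {"type": "LineString",
                             "coordinates": [[float(x), float(y)] for x, y in line]},
            })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
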