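"""Species-by-site detection tables: I/O, rarefaction, filtering, distances.

Detection matrices hold either raw read counts or binary presence/absence,
with species as rows and sites as columns (the layout of eDNA metabarcoding
supplementary tables).  Preprocessing follows the usual metabarcoding
pipeline: rarefy per-site read totals to a common depth, drop taxa flagged
as species complexes, drop taxa occupying too few sites, and drop sites with
missing covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


class FormatError(ValueError):
    """Malformed detection or site table."""


class ConsistencyError(ValueError):
    """Detection matrix and site table disagree."""


@dataclass
class DetectionMatrix:
    """Species x site detection table.

    ``data`` is a DataFrame with species ids as index and site ids as
    columns; ``mode`` is ``"counts"`` (non-negative integers) or
    ``"presence"`` (binary).  ``is_species_complex`` flags taxa that lump
    several species and are removed before model fitting.
    """

    data: pd.DataFrame
    mode: str = "presence"
    is_species_complex: pd.Series = None

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise FormatError("duplicate species ids")
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate site ids")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("non-numeric cells")
        if (vals < 0).any():
            raise FormatError("negative cells")
        if self.mode == "presence" and not np.isin(vals, (0, 1)).all():
            raise FormatError("presence mode requires binary values")
        if self.mode not in ("counts", "presence"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.is_species_complex is None:
            self.is_species_complex = pd.Series(False, index=self.data.index)
        else:
            self.is_species_complex = self.is_species_complex.reindex(
                self.data.index, fill_value=False).astype(bool)

    @classmethod
    def from_arrays(cls, values, species_ids, site_ids, mode="presence", is_species_complex=None):
        df = pd.DataFrame(np.asarray(values), index=list(species_ids), columns=list(site_ids))
        flags = None
        if is_species_complex is not None:
            flags = pd.Series(np.asarray(is_species_complex, dtype=bool), index=list(species_ids))
        return cls(df, mode=mode, is_species_complex=flags)

    @property
    def species_ids(self):
        return list(self.data.index)

    @property
    def site_ids(self):
        return list(self.data.columns)

    @property
    def n_species(self):
        return self.data.shape[0]

    @property
    def n_sites(self):
        return self.data.shape[1]

    def to_presence(self) -> "DetectionMatrix":
        """Binarize counts; identity on presence mode."""
        if self.mode == "presence":
            return self
        return DetectionMatrix((self.data > 0).astype(np.int64), mode="presence",
                               is_species_complex=self.is_species_complex.copy())

    def occupancy(self) -> pd.Series:
        """Number of sites where each species is detected."""
        return (self.data > 0).sum(axis=1)

    def to_tsv(self, path):
        self.data.to_csv(path, sep="\t", index_label="species")


@dataclass
class SiteTable:
    """Per-site coordinates, district labels and environmental covariates.

    ``data`` is indexed by site id with columns ``lon``, ``lat``,
    ``district`` and one column per covariate (NaN where missing).
    ``distance_convention`` declares how pairwise distances are computed:
    ``"haversine-km"`` for real longitude/latitude data, ``"euclidean"``
    for synthetic planar coordinates.
    """

    data: pd.DataFrame
    covariate_cols: tuple = ()
    distance_convention: str = "euclidean"
    district_vocabulary: tuple = None

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise FormatError("duplicate site ids")
        for col in ("lon", "lat"):
            if col not in self.data.columns:
                raise FormatError(f"site table missing column {col!r}")
            if not np.isfinite(self.data[col].to_numpy(dtype=float)).all():
                raise FormatError(f"non-finite {col}")
        if self.distance_convention not in ("haversine-km", "euclidean"):
            raise ValueError(f"unknown distance convention {self.distance_convention!r}")
        if "district" in self.data.columns and self.district_vocabulary is not None:
            bad = set(self.data["district"]) - set(self.district_vocabulary)
            if bad:
                raise ConsistencyError(f"district labels outside vocabulary: {sorted(bad)}")
        self.covariate_cols = tuple(self.covariate_cols)

    @classmethod
    def from_arrays(cls, site_ids, coords, covariates=None, districts=None,
                    distance_convention="euclidean", district_vocabulary=None):
        coords = np.asarray(coords, dtype=float)
        df = pd.DataFrame({"lon": coords[:, 0], "lat": coords[:, 1]}, index=list(site_ids))
        if districts is not None:
            df["district"] = list(districts)
        cov_cols = ()
        if covariates:
            for name, vals in covariates.items():
                df[name] = np.asarray(vals, dtype=float)
            cov_cols = tuple(covariates)
        return cls(df, covariate_cols=cov_cols, distance_convention=distance_convention,
                   district_vocabulary=district_vocabulary)

    @property
    def site_ids(self):
        return list(self.data.index)

    def coords(self):
        return self.data[["lon", "lat"]].to_numpy(dtype=float)

    def covariate_matrix(self, cols=None):
        cols = list(cols) if cols is not None else list(self.covariate_cols)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ConsistencyError(f"covariates not in site table: {missing}")
        return self.data[cols].to_numpy(dtype=float)

    def to_csv(self, path):
        self.data.to_csv(path, index_label="site")


def read_detection_table(path, sep=None, species_complex_ids=()):
    """Read a species x site table (first column species ids, header site ids).

    Mode is inferred: all values in {0, 1} -> presence, otherwise counts.
    """
    sep = sep if sep is not None else ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise FormatError("duplicate species ids")
    if df.columns.duplicated().any():
        raise FormatError("duplicate site ids")
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError("non-numeric cells") from exc
    if not np.isfinite(vals).all():
        raise FormatError("missing or non-finite cells")
    if (vals < 0).any():
        raise FormatError("negative cells")
    if not np.allclose(vals, np.round(vals)):
        raise FormatError("non-integer cells")
    ivals = np.round(vals).astype(np.int64)
    mode = "presence" if np.isin(ivals, (0, 1)).all() else "counts"
    df.index.name = None
    flags = pd.Series(df.index.isin(set(species_complex_ids)), index=df.index)
    return DetectionMatrix(pd.DataFrame(ivals, index=df.index, columns=df.columns),
                           mode=mode, is_species_complex=flags)


def read_site_table(path, covariate_cols=(), distance_convention="haversine-km",
                    district_vocabulary=None):
    df = pd.read_csv(path, index_col=0)
    return SiteTable(df, covariate_cols=tuple(covariate_cols),
                     distance_convention=distance_convention,
                     district_vocabulary=district_vocabulary)


def rarefy_counts(m: DetectionMatrix, depth: int, seed=0):
    """Subsample each site's reads without replacement to exactly ``depth``.

    Sites whose total read count is below ``depth`` are left unchanged and
    returned in the ``short_sites`` list (the survey keeps low-volume
    samples rather than discarding them).  Deterministic per seed.
    """
    if m.mode != "counts":
        raise ValueError("rarefaction requires a count-mode matrix")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = m.data.to_numpy().copy()
    short_sites = []
    for c, site in enumerate(m.data.columns):
        total = int(out[:, c].sum())
        if total < depth:
            short_sites.append(site)
            continue
        if total == depth:
            continue
        out[:, c] = rng.multivariate_hypergeometric(out[:, c], depth)
    if short_sites:
        warnings.warn(f"{len(short_sites)} site(s) below rarefaction depth left unchanged",
                      stacklevel=2)
    rarefied = DetectionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                               mode="counts", is_species_complex=m.is_species_complex.copy())
    return rarefied, short_sites


def filter_species(m: DetectionMatrix, min_sites: int = 6, drop_complexes: bool = True):
    """Drop species-complex taxa and taxa occupying fewer than ``min_sites`` sites.

    Occupancy is computed once on the input (a single preprocessing pass, not
    iterated to a fixed point).  Returns the filtered matrix and a removal
    report ``{species_id: reason}``.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    occupancy = m.occupancy()
    report = {}
    keep = []
    for sp in m.data.index:
        if drop_complexes and bool(m.is_species_complex.loc[sp]):
            report[sp] = "species_complex"
        elif occupancy.loc[sp] < min_sites:
            report[sp] = f"occupancy<{min_sites}"
        else:
            keep.append(sp)
    out = DetectionMatrix(m.data.loc[keep], mode=m.mode,
                          is_species_complex=m.is_species_complex.loc[keep])
    return out, report


def filter_sites(m: DetectionMatrix, sites: SiteTable, required_covariates=()):
    """Drop sites where any required covariate is missing, from both tables."""
    if list(m.site_ids) != list(sites.site_ids):
        raise ConsistencyError("detection matrix and site table have different site ids")
    required = list(required_covariates) if required_covariates else list(sites.covariate_cols)
    missing_cols = [c for c in required if c not in sites.data.columns]
    if missing_cols:
        raise ConsistencyError(f"required covariates absent from site table: {missing_cols}")
    bad = sites.data[required].isna().any(axis=1) if required else pd.Series(False, index=sites.data.index)
    removed = list(sites.data.index[bad])
    keep = list(sites.data.index[~bad])
    m_out = DetectionMatrix(m.data[keep], mode=m.mode,
                            is_species_complex=m.is_species_complex.copy())
    s_out = SiteTable(sites.data.loc[keep], covariate_cols=sites.covariate_cols,
                      distance_convention=sites.distance_convention,
                      district_vocabulary=sites.district_vocabulary)
    report = {site: "missing_covariate" for site in removed}
    return m_out, s_out, report


def site_richness(m: DetectionMatrix) -> pd.Series:
    """Number of species detected (> 0) per site."""
    return (m.data > 0).sum(axis=0)


def jaccard_distances(m: DetectionMatrix) -> pd.DataFrame:
    """Pairwise Jaccard distances between sites, ``1 - |A∩B| / |A∪B|``.

    Counts are binarized first.  A pair of sites with no species at all has
    distance 0 by convention (scipy's 0/0 = 0 rule).
    """
    pres = m.to_presence().data.to_numpy().T.astype(bool)  # sites x species
    d = squareform(pdist(pres, metric="jaccard"))
    return pd.DataFrame(d, index=m.site_ids, columns=m.site_ids)
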