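"""Descriptive community structure: district richness summaries and t-SNE ordination."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .community import ConsistencyError, SiteTable


def district_richness_summary(richness: pd.Series, sites: SiteTable) -> pd.DataFrame:
    """Per-district richness summary (n, median, quartiles).

    ``richness`` is indexed by site id; districts come from the site table.
    Districts with no sites are absent from the output.
    """
    if "district" not in sites.data.columns:
        raise ConsistencyError("site table has no district column")
    if not richness.index.equals(sites.data.index):
        richness = richness.reindex(sites.data.index)
        if richness.isna().any():
            raise ConsistencyError("richness and site table site ids do not align")
    if sites.district_vocabulary is not None:
        bad = set(sites.data["district"]) - set(sites.district_vocabulary)
        if bad:
            raise ConsistencyError(f"unknown district labels: {sorted(bad)}")
    df = pd.DataFrame({"richness": richness, "district": sites.data["district"]})
    grouped = df.groupby("district")["richness"]
    out = grouped.agg(n="size", median="median",
                      q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
    return out


def tsne_embed(dist_matrix, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of a precomputed (square, symmetric) distance matrix.

    Deterministic for a fixed seed (random initialization seeded by ``seed``).
    """
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if perplexity >= n - 1:
        raise ValueError("perplexity must be < n - 1")
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                perplexity=perplexity, random_state=seed)
    return tsne.fit_transform(d)
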