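import warnings

import numpy as np
import pytest

from latentniche import SpatialGLLVM, SyntheticConfig, generate_communities


@pytest.fixture(scope="session")
def small_community():
    """A small synthetic coastal community with known truth (80 sites, 25 species)."""
    cfg = SyntheticConfig(n_sites=80, n_species=25, n_latent=2,
                          matern_ranges=(0.3, 0.6), seed=42)
    truth, detections, sites = generate_communities(cfg)
    return truth, detections, sites


@pytest.fixture(scope="session")
def small_fit(small_community):
    """A fitted two-latent-variable model on the small community (fixed priors)."""
    truth, detections, sites = small_community
    Y = detections.data.to_numpy().T.astype(float)
    model = SpatialGLLVM(n_latent=2, spatial_ranges=(0.3, 0.6), sigma_alpha=0.3,
                         n_outer=1, max_iter=1500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Y, truth.coords, truth.covariates)
    return model
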