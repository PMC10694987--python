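import warnings

import numpy as np
import pytest

from gbpath import synthetic_data as sd

# umap-learn warns that a fixed random_state disables parallelism; that is
# exactly what we want for reproducible embeddings.
warnings.filterwarnings("ignore", message=".*random_state.*", module="umap")


@pytest.fixture(scope="session")
def noise_free_sim():
    """A dense noise-free H-DAB tile shared by round-trip and ratio tests."""
    cfg = sd.ImageSimConfig(
        width=700, height=700, n_cells=500, dab_positive_fraction=0.3,
        background_noise_sd=0.0, allow_overlap=True, seed=11,
    )
    return sd.generate_ihc_image(cfg)


@pytest.fixture(scope="session")
def nonoverlap_sim():
    """A sparse non-overlapping tile where every nucleus is a separate object."""
    cfg = sd.ImageSimConfig(
        width=600, height=600, n_cells=60, allow_overlap=False,
        morphology_populations=[sd.MorphologyPopulation(1.0, 10.0, 1.0, 0.6, 0.02)],
        background_noise_sd=0.0, seed=7,
    )
    return sd.generate_ihc_image(cfg)


@pytest.fixture(scope="session")
def clustered_expression():
    """A 3-cluster expression matrix with a clear signature effect."""
    cfg = sd.ExprSimConfig(
        n_samples=60, n_genes=80, k_clusters=3, signature_size=30,
        effect_size=2.5, noise_sd=0.5, n_housekeeping=4, seed=3,
    )
    expr, labels, ann = sd.generate_expression(cfg)
    signature = [g for g in expr.index if g.startswith("sig_")]
    return np.log(expr.loc[signature]), labels
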