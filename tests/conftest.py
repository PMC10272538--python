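import numpy as np
import pandas as pd
import pytest

from traitkrige.synthetic import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def block_config(seed: int, noise_sd: float = 0.1) -> SyntheticConfig:
    """Five planted 3-trait factor blocks plus one weakly loading trait.

    Within-block CWM correlations exceed 0.8 by construction, so the MDS
    builder should retain exactly one trait per block.
    """
    traits = [f"T{i}" for i in range(15)] + ["Tw"]
    loading_spec = {f"T{i}": (i // 3, 0.95) for i in range(15)}
    loading_spec["Tw"] = (0, 0.2)
    scales = {t: (10.0, 2.0) for t in traits}
    return SyntheticConfig(n_latent_factors=5, loading_spec=loading_spec,
                           trait_scales=scales, noise_sd=noise_sd, seed=seed)


def block_trait_table(seed: int, noise_sd: float = 0.1) -> pd.DataFrame:
    cfg = block_config(seed, noise_sd)
    cols = ["plot", "subplot", "x", "y"] + list(cfg.loading_spec)
    # reuse the generator machinery but with the custom trait set
    from traitkrige.synthetic import subplot_centers, _trait_block
    rng = np.random.default_rng(seed)
    centers = subplot_centers(cfg.grid_side, cfg.subplot_size)
    n_sub = len(centers)
    index = pd.DataFrame({
        "plot": np.repeat([chr(ord("A") + i) for i in range(cfg.n_plots)], n_sub),
        "subplot": np.tile(np.arange(1, n_sub + 1), cfg.n_plots),
        "x": np.tile(centers[:, 0], cfg.n_plots),
        "y": np.tile(centers[:, 1], cfg.n_plots),
    })
    block = _trait_block(cfg, list(cfg.loading_spec), len(index), rng)
    return pd.concat([index, block], axis=1)[cols]


@pytest.fixture(scope="session")
def default_dataset():
    return generate(SyntheticConfig(seed=42))
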