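import numpy as np
import pytest

from rbplandscape import (
    SimulationConfig,
    binarize,
    compute_landscape,
    define_background,
    generate_compendium,
    generate_score_matrix,
    permutation_control,
)


@pytest.fixture(scope="session")
def strong_instance():
    """One strong-effect synthetic instance with everything precomputed."""
    cfg = SimulationConfig(seed=1)
    compendium = generate_compendium(cfg)
    matrix, ledger = generate_score_matrix(cfg, compendium)
    network = binarize(matrix, cfg.threshold)
    background = define_background(network, compendium)
    landscape = compute_landscape(network, compendium, background)
    verdicts = permutation_control(
        network, compendium, background, n_shuffles=1000, seed=1, landscape=landscape
    )
    return {
        "cfg": cfg,
        "compendium": compendium,
        "matrix": matrix,
        "ledger": ledger,
        "network": network,
        "background": background,
        "landscape": landscape,
        "verdicts": verdicts,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
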