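import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def paper_like_fit():
    """One fitted model on the default four-source simulator (reused)."""
    import cstfp

    cfg = cstfp.default_paper_like_config(seed=7)
    trials = cstfp.generate_trials(cfg)
    model = cstfp.fit(
        trials,
        cstfp.CstfpConfig(
            F=4,
            r=1,
            P=41,
            eps=0.05,
            window_scheme="block_combination",
            window_params={"D": 6, "J": 10},
            seed=7,
        ),
    )
    return cfg, trials, model
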