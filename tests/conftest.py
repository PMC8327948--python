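import numpy as np
import pytest

import morphomod as mm


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated pair dataset with its superimposed symmetric shapes."""
    params = mm.SyntheticParams(seed=11, n_wild=20, n_domestic=20)
    dataset, module_map, pairing, truth = mm.simulate_dataset(params)
    fit = mm.gpa(dataset)
    sym, asym = mm.symmetric_component(fit, pairing)
    return {
        "params": params,
        "dataset": dataset,
        "module_map": module_map,
        "pairing": pairing,
        "truth": truth,
        "fit": fit,
        "sym": sym,
        "asym": asym,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
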