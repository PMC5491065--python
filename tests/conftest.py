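import numpy as np
import pytest
from hypothesis import settings

import otopattern as op

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_run():
    """Desk-scale synthetic experiment run end to end: 4,000 probes,
    40 planted per pattern, the 15-array design."""
    cfg = op.SimulationConfig(
        n_probes=4000,
        n_neg_controls=200,
        planted={label: 40 for label in op.GROUP_LABEL_ORDER},
        seed=11,
    )
    exp = op.simulate_experiment(cfg)
    matrix, ctypes = op.assemble_matrix(exp.scans, exp.sheet)
    log2m, decisions = op.preprocess_pipeline(matrix, ctypes)
    results = op.ExpressionPatternModel(log2m, exp.sheet).fit()
    return {
        "config": cfg,
        "experiment": exp,
        "raw": matrix,
        "control_types": ctypes,
        "log2": log2m,
        "decisions": decisions,
        "results": results,
    }


@pytest.fixture(scope="session")
def default_run():
    """The full default study conditions: 60,000 probes, 100 planted per
    binary pattern, effect 4 log2, noise sd 0.25, 15 arrays."""
    cfg = op.SimulationConfig(seed=20170601)
    exp = op.simulate_experiment(cfg)
    matrix, ctypes = op.assemble_matrix(exp.scans, exp.sheet)
    log2m, decisions = op.preprocess_pipeline(matrix, ctypes)
    results = op.ExpressionPatternModel(log2m, exp.sheet).fit()
    return {
        "config": cfg,
        "experiment": exp,
        "log2": log2m,
        "decisions": decisions,
        "results": results,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
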