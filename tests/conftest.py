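import logging

import numpy as np
import pandas as pd
import pytest

from scmod.pipeline import run_pipeline, synthetic_config
from scmod.preprocess import ExpressionDataset
from scmod.simulate import SimulationSpec, simulate

logging.getLogger("scmod").setLevel(logging.ERROR)

PIPELINE_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture
def toy_ds():
    """Small dense dataset: 8 genes x 12 samples, two subtypes."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    samples = [f"s{i:02d}" for i in range(12)]
    values = pd.DataFrame(
        rng.gamma(4.0, 3.0, size=(8, 12)), index=genes, columns=samples
    )
    labels = pd.Series(["a"] * 6 + ["b"] * 6, index=samples)
    return ExpressionDataset(values=values, labels=labels, log_transformed=False)


@pytest.fixture(scope="session")
def sim_runs():
    """Full pipeline on the default synthetic study, five seeds.

    Shared by the recovery, separation, and end-to-end tests so the
    expensive part runs once per session.
    """
    runs = []
    for seed in PIPELINE_SEEDS:
        ds, truth = simulate(SimulationSpec(seed=seed))
        cfg = synthetic_config(seed=seed, E=50)
        res = run_pipeline(cfg, ds=ds)
        runs.append({"seed": seed, "truth": truth, "result": res, "cfg": cfg})
    return runs
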