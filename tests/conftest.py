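import numpy as np
import pandas as pd
import pytest

from xsci.io import ExpressionStudy
from xsci.pipeline import RunConfig, run_pipeline
from xsci.simulate import SimulationConfig, simulate_dataset

#: all four studies at 4 samples per arm (the recovery-study conditions)
PLAN_4PER_ARM = (
    ("rat_clip", "rat", 4, 4),
    ("rat_transection", "rat", 4, 4),
    ("mouse_hemisection", "mouse", 4, 4),
    ("axolotl_transection", "salamander", 4, 4),
)


@pytest.fixture
def toy_study() -> ExpressionStudy:
    """A tiny deterministic 6-probeset, 4+4-sample study."""
    rng = np.random.default_rng(101)
    cols = [f"inj{i}" for i in range(4)] + [f"ctl{i}" for i in range(4)]
    mat = pd.DataFrame(
        rng.normal(7.0, 0.6, size=(6, 8)),
        index=[f"ps{i}" for i in range(6)],
        columns=cols,
    )
    mat.loc[["ps0", "ps1"], cols[:4]] += 2.0  # two planted DE probesets
    groups = {c: ("injured" if c.startswith("inj") else "control") for c in cols}
    annot = {"ps0": "GeneA", "ps1": "GeneA", "ps2": "GeneB",
             "ps3": "GeneC", "ps4": "GeneC"}  # ps5 unmapped
    return ExpressionStudy("toy", "rat", mat, groups, annot)


@pytest.fixture(scope="session")
def small_dataset():
    """A 120-gene simulated dataset shared across tests (read-only)."""
    cfg = SimulationConfig(seed=9, n_genes=120)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_run():
    """The full pipeline under the planted-recovery study conditions."""
    cfg = RunConfig(
        simulation=SimulationConfig(
            seed=42, n_genes=500, species_plan=PLAN_4PER_ARM,
            frac_consistent=0.1, frac_opposite=0.1,
            effect_log2fc=2.0, noise_sd=0.5, ortholog_dropout=0.0,
        ),
        seed=42,
    )
    return run_pipeline(cfg)
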