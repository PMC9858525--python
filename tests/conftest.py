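import logging

import numpy as np
import pytest

from pleiocross import harmonize_pair
from pleiocross.simulate import SimConfig, simulate_study
from pleiocross.sumstats import LDReference

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated two-trait study shared across tests."""
    cfg = SimConfig(M=4000, n_genes=100, seed=7)
    ss1, ss2, panel, genes, segments, effects = simulate_study(cfg)
    return {
        "cfg": cfg,
        "ss1": ss1,
        "ss2": ss2,
        "panel": panel,
        "genes": genes,
        "segments": segments,
        "effects": effects,
        "pair": harmonize_pair(ss1, ss2),
    }


@pytest.fixture()
def toy_panel():
    """Two hand-built LD blocks: a correlated pair plus three near-independent SNPs."""
    R1 = np.array(
        [
            [1.0, 0.7, 0.1],
            [0.7, 1.0, 0.1],
            [0.1, 0.1, 1.0],
        ]
    )
    R2 = np.array([[1.0, 0.2], [0.2, 1.0]])
    return LDReference(
        blocks=[
            (np.array(["s1", "s2", "s3"]), R1),
            (np.array(["s4", "s5"]), R2),
        ],
        n_ref=10_000,
    )
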