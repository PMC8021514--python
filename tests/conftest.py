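import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from methylpanel import BetaMatrix, ProbeAnnotation, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    config = SimulationConfig(seed=11, n_probes=1200)
    return simulate_cohort(config)


@pytest.fixture
def tiny_beta():
    """3 probes x 4 samples with known values, detection p attached."""
    beta = pd.DataFrame(
        [[0.1, 0.2, 0.8, 0.9], [0.5, 0.5, 0.5, 0.5], [0.0, 1.0, 0.3, 0.7]],
        index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    detection = pd.DataFrame(
        np.full((3, 4), 0.001),
        index=beta.index,
        columns=beta.columns,
    )
    return BetaMatrix(beta, detection)


@pytest.fixture
def tiny_annotation():
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": ["1", "X", "7"],
                "position": [100, 200, 300],
                "gene_symbol": ["GENE1", None, "CDK14"],
                "cpg_type": ["Island", "OpenSea", "S_Shore"],
                "gene_region": ["TSS200", "Intergenic", "FirstIntron"],
            },
            index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
        )
    )
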