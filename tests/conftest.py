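import numpy as np
import pandas as pd
import pytest

import panprost as pp


@pytest.fixture
def tiny_expression() -> pp.ExpressionMatrix:
    """3 genes x 2 samples, log2 scale."""
    return pp.ExpressionMatrix(
        data=pd.DataFrame(
            [[1.5, 2.5], [3.0, 4.0], [5.25, 6.75]],
            index=pd.Index(["TP53", "PTEN", "AR"], name="gene"),
            columns=["S1", "S2"],
        )
    )


@pytest.fixture
def clinical_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(1, 13)],
            "patient_id": [f"P{i}" for i in range(1, 13)],
            "sample_type": ["primary"] * 10 + ["normal"] * 2,
            "grade_group": ["<=6", "7", ">=8"] * 4,
            "gleason_primary": [3, 3, 4] * 4,
            "gleason_secondary": [3, 4, 5] * 4,
            "gleason_sum": [6, 7, 9] * 4,
            "isup": [1, 2, 5] * 4,
            "bcr_event": [0, 1] * 6,
            "time_to_bcr": [12.0 + i for i in range(12)],
            "os_event": [0] * 12,
            "time_to_os": [60.0] * 12,
        }
    )


@pytest.fixture
def clinical(clinical_frame) -> pp.ClinicalTable:
    return pp.ClinicalTable(data=clinical_frame)


@pytest.fixture(scope="session")
def sim_bundles():
    """Default-condition synthetic studies, shared across tests (seed 11)."""
    cfg = pp.SimConfig(seed=11)
    return pp.simulate_multistudy(cfg)


@pytest.fixture(scope="session")
def ar_matrix() -> pp.ExpressionMatrix:
    """Expression matrix containing the full AR signature, 40 samples."""
    sig = pp.get_signature("ar")
    rng = np.random.default_rng(3)
    genes = sig.genes + [f"FILLER{i}" for i in range(10)]
    return pp.ExpressionMatrix(
        data=pd.DataFrame(
            rng.normal(8.0, 1.0, size=(len(genes), 40)),
            index=pd.Index(genes, name="gene"),
            columns=[f"S{i:02d}" for i in range(40)],
        )
    )
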