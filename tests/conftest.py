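import numpy as np
import pandas as pd
import pytest

from lesionexpr import ProbeMatchTable, StudyDesign


@pytest.fixture
def toy_match_table() -> ProbeMatchTable:
    """One clean probe set, one with a promiscuous probe, one matching nothing."""
    return ProbeMatchTable.from_records(
        [
            ("ps1", "p1", ["PGR"]),
            ("ps1", "p2", ["PGR"]),
            ("ps1", "p3", ["PGR"]),
            ("ps2", "q1", ["ESR1"]),
            ("ps2", "q2", ["ESR1"]),
            ("ps2", "q3", ["ESR1"]),
            ("ps2", "q4", ["ESR1", "ESR2"]),
            ("ps3", "r1", []),
            ("ps3", "r2", []),
        ]
    )


@pytest.fixture
def paired_design() -> StudyDesign:
    rows = [
        {"sample_id": f"P{i}_{c}", "patient_id": f"P{i}", "tissue_class": c}
        for i in range(1, 5)
        for c in ("TDLU", "HELU")
    ]
    return StudyDesign(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
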