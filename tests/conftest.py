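import numpy as np
import pandas as pd
import pytest

from apocrine.io import ExpressionMatrix, ProbeAnnotation
from apocrine.synthetic import generate_expression


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    return ExpressionMatrix(values, ["p1", "p2", "p3"], ["s1", "s2"])


@pytest.fixture()
def plain_annotation():
    def make(probe_ids, controls=()):
        return ProbeAnnotation(
            pd.DataFrame(
                {
                    "gene_symbol": [f"G{i}" for i in range(len(probe_ids))],
                    "unigene_id": [f"Hs.{i}" for i in range(len(probe_ids))],
                    "entrez_id": [str(i + 1) for i in range(len(probe_ids))],
                    "is_control": [p in controls for p in probe_ids],
                },
                index=pd.Index(probe_ids, name="probe_id"),
            )
        )

    return make


@pytest.fixture(scope="session")
def study_like_scenario():
    """One shared cohort at the default study-like conditions (74 samples,
    5 subtypes + 5 apocrine of which 3 Cowden, 84-probe block, 20,000
    probes; the probe count matters because the rCV selection window is a
    cohort percentile)."""
    return generate_expression(seed=0)
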