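import pandas as pd
import pytest

from crossprio import ExpressionMatrix, OrthologMap, canonical_symbol
from crossprio.datasets import load_cohort_patients, load_cohort_variants


@pytest.fixture(scope="session")
def cohort_variants():
    """The bundled 27-row candidate-gene VUS table."""
    return load_cohort_variants()


@pytest.fixture(scope="session")
def cohort_patients():
    """The bundled 32-patient cohort table."""
    return load_cohort_patients()


@pytest.fixture(scope="session")
def cohort_ortholog_map(cohort_variants):
    """Human->mouse map covering every gene in the bundled variant table."""
    genes = sorted({r.gene for r in cohort_variants})
    return OrthologMap([(g, canonical_symbol(g, "mouse")) for g in genes])


def make_matrix(data: dict, groups: dict, unit: str = "FPKM", index=None) -> ExpressionMatrix:
    frame = pd.DataFrame(data)
    if index is not None:
        frame.index = index
    else:
        frame.index = [f"Gene{i:03d}" for i in range(1, len(frame) + 1)]
    return ExpressionMatrix(values=frame, groups=groups, unit=unit)
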