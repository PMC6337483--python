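import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from ddipipe.integration import IntegratedDataset
from ddipipe.io import ExpressionStudy


def make_study(values, groups, study_id="S1", genes=None, samples=None):
    """Build an ExpressionStudy from a plain 2-D array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"{study_id}_s{j+1}" for j in range(values.shape[1])]
    return ExpressionStudy(
        study_id=study_id,
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        groups=pd.Series(list(groups), index=samples),
    )


def make_integrated(values, groups, genes=None, samples=None, study="S1"):
    """Build an IntegratedDataset directly from a plain 2-D array (no z-scoring)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    info = pd.DataFrame({"study": study, "group": list(groups)}, index=samples)
    return IntegratedDataset(values=frame, sample_info=info, provenance=[study])


@pytest.fixture
def tiny_study():
    return make_study([[1.0, 4.0], [2.0, 5.0], [3.0, 7.0]], ["case", "control"])
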