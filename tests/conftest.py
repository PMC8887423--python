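import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ribopara.digestion import build_peptide_index
from ribopara.quantify import AbundanceMatrix, SampleDesign
from ribopara.registry import load_bundled_registry
from ribopara.synthetic import make_toy_registry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundled_registry():
    return load_bundled_registry()


@pytest.fixture(scope="session")
def bundled_index(bundled_registry):
    return build_peptide_index(bundled_registry)


@pytest.fixture(scope="session")
def toy_registry():
    return make_toy_registry(seed=11)


@pytest.fixture
def mk_design():
    """Factory: a one-channel-per-tissue design over n replicate runs."""

    def build(tissues, n_reps=1, pooled=False, complex="m80S"):
        rows = []
        for i in range(n_reps):
            run, rep = f"TMT{i + 1}", f"rep{i + 1}"
            for j, tissue in enumerate(tissues):
                rows.append((run, f"c{j + 1:02d}", tissue, complex, rep, False))
            if pooled:
                rows.append(
                    (run, f"c{len(tissues) + 1:02d}", "pool", complex, rep, True)
                )
        return SampleDesign(pd.DataFrame(rows, columns=SampleDesign.COLUMNS))

    return build


@pytest.fixture
def mk_matrix(mk_design):
    """Factory: an AbundanceMatrix from a {protein: [values]} dict.

    Values are laid out one channel per tissue per run, matching the design
    produced by the same call.
    """

    def build(rows, tissues, n_reps=1, stage="normalized", pooled=False):
        design = mk_design(tissues, n_reps=n_reps, pooled=pooled)
        cols = pd.MultiIndex.from_tuples(design.columns(), names=["run", "channel"])
        values = pd.DataFrame(
            {acc: list(vals) for acc, vals in rows.items()}, index=cols
        ).T
        values.columns = cols
        return AbundanceMatrix(values=values.astype(float), stage=stage, design=design)

    return build
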