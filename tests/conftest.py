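import numpy as np
import pytest

from netreduce import MetabolicModel, build_toy


@pytest.fixture(scope="session")
def worked_example():
    return build_toy("worked_example")


@pytest.fixture(scope="session")
def diamond():
    return build_toy("diamond")


@pytest.fixture(scope="session")
def oxidase_pair():
    return build_toy("oxidase_pair")


@pytest.fixture()
def chain_model():
    """Linear chain X_ext -> A -> B -> Y_ext with uptake capped at 10."""
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["R_up", "R_mid", "R_ex"],
        S=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        lower_bounds=np.array([0.0, 0.0, 0.0]),
        upper_bounds=np.array([10.0, 1000.0, 1000.0]),
        objective=np.array([0.0, 0.0, 1.0]),
        external_species=["X_ext", "Y_ext"],
        S_ext=np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
        name="chain",
    )
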