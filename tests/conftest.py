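import importlib.resources as ir

import pandas as pd
import pytest
from hypothesis import settings

from cyclefba.cycle import CycleSpec, famine_phase, feast_phase
from cyclefba.toy import make_toy_model

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def linear_toy():
    return make_toy_model("linear", q_max=10.0, gam=2.0, ngam=1.0)


@pytest.fixture
def redundant_toy():
    return make_toy_model("redundant", q_max=10.0, gam=2.0, ngam=1.0)


@pytest.fixture
def two_pool_toy():
    return make_toy_model("two_pool", q_max=10.0, gam=2.0, ngam=1.0)


def make_cycle_spec(model, sub_objective="none", fixed_storage=None,
                    target=None, feast_fraction=0.5, uptake=10.0,
                    storage_units="native"):
    return CycleSpec(
        model=model,
        feast=feast_phase(feast_fraction, {"upt": (0.0, uptake)}),
        famine=famine_phase(1.0 - feast_fraction),
        fixed_storage=dict(fixed_storage or {}),
        storage_units=storage_units,
        target_cycle_growth=target,
        sub_objective=sub_objective,
    )


@pytest.fixture
def cycle_spec(linear_toy):
    return make_cycle_spec(linear_toy)


@pytest.fixture
def storage_flux_table():
    path = ir.files("cyclefba") / "data" / "rha1_storage_fluxes.tsv"
    return pd.read_csv(str(path), sep="\t")
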