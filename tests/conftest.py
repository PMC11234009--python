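import numpy as np
import pytest

from coldwater import BioheatModel, build_default_body
from coldwater.control import PASSIVE


@pytest.fixture(scope="session")
def body():
    return build_default_body()


@pytest.fixture(scope="session")
def passive_model(body):
    """Solver on the default body with thermoregulation disabled."""
    return BioheatModel(body, controls=PASSIVE)


@pytest.fixture(scope="session")
def cooling_suite(body):
    """The full built-in cooling grid, run once per session."""
    from coldwater import builtin_scenarios, run_cooling_suite

    return {s.label: s for s in run_cooling_suite(builtin_scenarios(), body)}


@pytest.fixture(scope="session")
def posthypo_state(body):
    from coldwater import post_hypothermic_state

    return post_hypothermic_state(body)
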