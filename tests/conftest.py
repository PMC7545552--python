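import pytest

from webpsa.pipeline import run_gender
from webpsa.scenarios import default_stage_spec, make_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-scale strong-selection scenario shared across tests."""
    return make_scenario(seed=42, n_population=20_000, n_ref=2_000, n_web=1_000)


@pytest.fixture(scope="session")
def male_run(small_scenario):
    """Full per-gender pipeline result (no bootstrap) on the small scenario."""
    sc = small_scenario
    return run_gender(
        sc["reference"],
        sc["web"],
        sc["margins"],
        default_stage_spec(),
        sc["outcomes"],
        "male",
    )
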