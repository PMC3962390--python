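import pytest

import neuromobile as nm


@pytest.fixture(scope="session")
def model() -> nm.MatrixModel:
    return nm.MatrixModel.default()


@pytest.fixture(scope="session")
def tree(model) -> nm.MobileTree:
    return nm.calibrate_lever_lengths(nm.default_tree(), model.baseline)


@pytest.fixture(scope="session")
def alcohol_result(model, tree) -> nm.ScenarioResult:
    """Default four-phase alcohol scenario (alpha = gamma = 1.3)."""
    return nm.run_scenario(model, tree, nm.build_alcohol_timeline())


@pytest.fixture(scope="session")
def diazepam_result(model, tree) -> nm.ScenarioResult:
    schedule = nm.apply_treatment(nm.build_alcohol_timeline(), preset="diazepam")
    return nm.run_scenario(model, tree, schedule)
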