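import pytest

from sprintgc.inception_net import GroundContactNet, ModelSpec
from sprintgc.study_io import TRAIN, VAL, StudyDesign
from sprintgc.synthetic_gait import GaitSimConfig, generate_run, generate_study


@pytest.fixture(scope="session")
def sim_cfg():
    return GaitSimConfig(seed=7)


@pytest.fixture(scope="session")
def run_record(sim_cfg):
    return generate_run(sim_cfg, "a01", "r1", "left")


def make_tiny_design() -> StudyDesign:
    """Two athletes x one run x two legs: one TRAIN athlete, one VAL."""
    athletes = [("x1", "M"), ("x2", "F")]
    split = {("x1", "r1"): TRAIN, ("x2", "r1"): VAL}
    return StudyDesign(athletes, ["r1"], ("left", "right"), (), split)


@pytest.fixture(scope="session")
def tiny_study():
    cfg = GaitSimConfig(seed=3, n_steps=3)
    return generate_study(cfg, make_tiny_design())


@pytest.fixture(scope="session")
def tiny_spec():
    """A deliberately small architecture for fast training tests."""
    return ModelSpec(
        n_blocks=1, kernel_sizes=(1, 3), branch_filters=8, concat_channels=16,
        in_channels=2, lr=0.01, seed=3,
    )


@pytest.fixture()
def tiny_model(tiny_spec):
    return GroundContactNet(tiny_spec)


@pytest.fixture(scope="session")
def reference_experiment():
    """The scaled-down reference experiment: default synthetic study,
    6-block model, window 100 / stride 15, early stopping. Trained once
    per session; several end-to-end tests share it."""
    from sprintgc.pipeline import run_experiment

    return run_experiment(seed=1)
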