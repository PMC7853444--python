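import numpy as np
import pytest

from copefr.fr_fit import FRParameters
from copefr.synthetic import SimulationConfig, generate_fr_dataset
from copefr.trials import ExperimentDesign, PredationTrial


def single_group_design() -> ExperimentDesign:
    """The standard density gradient for one species x temperature group."""
    return ExperimentDesign(species_list=("M_albidus",), temperatures_list=(20,))


def simulate_group(
    seed: int,
    b: float = 1.0,
    h: float = 0.5,
    m: float = 0.0,
    simulator: str = "binomial",
) -> list[PredationTrial]:
    """One group's trials (28 predator + 7 control dishes) at known truth."""
    cfg = SimulationConfig(
        seed=seed,
        design=single_group_design(),
        group_params={("M_albidus", 20): FRParameters(b=b, h=h, m=m, q=0)},
    )
    trials, _ = generate_fr_dataset(cfg, simulator=simulator)
    return trials


@pytest.fixture
def small_trials() -> list[PredationTrial]:
    """Three hand-written trials: two treatments and one control."""
    return [
        PredationTrial("t1", "FR", "M_albidus", 20, 8, 3, copepod_length_mm=1.8),
        PredationTrial("t2", "FR", "M_viridis", 15, 16, 10, copepod_length_mm=2.2),
        PredationTrial("t3", "FR", "none", 25, 32, 31, predator_count=0),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
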