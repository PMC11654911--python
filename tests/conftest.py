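import numpy as np
import pytest

from lodgeseg import encoding, objective, synthdata


def make_scenes(n: int, size: int, seed: int) -> list[synthdata.LodgingScene]:
    return [
        synthdata.generate_scene(
            synthdata.SceneParams(
                size=(size, size),
                seed=int(np.random.default_rng([seed, i]).integers(2**31)),
            )
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def desk_dataset():
    """The desk-scale study conditions: 40 train / 12 val scenes at 64x64."""
    scenes = make_scenes(52, 64, seed=11)
    return (
        objective.scenes_to_arrays(scenes[:40]),
        objective.scenes_to_arrays(scenes[40:]),
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A minimal training task for plumbing tests: 6 train / 2 val at 32x32."""
    scenes = make_scenes(8, 32, seed=7)
    return (
        objective.scenes_to_arrays(scenes[:6]),
        objective.scenes_to_arrays(scenes[6:]),
    )


@pytest.fixture(scope="session")
def base_plan():
    return encoding.reference_base_plan()


@pytest.fixture(scope="session")
def optimized_plan():
    return encoding.reference_optimized_plan()


@pytest.fixture(scope="session")
def desk_plan(base_plan):
    return base_plan.scaled(4)


@pytest.fixture(scope="session")
def small_plan(base_plan):
    return base_plan.scaled(8)
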