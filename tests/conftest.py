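import pytest
from hypothesis import settings

from mixqspr import pipeline, synthetic_data

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    """A tiny but fully exercised synthetic study."""
    return synthetic_data.SyntheticSpec(
        n_cations=5,
        n_anions=3,
        n_solutes=2,
        n_raffinates=2,
        temperatures=(288.15, 308.15, 328.15),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_components(small_spec):
    return synthetic_data.generate_components(small_spec)


@pytest.fixture(scope="session")
def small_dataset(small_spec, small_components):
    return synthetic_data.generate_dataset(small_spec, small_components)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """The desk-scale study: ~4.9k synthetic points, 4-config grid, 100 epochs.

    Trains both the selectivity regressor and the reliability classifier,
    evaluates them on the held-out optimization set and screens the
    combinatorial library for the first solute/raffinate pair at 298 K.
    """
    workdir = tmp_path_factory.mktemp("study")
    config = {"seed": 1, "epochs": 100, "cv_fraction": 0.2}
    artifacts = pipeline.run_pipeline(config, workdir)
    return {"workdir": workdir, "artifacts": artifacts, "config": config}
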