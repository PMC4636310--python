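import pytest

from cazyprofiler.synthetic import (
    SimulationConfig,
    generate_cohort,
    worked_example_fixture,
)


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    """The tiny hand-checkable 4-sample cohort, generated once."""
    return worked_example_fixture(tmp_path_factory.mktemp("worked_example"))


def small_config(**overrides) -> SimulationConfig:
    """A fast hit-level cohort: 12 samples, 24 families, ~100 hits each."""
    defaults = dict(
        n_samples=12,
        n_families=24,
        mean_hits_per_mbp=40.0,
        metagenome_size_range_bp=(2_000_000, 5_000_000),
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Hit-level files + ground truth for a small seeded cohort."""
    outdir = tmp_path_factory.mktemp("small_cohort")
    paths, truth = generate_cohort(small_config(), outdir)
    return paths, truth
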