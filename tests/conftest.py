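import pytest

from coralcf.synthetic import GeneratorParams, generate_study


@pytest.fixture(scope="session")
def study_seed1():
    """Default synthetic study at seed 1: (samples, env, rates, truth)."""
    return generate_study(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def study_zero_noise():
    """Noise-free synthetic study at seed 1 (exact-recovery tests)."""
    return generate_study(GeneratorParams(seed=1).zero_noise())


@pytest.fixture()
def study_csvs(study_seed1, tmp_path):
    """Seed-1 study written out as the pipeline's three CSV inputs."""
    samples, env, rates, truth = study_seed1
    paths = {
        "geochem": tmp_path / "geochemistry.csv",
        "env": tmp_path / "environment.csv",
        "rates": tmp_path / "rates.csv",
    }
    samples.to_csv(paths["geochem"], index=False)
    env.assign(date=env["date"].dt.date).to_csv(paths["env"], index=False)
    rates.to_csv(paths["rates"], index=False)
    return paths, truth
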