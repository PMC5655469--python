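import pytest

import oaburden as ob

SEED = 1234


@pytest.fixture(scope="session")
def fixture_tables():
    return ob.load_fixture_tables()


@pytest.fixture(scope="session")
def utilities(fixture_tables):
    return fixture_tables[0]


@pytest.fixture(scope="session")
def prevalence(fixture_tables):
    return fixture_tables[1]


@pytest.fixture(scope="session")
def life_table():
    return ob.generate_life_table()


@pytest.fixture(scope="session")
def pain_curve():
    return ob.generate_pain_curve()


@pytest.fixture(scope="session")
def population():
    return ob.generate_population_counts(1_800_000)


@pytest.fixture(scope="session")
def model_tables(utilities, life_table, pain_curve):
    return ob.ModelTables(utilities=utilities, life_table=life_table, pain_curve=pain_curve)


@pytest.fixture(scope="session")
def pipeline_inputs(utilities, life_table, pain_curve, prevalence, population):
    return ob.PipelineInputs(
        utilities=utilities,
        life_table=life_table,
        pain_curve=pain_curve,
        prevalence=prevalence,
        population=population,
        n_per_stratum=800,
        seed=SEED,
    )


@pytest.fixture(scope="session")
def burden_frame(pipeline_inputs):
    _, frame = ob.run_burden(pipeline_inputs)
    return frame
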