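import pytest
from hypothesis import HealthCheck, settings

from precocity import build_study_tree, load_study_table, phylo_covariance

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_table():
    return load_study_table()


@pytest.fixture(scope="session")
def study_tree(study_table):
    return build_study_tree(study_table, seed=1)


@pytest.fixture(scope="session")
def study_cov(study_table, study_tree):
    return phylo_covariance(study_tree).reorder(list(study_table["species"]))
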