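import pytest

from budclock.envcorrelation import select_genes_by_keywords
from budclock.io_formats import GeneSet
from budclock.normalization import cpm, filter_by_expression_sum
from budclock.synthetic_data import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic scenario at seed 1 (matrix, sheet, ann, env, truth)."""
    return simulate_counts(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_cpm(default_sim):
    matrix, _, _, _, _ = default_sim
    return cpm(matrix)


@pytest.fixture(scope="session")
def default_focal(default_sim, default_cpm):
    """Keyword-selected genes passing the CPM-sum-10 cutoff, plus the pool."""
    _, _, annotation, _, _ = default_sim
    keyword_set = select_genes_by_keywords(annotation, ["heat", "shock"])
    eligible = filter_by_expression_sum(default_cpm, 10.0)
    focal = GeneSet(keyword_set.name, keyword_set.members & eligible.members)
    return focal, eligible
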