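import dendropy
import numpy as np
import pytest

from helpers import lambda_grid_argmax
from precocity import (
    blomberg_k,
    blomberg_k_test,
    pagel_lambda_ml,
    phylo_covariance,
    phylo_mean,
    simulate_lambda_trait,
    simulate_yule_tree,
)
from precocity.errors import DomainError
from precocity.synthetic import rescale_tree_depth

# A frozen 16-tip ultrametric tree and trait vector used as an oracle
# fixture.  Reference values below were computed with the independent R
# implementation phytools::phylosig 2.5 (K and ML lambda) on this exact
# data; the trait was drawn from the lambda-Brownian model (lambda = 0.7)
# so the lambda optimum is interior.
ORACLE_NEWICK = (
    "(((((sp001:0.19745505045570635,sp002:0.19745505045570635)"
    ":0.05906576432555471,(sp003:0.019433621088027892,sp004:0.019433621088027892)"
    ":0.2370871936932332):0.3243644129028475,sp005:0.5808852276841086)"
    ":0.11545081585998843,(sp006:0.07854210230319056,sp007:0.07854210230319056)"
    ":0.6177939412409065):0.30366395645590294,(((((sp008:0.08445301847830146,"
    "sp009:0.08445301847830146):0.1414755270827193,sp010:0.22592854556102077)"
    ":0.10829596072353805,sp011:0.3342245062845588):0.0747918308904288,"
    "((sp012:0.028701458100341297,sp013:0.028701458100341297)"
    ":0.23663493525886853,(sp014:0.03469490979173707,sp015:0.03469490979173707)"
    ":0.23064148356747277):0.14367994381577778):0.28487522061990633,"
    "sp016:0.693891557794894):0.306108442205106):0.0;"
)
ORACLE_TRAIT = {
    "sp001": 0.18905338179362755,
    "sp002": -0.32625561086960964,
    "sp003": -0.37954824540345355,
    "sp004": -1.9048190245470713,
    "sp005": 1.4371867207881526,
    "sp006": 1.1486742022275083,
    "sp007": 0.47806400169285873,
    "sp008": 0.7738065867280484,
    "sp009": 0.7117875834068708,
    "sp010": 0.046771679530281426,
    "sp011": 1.1282765016662952,
    "sp012": 0.18075174859976065,
    "sp013": 0.06451711420115569,
    "sp014": -0.3192683946788521,
    "sp015": 0.3208699354310175,
    "sp016": 0.06560431785532234,
}
PHYTOOLS_K = 0.159254306588
PHYTOOLS_LAMBDA = 0.486769580339
PHYTOOLS_LOGL = -18.239991406103


@pytest.fixture(scope="module")
def oracle_case():
    tree = dendropy.Tree.get(data=ORACLE_NEWICK, schema="newick")
    cov = phylo_covariance(tree).reorder(list(ORACLE_TRAIT))
    x = np.array(list(ORACLE_TRAIT.values()))
    return x, cov


class TestPhyloMean:
    def test_identity_covariance_gives_arithmetic_mean(self):
        x = np.array([1.0, 4.0, -2.0, 3.0])
        assert phylo_mean(x, np.eye(4)) == pytest.approx(x.mean())

    def test_constant_trait_returns_the_constant(self, study_cov):
        x = np.full(study_cov.n, 3.7)
        assert phylo_mean(x, study_cov) == pytest.approx(3.7)

    def test_three_taxon_hand_computation(self):
        # tree ((A:1,B:1):1,C:2): C^-1 1 = (1/3, 1/3, 1/2), 1'C^-1 1 = 7/6
        # so for x = (1, 2, 4): mean = (1/3 + 2/3 + 2) / (7/6) = 18/7
        C = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        assert phylo_mean([1.0, 2.0, 4.0], C) == pytest.approx(18 / 7)


class TestBlombergK:
    def test_star_tree_gives_exactly_one(self):
        C = 2.7 * np.eye(8)
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=8)
            assert blomberg_k(x, C) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, study_cov, study_table):
        x = study_table["s50"].to_numpy()
        k = blomberg_k(x, study_cov)
        assert blomberg_k(-3.2 * x + 11.0, study_cov) == pytest.approx(k)

    def test_tree_rescaling_invariance(self, study_cov, study_table):
        from precocity.phylogeny import PhyloCovariance

        x = study_table["s50"].to_numpy()
        scaled = PhyloCovariance(
            matrix=7.5 * study_cov.matrix, taxa=study_cov.taxa
        )
        assert blomberg_k(x, scaled) == pytest.approx(blomberg_k(x, study_cov))

    def test_constant_trait_rejected(self, study_cov):
        with pytest.raises(DomainError):
            blomberg_k(np.ones(study_cov.n), study_cov)

    def test_matches_independent_reference(self, oracle_case):
        x, cov = oracle_case
        assert blomberg_k(x, cov) == pytest.approx(PHYTOOLS_K, abs=1e-9)


class TestKPermutationTest:
    def test_detects_strong_signal(self):
        # caterpillar tree with unit branches; trait = node depth of each tip
        parts = "t1:1"
        for i in range(2, 17):
            parts = f"(t{i}:1,{parts}):1"
        tree = dendropy.Tree.get(data=parts + ";", schema="newick")
        cov = phylo_covariance(tree)
        depths = np.diag(cov.matrix)
        res = blomberg_k_test(depths, cov, n_perm=999, seed=11)
        assert res.p_value <= 0.05

    def test_p_value_granularity_and_reproducibility(self, study_cov, study_table):
        x = study_table["s50"].to_numpy()
        r1 = blomberg_k_test(x, study_cov, n_perm=999, seed=4)
        r2 = blomberg_k_test(x, study_cov, n_perm=999, seed=4)
        assert r1.p_value == r2.p_value
        assert round(r1.p_value * 1000, 9) % 1 == 0
        assert 0 < r1.p_value <= 1


class TestPagelLambda:
    def test_matches_grid_argmax(self, oracle_case):
        x, cov = oracle_case
        res = pagel_lambda_ml(x, cov)
        assert abs(res.estimate - lambda_grid_argmax(x, cov)) <= 2e-3

    def test_matches_independent_reference(self, oracle_case):
        x, cov = oracle_case
        res = pagel_lambda_ml(x, cov)
        assert res.estimate == pytest.approx(PHYTOOLS_LAMBDA, abs=1e-4)
        assert res.loglik_at_estimate == pytest.approx(PHYTOOLS_LOGL, abs=1e-6)

    def test_loglik_no_worse_than_endpoints(self, oracle_case):
        from precocity.signal import lambda_loglik

        x, cov = oracle_case
        res = pagel_lambda_ml(x, cov)
        assert res.loglik_at_estimate >= lambda_loglik(x, cov, 0.0) - 1e-9
        assert res.loglik_at_estimate >= lambda_loglik(x, cov, 1.0) - 1e-9
        assert res.loglik_at_estimate >= res.loglik_at_null

    def test_recovers_brownian_motion(self):
        # traits simulated at lambda = 1 should give high estimates on average
        tree = rescale_tree_depth(simulate_yule_tree(64, seed=9))
        cov = phylo_covariance(tree)
        est = []
        for seed in range(20):
            x = simulate_lambda_trait(tree, 1.0, 1.0, 0.0, seed=100 + seed)
            est.append(pagel_lambda_ml(x.to_numpy(), cov).estimate)
        assert np.mean(est) >= 0.8

    def test_null_rejection_rate_is_conservative(self):
        # lambda = 0 truth: LRT at the boundary rejects at most ~alpha
        tree = rescale_tree_depth(simulate_yule_tree(32, seed=13))
        cov = phylo_covariance(tree)
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(size=cov.n)
            if pagel_lambda_ml(x, cov).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.08

    def test_nonultrametric_covariance_warns(self):
        tree = dendropy.Tree.get(data="((A:1,B:2):1,C:5);", schema="newick")
        cov = phylo_covariance(tree)
        with pytest.warns(UserWarning, match="ultrametric"):
            pagel_lambda_ml(np.array([1.0, 2.0, 0.5]), cov)
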