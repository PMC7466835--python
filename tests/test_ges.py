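import numpy as np
import pytest

from emonet.epochs import standardize
from emonet.exceptions import NoTriangleFreeGraphError
from emonet.ges import (
    PooledScorer,
    ScoreConfig,
    ges,
    local_bic,
    pooled_score,
    select_penalty,
)
from emonet.graphs import cpdag_of, enumerate_dags
from emonet.simulate import GroundTruthModel, sample_ground_truth, simulate_condition_series

from conftest import exhaustive_best_cpdag, make_series


def _sim(model, n, seed):
    return standardize(simulate_condition_series(model, n, seed))


@pytest.fixture(scope="module")
def fixture_table():
    """A fixed 8-row, 3-column standardized table."""
    rng = np.random.default_rng(42)
    return standardize(make_series(rng.normal(size=(8, 3)), rois=["X", "Y", "Z"]))


class TestLocalBic:
    def test_empty_parent_set_closed_form(self):
        """On a standardized column the residual variance is exactly 1, so
        the score reduces to the penalty -c * ln(n)."""
        rng = np.random.default_rng(0)
        s = standardize(make_series(rng.normal(size=(100, 2)), rois=["X", "Y"]))
        assert local_bic(s, "X", set(), c=1.0) == pytest.approx(-np.log(100), abs=1e-9)
        assert local_bic(s, "X", set(), c=2.0) == pytest.approx(-2 * np.log(100), abs=1e-9)

    def test_uncorrelated_parent_changes_penalty_only(self):
        """A parent with exactly zero sample correlation leaves the fit
        untouched; the score drops by exactly c * ln(n)."""
        n = 64
        x = np.sin(np.arange(n))
        y = np.cos(2 * np.arange(n))
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        # orthogonalize y against x exactly
        y = y - (y @ x) / (x @ x) * x
        y = (y - y.mean()) / y.std()
        s = make_series(np.column_stack([x, y]), rois=["X", "Y"])
        base = local_bic(s, "X", set(), c=1.5)
        with_parent = local_bic(s, "X", {"Y"}, c=1.5)
        assert with_parent - base == pytest.approx(-1.5 * np.log(n), abs=1e-8)

    def test_matches_brute_force_residual_variance(self, fixture_table):
        """Digit-for-digit against an explicit normal-equations fit."""
        s = fixture_table
        x = s.data[["X", "Z"]].to_numpy()
        y = s.data["Y"].to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        var = np.mean((y - x @ beta) ** 2)
        n, k, c = 8, 3, 1.0
        expected = -n * np.log(var) - c * k * np.log(n)
        assert local_bic(s, "Y", {"X", "Z"}, c=c) == pytest.approx(expected, abs=1e-10)

    def test_node_in_parents_rejected(self, fixture_table):
        with pytest.raises(ValueError):
            local_bic(fixture_table, "X", {"X"})


class TestPooledScore:
    def test_identical_datasets_equal_single(self, fixture_table):
        single = local_bic(fixture_table, "Y", {"X"}, c=1.0)
        pooled = pooled_score([fixture_table] * 4, "Y", {"X"}, c=1.0)
        assert pooled == pytest.approx(single, abs=1e-12)

    def test_mean_lies_between_extremes_and_matches_hand_average(self):
        rng = np.random.default_rng(1)
        a = standardize(make_series(rng.normal(size=(30, 2)), rois=["X", "Y"]))
        b = standardize(make_series(rng.normal(size=(30, 2)), rois=["X", "Y"]))
        va = local_bic(a, "Y", {"X"})
        vb = local_bic(b, "Y", {"X"})
        pooled = pooled_score([a, b], "Y", {"X"})
        assert pooled == pytest.approx((va + vb) / 2, abs=1e-12)
        assert min(va, vb) <= pooled <= max(va, vb)

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_score([], "Y", {"X"})


class TestScoreProperties:
    def test_decomposability_matches_whole_model_likelihood(self):
        """Sum of local scores equals the whole-model Gaussian likelihood:
        the implied ML covariance of a DAG fit has det = prod of residual
        variances, so -n*ln(det) must equal the summed likelihood terms."""
        truth = sample_ground_truth(
            ("A", "B", "C", "D"), edges=[("A", "B"), ("B", "C"), ("A", "D")], seed=0
        )
        data = _sim(truth, 300, seed=0)
        dag = truth.dag()
        scorer = PooledScorer([data], c=1.0)
        total = scorer.total(dag)
        # independent whole-model evaluation
        n = data.n_timepoints
        x = data.values()
        log_det = 0.0
        n_params = 0
        idx = {m: i for i, m in enumerate(data.rois)}
        for node in dag.nodes:
            pa = sorted(dag.parents(node))
            y = x[:, idx[node]]
            if pa:
                xp = x[:, [idx[p] for p in pa]]
                beta, *_ = np.linalg.lstsq(xp, y, rcond=None)
                resid = y - xp @ beta
            else:
                resid = y
            log_det += np.log(np.mean(resid**2))
            n_params += len(pa) + 1
        expected = -n * log_det - n_params * np.log(n)
        assert total == pytest.approx(expected, rel=1e-10)

    def test_markov_equivalent_dags_score_identically(self):
        """Every DAG in one equivalence class gets the same total BIC."""
        rng = np.random.default_rng(5)
        data = standardize(make_series(rng.normal(size=(60, 3)), rois=["A", "B", "C"]))
        scorer = PooledScorer([data], c=1.0)
        by_class = {}
        for dag in enumerate_dags(("A", "B", "C")):
            by_class.setdefault(cpdag_of(dag), []).append(scorer.total(dag))
        for scores in by_class.values():
            assert max(scores) - min(scores) < 1e-9


class TestGes:
    def test_independent_columns_give_empty_graph(self):
        m = GroundTruthModel(nodes=("A", "B", "C", "D"), ar_coefficient=0.0)
        datasets = [_sim(m, 500, seed=s) for s in range(5)]
        cp = ges(datasets, c=1.0)
        assert cp.n_edges == 0

    def test_single_strong_edge_recovered(self):
        m = GroundTruthModel(
            nodes=("X", "Y", "Z"), weights={("X", "Y"): 0.8}, ar_coefficient=0.0
        )
        datasets = [_sim(m, 500, seed=s) for s in range(3)]
        cp = ges(datasets, c=1.0)
        assert cp.skeleton() == {("X", "Y")}

    @pytest.mark.parametrize(
        "n_nodes,density,n,seed",
        [(3, 0.5, 150, 0), (3, 0.5, 150, 1), (3, 0.5, 150, 2), (3, 0.5, 150, 3),
         (4, 0.3, 600, 4), (4, 0.3, 600, 5), (4, 0.3, 600, 6), (4, 0.3, 600, 7)],
    )
    def test_matches_exhaustive_search_optimum(self, n_nodes, density, n, seed):
        """GES lands on the CPDAG of the enumeration-optimal DAG."""
        nodes = tuple("ABCD"[:n_nodes])
        truth = sample_ground_truth(nodes, edge_density=density, seed=seed)
        datasets = [_sim(truth, n, seed=seed * 10 + k) for k in range(3)]
        got = ges(datasets, c=1.0)
        want = exhaustive_best_cpdag(datasets, c=1.0)
        assert got == want

    def test_penalty_monotonicity_on_edge_count(self):
        truth = sample_ground_truth(
            ("A", "B", "C", "D", "E"), edge_density=0.4, seed=9
        )
        datasets = [_sim(truth, 200, seed=k) for k in range(4)]
        counts = [ges(datasets, c=c).n_edges for c in (1.0, 2.0, 3.0, 4.0)]
        # tolerate at most one edge of search noise in the monotone trend
        for a, b in zip(counts, counts[1:]):
            assert b <= a + 1


class TestSelectPenalty:
    def test_triangle_free_at_first_grid_value(self):
        m = GroundTruthModel(
            nodes=("X", "Y", "Z"), weights={("X", "Y"): 0.8}, ar_coefficient=0.0
        )
        datasets = [_sim(m, 400, seed=s) for s in range(3)]
        c, cp = select_penalty(datasets, ScoreConfig())
        assert c == 1.0
        assert not cp.has_triangle()

    def test_escalation_removes_spurious_triangle(self):
        """A strong chain with a weak direct path can triangulate at c=1;
        escalation must return a triangle-free skeleton."""
        m = GroundTruthModel(
            nodes=("X", "Y", "Z"),
            weights={("X", "Y"): 0.9, ("Y", "Z"): 0.9, ("X", "Z"): 0.25},
            ar_coefficient=0.0,
        )
        datasets = [_sim(m, 800, seed=100 + s) for s in range(8)]
        c, cp = select_penalty(datasets, ScoreConfig(penalty_grid=(1, 2, 3, 4, 6, 8, 12)))
        assert not cp.has_triangle()

    def test_exhausted_grid_raises_with_last_graph(self):
        # mixed-sign weights keep every partial correlation strong, so the
        # triangle survives a length-1 grid
        m = GroundTruthModel(
            nodes=("X", "Y", "Z"),
            weights={("X", "Y"): 0.8, ("Y", "Z"): 0.8, ("X", "Z"): -0.8},
            ar_coefficient=0.0,
        )
        datasets = [_sim(m, 2000, seed=s) for s in range(5)]
        with pytest.raises(NoTriangleFreeGraphError) as exc:
            select_penalty(datasets, ScoreConfig(penalty_grid=(1.0,)))
        assert exc.value.last_graph is not None
        assert exc.value.last_graph.has_triangle()
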