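import numpy as np
import pytest
from scipy import stats as sps

from emonet.design import build_task_design, default_design
from emonet.exceptions import (
    CyclicGraphError,
    EmptyGroupError,
    MissingModelError,
    StabilityError,
)
from emonet.simulate import (
    DEFAULT_ROIS,
    CohortSpec,
    GroundTruthModel,
    generate_cohort,
    sample_ground_truth,
    simulate_condition_series,
    simulate_run,
)


class TestSampleGroundTruth:
    def test_zero_density_gives_empty_edge_set(self):
        m = sample_ground_truth(DEFAULT_ROIS, edge_density=0.0, seed=0)
        assert m.edges == frozenset()

    def test_explicit_edges_pass_through(self):
        m = sample_ground_truth(
            ("A", "B", "C"), edges=[("A", "B"), ("B", "C")], seed=0
        )
        assert m.edges == {("A", "B"), ("B", "C")}

    def test_explicit_cycle_rejected(self):
        with pytest.raises(CyclicGraphError):
            sample_ground_truth(
                ("A", "B", "C"), edges=[("A", "B"), ("B", "C"), ("C", "A")], seed=0
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_sampled_edges_acyclic_and_deterministic(self, seed):
        """Acyclicity verified by topological sort (Dag construction), and
        identical edge sets on repeated calls with one seed."""
        a = sample_ground_truth(DEFAULT_ROIS, edge_density=0.25, seed=seed)
        b = sample_ground_truth(DEFAULT_ROIS, edge_density=0.25, seed=seed)
        assert a.edges == b.edges
        assert len(a.dag().topological_order()) == len(DEFAULT_ROIS)

    def test_forbid_triangles_yields_triangle_free_skeleton(self):
        from emonet.graphs import Cpdag

        for seed in range(10):
            m = sample_ground_truth(
                DEFAULT_ROIS, edge_density=0.6, seed=seed, forbid_triangles=True
            )
            cp = Cpdag(m.nodes, m.edges, frozenset())
            assert not cp.has_triangle()

    def test_weights_within_range_and_nonzero(self):
        m = sample_ground_truth(DEFAULT_ROIS, edge_density=0.5, seed=3)
        for w in m.weights.values():
            assert 0.4 <= abs(w) <= 0.8

    def test_overlarge_weight_rejected(self):
        with pytest.raises(StabilityError):
            GroundTruthModel(nodes=("A", "B"), weights={("A", "B"): 2.0})

    def test_unstable_ar_rejected(self):
        with pytest.raises(StabilityError):
            GroundTruthModel(nodes=("A", "B"), ar_coefficient=1.0)


class TestSimulateConditionSeries:
    def test_null_model_columns_uncorrelated(self):
        m = GroundTruthModel(
            nodes=("A", "B", "C"), noise_family="gaussian", ar_coefficient=0.0
        )
        s = simulate_condition_series(m, 5000, seed=0)
        corr = np.corrcoef(s.values().T)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_covariance_matches_sem_closed_form(self):
        """Sample covariance approaches (I-B)^-1 D (I-B)^-T."""
        m = GroundTruthModel(
            nodes=("A", "B", "C", "D"),
            weights={("A", "B"): 0.7, ("B", "C"): -0.5, ("A", "D"): 0.4},
            noise_family="laplace",
            ar_coefficient=0.0,
        )
        s = simulate_condition_series(m, 20000, seed=1)
        sample = np.cov(s.values().T, bias=True)
        assert np.max(np.abs(sample - m.implied_covariance())) < 0.05

    def test_fixed_seed_bit_identical(self):
        m = sample_ground_truth(DEFAULT_ROIS, seed=4)
        a = simulate_condition_series(m, 100, seed=11)
        b = simulate_condition_series(m, 100, seed=11)
        assert np.array_equal(a.values(), b.values())

    @pytest.mark.parametrize(
        "family,min_kurt,max_kurt",
        [
            ("laplace", 0.5, np.inf),
            ("squared_gaussian", 0.5, np.inf),
            ("gaussian", -0.3, 0.3),
        ],
    )
    def test_noise_family_kurtosis(self, family, min_kurt, max_kurt):
        """Non-Gaussian families show positive excess kurtosis (needed for
        direction identifiability); the Gaussian family does not."""
        m = GroundTruthModel(nodes=("A",), noise_family=family, ar_coefficient=0.0)
        s = simulate_condition_series(m, 5000, seed=2)
        k = sps.kurtosis(s.values()[:, 0])
        assert min_kurt < k < max_kurt

    def test_noise_scale_is_sd_for_every_family(self):
        for family in ("gaussian", "laplace", "squared_gaussian"):
            m = GroundTruthModel(
                nodes=("A",), noise_family=family, noise_scale=2.0, ar_coefficient=0.0
            )
            s = simulate_condition_series(m, 20000, seed=3)
            assert s.values()[:, 0].std() == pytest.approx(2.0, rel=0.1)

    def test_too_short_series_rejected(self):
        m = GroundTruthModel(nodes=("A",))
        with pytest.raises(ValueError):
            simulate_condition_series(m, 10, seed=0)


class TestSimulateRun:
    def _models(self, conditions, **kwargs):
        return {
            c: sample_ground_truth(DEFAULT_ROIS, edge_density=0.2, seed=i, **kwargs)
            for i, c in enumerate(conditions)
        }

    def test_default_design_gives_240_rows(self):
        design = default_design(seed=0)
        run = simulate_run("s1", "g", design, self._models(design.conditions), seed=0)
        assert run.series.n_timepoints == 240

    def test_minimal_block_arithmetic(self):
        design = build_task_design(2, 1, 5, 4, 0, ["only"], seed=0)
        run = simulate_run("s1", "g", design, self._models(["only"]), seed=0)
        assert run.series.n_timepoints == 10

    def test_blocks_partition_rows(self):
        design = default_design(seed=1)
        run = simulate_run("s1", "g", design, self._models(design.conditions), seed=1)
        covered = []
        for b in run.blocks:
            assert b.start <= b.stim_start < b.stop
            covered.extend(range(b.start, b.stop))
        assert covered == list(range(run.series.n_timepoints))

    def test_missing_condition_model_rejected(self):
        design = default_design(seed=0)
        models = self._models(design.conditions)
        models.pop(design.conditions[0])
        with pytest.raises(MissingModelError):
            simulate_run("s1", "g", design, models, seed=0)


class TestGenerateCohort:
    def _spec(self, group, n):
        design = default_design(seed=0)
        models = {
            c: sample_ground_truth(DEFAULT_ROIS, edge_density=0.2, seed=i)
            for i, c in enumerate(design.conditions)
        }
        return design, CohortSpec(group=group, n_subjects=n, models=models)

    def test_patient_control_cohort_size(self):
        """16 patients + 14 controls = the 30 analyzed subjects."""
        design, s1 = self._spec("GAD", 16)
        _, s2 = self._spec("HC", 14)
        runs = generate_cohort([s1, s2], design, seed=0)
        assert len(runs) == 30
        assert sum(r.group == "GAD" for r in runs) == 16

    def test_single_subject(self):
        design, s1 = self._spec("g", 1)
        assert len(generate_cohort([s1], design, seed=0)) == 1

    def test_master_seed_determinism(self):
        design, s1 = self._spec("g", 3)
        a = generate_cohort([s1], design, seed=5)
        b = generate_cohort([s1], design, seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.series.values(), rb.series.values())

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroupError):
            self._spec("g", 0)
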