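import numpy as np
import pytest

from specdelim import (
    ClusteringParams,
    DistanceMatrix,
    FRecord,
    GridSpec,
    OptimizationResult,
    Partition,
    apply_global_best,
    f_linkage_cluster,
    grid_optimize,
    median_of_grid,
    mri,
    results_table,
    select_concept,
)
from specdelim.errors import ClusteringError

from conftest import random_distance_matrix, random_partition

COARSE = GridSpec(t_step=0.02, f_values=(0.0, 0.25, 0.5, 0.75, 1.0))


class TestMedianOfGrid:
    @pytest.mark.parametrize(
        "values,expect",
        [
            ([0.01], 0.01),
            ([0.01, 0.02, 0.03], 0.02),
            ([0.01, 0.02, 0.03, 0.04], 0.025),
        ],
    )
    def test_examples(self, values, expect):
        assert median_of_grid(values) == pytest.approx(expect)

    def test_empty_rejected(self):
        with pytest.raises(ClusteringError):
            median_of_grid([])


class TestGridSpec:
    def test_t_values_are_exact_step_multiples(self):
        g = GridSpec(t_step=0.0001)
        assert g.i_max == 10000
        assert g.t_of(263) == pytest.approx(0.0263)

    def test_bad_specs_rejected(self):
        with pytest.raises(ClusteringError):
            GridSpec(t_step=0.0)
        with pytest.raises(ClusteringError):
            GridSpec(f_values=())
        with pytest.raises(ClusteringError):
            GridSpec(t_min=0.00015, t_step=0.0001)


class TestGridOptimize:
    def test_singleton_reference_perfect_below_min_distance(self, rng):
        m = random_distance_matrix(rng, 6, scale=0.9)
        ref = Partition({l: l for l in m.labels})  # all singletons
        res = grid_optimize(m, ref, COARSE)
        assert res.global_best_mri == 1.0
        rec0 = res.record_for(0.0)
        assert rec0.best_mri == 1.0
        assert 0.0 in rec0.best_t_values  # T below every distance

    def test_clean_blocks_perfect_for_every_f(self, two_block_matrix):
        m, ref = two_block_matrix
        grid = GridSpec(t_step=0.01, f_values=(0.0, 0.5, 1.0))
        res = grid_optimize(m, ref, grid)
        max_within = 0.010
        min_between = 0.220
        for rec in res.f_records:
            assert rec.best_mri == 1.0
            # every grid T strictly inside the separation gap attains the best
            inside = [
                grid.t_of(i)
                for i in range(grid.i_min, grid.i_max + 1)
                if max_within < grid.t_of(i) < min_between
            ]
            assert set(inside) <= set(rec.best_t_values)

    @pytest.mark.parametrize("seed", range(5))
    def test_interval_cache_equals_naive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        m = random_distance_matrix(rng, n)
        ref = random_partition(rng, n, 3)
        a = grid_optimize(m, ref, COARSE, method="interval")
        b = grid_optimize(m, ref, COARSE, method="naive")
        for ra, rb in zip(a.f_records, b.f_records):
            assert ra.best_mri == rb.best_mri  # bit-identical
            assert ra.best_t_values == rb.best_t_values

    def test_variant_recorded_and_used(self, two_block_matrix):
        m, ref = two_block_matrix
        res = grid_optimize(m, ref, COARSE, variant="ari")
        assert res.variant == "ari"
        assert res.global_best_mri == 1.0

    def test_reference_ids_must_be_in_matrix(self, two_block_matrix):
        m, _ = two_block_matrix
        ref = Partition({"zz": "A", "a": "A", "b": "B"})
        with pytest.raises(ClusteringError):
            grid_optimize(m, ref, COARSE)

    def test_reclustering_at_chosen_params_reproduces_best(self, two_block_matrix):
        m, ref = two_block_matrix
        res = grid_optimize(m, ref, GridSpec(t_step=0.005))
        part = f_linkage_cluster(m, res.chosen_params())
        assert mri(part, ref, res.variant) == res.global_best_mri

    def test_finer_grid_never_lowers_per_f_best(self, rng):
        m = random_distance_matrix(rng, 8)
        ref = random_partition(rng, 8, 3)
        coarse = grid_optimize(m, ref, GridSpec(t_step=0.05, f_values=(0.0, 0.5, 1.0)))
        fine = grid_optimize(m, ref, GridSpec(t_step=0.01, f_values=(0.0, 0.5, 1.0)))
        for rc, rf in zip(coarse.f_records, fine.f_records):
            assert rf.best_mri >= rc.best_mri

    def test_median_in_best_t_closed_range(self, rng):
        m = random_distance_matrix(rng, 9)
        ref = random_partition(rng, 9, 4)
        res = grid_optimize(m, ref, COARSE)
        for rec in res.f_records:
            assert min(rec.best_t_values) <= rec.median_best_t <= max(rec.best_t_values)

    def test_global_best_is_max_over_f_records(self, rng):
        m = random_distance_matrix(rng, 7)
        ref = random_partition(rng, 7, 3)
        res = grid_optimize(m, ref, COARSE)
        assert res.global_best_mri == max(r.best_mri for r in res.f_records)


def _result(name, n_blocks, per_f):
    return OptimizationResult(
        reference_name=name,
        variant="mri",
        n_reference_blocks=n_blocks,
        f_records=[FRecord(f=f, best_mri=v, best_t_values=(t,)) for f, v, t in per_f],
    )


class TestSelectConcept:
    def test_largest_global_best_wins(self):
        results = [
            _result("key1", 12, [(0.0, 0.642, 0.012)]),
            _result("key2", 8, [(0.0, 0.814, 0.022)]),
            _result("key3", 24, [(0.0, 0.523, 0.001)]),
        ]
        assert select_concept(results).reference_name == "key2"

    def test_single_result_wins(self):
        res = _result("only", 5, [(0.0, 0.5, 0.01)])
        assert select_concept([res]) is res

    def test_tied_f_values_pick_lower_middle(self):
        per_f = [(round(0.05 * k, 2), 0.7, 0.01) for k in range(21)]
        per_f = [
            (f, 0.862 if 0.65 <= f <= 0.90 else 0.7, 0.02 + f / 100) for f, _, _ in per_f
        ]
        res = _result("full", 8, per_f)
        assert res.tied_f_values == [0.65, 0.70, 0.75, 0.80, 0.85, 0.90]
        assert res.chosen_f == 0.75

    def test_mri_tie_broken_toward_fewer_species_then_name(self):
        a = _result("broad", 5, [(0.0, 0.8, 0.01)])
        b = _result("narrow", 9, [(0.0, 0.8, 0.01)])
        assert select_concept([a, b]).reference_name == "broad"
        c = _result("alpha", 5, [(0.0, 0.8, 0.01)])
        assert select_concept([a, c]).reference_name == "alpha"

    def test_empty_rejected(self):
        with pytest.raises(ClusteringError):
            select_concept([])


class TestApplyGlobalBest:
    def test_two_block_matrix_two_clusters(self, two_block_matrix):
        m, _ = two_block_matrix
        part = apply_global_best(m, ClusteringParams(T=0.05, F=0.75))
        assert part.n_blocks() == 2
        assert part.assignment["a"] == "0"  # numbered by smallest member

    def test_t_zero_gives_singletons(self, rng):
        m = random_distance_matrix(rng, 6)
        part = apply_global_best(m, ClusteringParams(T=0.0, F=0.75))
        assert part.n_blocks() == 6


class TestResultsTable:
    def test_layout_one_row_per_f(self, two_block_matrix):
        m, ref = two_block_matrix
        res = grid_optimize(m, ref, COARSE, reference_name="truth")
        df = results_table([res])
        assert list(df.columns) == ["F", "truth_highest_mri", "truth_median_best_t"]
        assert len(df) == len(COARSE.f_values)
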