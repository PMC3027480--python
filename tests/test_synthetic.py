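import numpy as np
import pytest

from specdelim import (
    SyntheticSpec,
    block_distance_matrix,
    p_distance_matrix,
    perturb_reference,
    simulate_species_complex,
    simulate_spore_measurements,
)
from specdelim.errors import SpecDelimError


def within_between(matrix, truth):
    pos = {l: i for i, l in enumerate(matrix.labels)}
    within, between = [], []
    labels = matrix.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            same = truth.assignment[labels[i]] == truth.assignment[labels[j]]
            (within if same else between).append(matrix.values[pos[labels[i]], pos[labels[j]]])
    return np.array(within), np.array(between)


class TestSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(SpecDelimError):
            SyntheticSpec(n_species=0)
        with pytest.raises(SpecDelimError):
            SyntheticSpec(r_in=0.1, r_out=0.05)
        with pytest.raises(SpecDelimError):
            SyntheticSpec(p_mis=1.5)

    def test_manifest_records_all_parameters(self):
        text = SyntheticSpec(seed=7).manifest()
        for key in ("n_species", "length", "r_in", "r_out", "seed=7"):
            assert key in text


class TestSimulate:
    def test_rin_zero_makes_species_members_identical(self):
        spec = SyntheticSpec(r_in=0.0, r_out=0.05, seed=1)
        aln, truth = simulate_species_complex(spec)
        m = p_distance_matrix(aln)
        w, _ = within_between(m, truth)
        assert np.all(w == 0.0)

    def test_single_species_single_block(self):
        aln, truth = simulate_species_complex(SyntheticSpec(n_species=1, seed=2))
        assert truth.n_blocks() == 1
        assert len(aln) == 6

    def test_deterministic_under_seed(self):
        a1, _ = simulate_species_complex(SyntheticSpec(seed=5))
        a2, _ = simulate_species_complex(SyntheticSpec(seed=5))
        a3, _ = simulate_species_complex(SyntheticSpec(seed=6))
        assert a1.rows == a2.rows
        assert a1.rows != a3.rows

    def test_within_distance_matches_closed_form(self):
        # mean within-species p-distance over replicates vs the two-step
        # mutation expectation, within 3 Monte-Carlo standard errors
        spec0 = SyntheticSpec()
        means = []
        for seed in range(30):
            aln, truth = simulate_species_complex(SyntheticSpec(seed=seed))
            w, _ = within_between(p_distance_matrix(aln), truth)
            means.append(w.mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - spec0.expected_within_p()) <= 3 * se + 1e-12

    def test_species_separated_from_each_other(self):
        aln, truth = simulate_species_complex(SyntheticSpec(seed=3))
        w, b = within_between(p_distance_matrix(aln), truth)
        assert w.max() < b.min()


class TestPerturb:
    @pytest.fixture
    def truth(self):
        _, t = simulate_species_complex(SyntheticSpec(seed=11))
        return t

    def test_zero_rates_identity(self, truth):
        ref = perturb_reference(truth, seed=4)
        assert ref.assignment == truth.assignment

    def test_split_all_doubles_block_count(self, truth):
        ref = perturb_reference(truth, p_split=1.0, seed=4)
        assert ref.n_blocks() == 2 * truth.n_blocks()

    def test_lump_all_halves_block_count(self, truth):
        ref = perturb_reference(truth, p_lump=1.0, seed=4)
        # 5 species -> 2 merged pairs + 1 leftover = 3 blocks
        assert ref.n_blocks() == 3

    def test_misassignment_rate_within_binomial_ci(self):
        truth_labels = {f"s{i:03d}": f"g{i % 5}" for i in range(100)}
        from specdelim import Partition

        truth = Partition(truth_labels)
        moved = 0
        total = 0
        for seed in range(500):
            ref = perturb_reference(truth, p_mis=0.1, seed=seed)
            moved += sum(ref.assignment[i] != truth.assignment[i] for i in truth_labels)
            total += len(truth_labels)
        p_hat = moved / total
        # 99% binomial CI around 0.1 for 50,000 draws
        half = 2.576 * np.sqrt(0.1 * 0.9 / total)
        assert abs(p_hat - 0.1) <= half

    def test_deterministic_under_seed(self, truth):
        r1 = perturb_reference(truth, p_split=0.5, p_mis=0.1, seed=9)
        r2 = perturb_reference(truth, p_split=0.5, p_mis=0.1, seed=9)
        assert r1.assignment == r2.assignment


class TestBlockMatrix:
    def test_structure_and_truth(self):
        m, truth = block_distance_matrix(n_species=3, species_sizes=4, seed=0)
        assert len(m) == 12
        w, b = within_between(m, truth)
        assert w.max() < b.min()

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(SpecDelimError):
            block_distance_matrix(within=(0, 0.1), between=(0.05, 0.2))


class TestSporeMeasurements:
    def test_grouped_by_specimen_and_positive(self):
        _, truth = simulate_species_complex(SyntheticSpec(seed=12))
        table = simulate_spore_measurements(truth, n_spores=5, seed=12)
        assert set(table.ids) == set(truth.ids)
        frame = table.to_frame()
        assert (frame[["length", "width"]] > 0).all().all()
        assert frame.groupby("specimen").size().eq(5).all()
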