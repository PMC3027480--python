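import numpy as np
import pytest

from specdelim import (
    ExclusionMask,
    MultipleAlignment,
    apply_mask,
    auto_edge_mask,
    p_distance_matrix,
)
from specdelim.errors import AlignmentError, MaskError, MatrixError


class TestMask:
    def test_empty_mask_is_identity(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "AC-T"])
        out = apply_mask(aln, ExclusionMask(()))
        assert out.rows == aln.rows

    def test_all_columns_masked_rejected(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(AlignmentError):
            apply_mask(aln, ExclusionMask((0, 1, 2, 3)))

    def test_column_count_arithmetic(self):
        # 10 columns minus a 4-column mask leaves 6
        aln = MultipleAlignment(["a"], ["ACGTACGTAC"])
        out = apply_mask(aln, ExclusionMask((0, 1, 8, 9)))
        assert out.length == 6
        assert out.rows == ["GTACGT"]

    def test_out_of_range_rejected(self):
        aln = MultipleAlignment(["a"], ["ACGT"])
        with pytest.raises(MaskError):
            apply_mask(aln, ExclusionMask((7,)))

    def test_duplicate_indices_rejected(self):
        with pytest.raises(MaskError):
            ExclusionMask((1, 1))

    def test_one_based_range_converter(self):
        mask = ExclusionMask.from_one_based_ranges([(1, 3), (10, 10)])
        assert mask.excluded == (0, 1, 2, 9)


class TestAutoEdgeMask:
    def test_no_gaps_gives_empty_mask(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "TGCA"])
        assert len(auto_edge_mask(aln, 0.5)) == 0

    def test_leading_gap_run(self):
        # one of two sequences padded with 4 leading gaps: those columns have
        # non-gap fraction 0.5, below a threshold of 0.6
        aln = MultipleAlignment(["a", "b"], ["----ACGTACGT", "ACGTACGTACGT"])
        mask = auto_edge_mask(aln, 0.6)
        assert mask.excluded == (0, 1, 2, 3)

    def test_interior_gap_column_never_masked(self):
        aln = MultipleAlignment(["a", "b"], ["AC--GT", "AC--GT"])
        assert len(auto_edge_mask(aln, 0.9)) == 0

    def test_trailing_run_and_threshold(self):
        rows = ["AAAA--", "AAAA--", "AAAAA-", "AAAAAA"]
        aln = MultipleAlignment(["a", "b", "c", "d"], rows)
        # col 4: 3/4 non-gap; col 5: 1/4 non-gap
        assert auto_edge_mask(aln, 0.5).excluded == (5,)
        assert auto_edge_mask(aln, 0.8).excluded == (4, 5)


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "ACGT"])
        m = p_distance_matrix(aln)
        assert m.values[0, 1] == 0.0

    def test_fully_different_rows_one(self):
        aln = MultipleAlignment(["a", "b"], ["AAAA", "TTTT"])
        assert p_distance_matrix(aln).values[0, 1] == 1.0

    def test_pairwise_deletion_hand_count(self):
        # gap column dropped: 5 compared sites, 1 mismatch -> 0.2
        aln = MultipleAlignment(["a", "b"], ["ACGT-A", "ACGAAA"])
        assert p_distance_matrix(aln).values[0, 1] == pytest.approx(0.2)

    def test_ambiguity_codes_treated_as_missing(self):
        aln = MultipleAlignment(["a", "b"], ["ACGTN", "ACGAR"])
        # cols 0-2 match, col 3 mismatch, col 4 missing both ways -> 1/4
        assert p_distance_matrix(aln).values[0, 1] == pytest.approx(0.25)

    def test_drop_ids_is_explicit(self):
        aln = MultipleAlignment(["a", "b", "c"], ["ACGT", "ACGA", "ACGG"])
        m = p_distance_matrix(aln, drop_ids=["c"])
        assert m.labels == ["a", "b"]

    def test_no_overlap_errors_by_default(self):
        aln = MultipleAlignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(MatrixError):
            p_distance_matrix(aln)
        with pytest.warns(UserWarning):
            m = p_distance_matrix(aln, on_no_overlap="impute")
        assert m.values[0, 1] == 1.0

    def test_row_permutation_permutes_matrix(self, rng):
        n, L = 6, 40
        rows = ["".join(rng.choice(list("ACGT-"), L)) for _ in range(n)]
        ids = [f"s{i}" for i in range(n)]
        m = p_distance_matrix(MultipleAlignment(ids, rows))
        perm = rng.permutation(n)
        m2 = p_distance_matrix(
            MultipleAlignment([ids[i] for i in perm], [rows[i] for i in perm])
        )
        np.testing.assert_array_equal(
            m2.values, m.submatrix([ids[i] for i in perm]).values
        )

    def test_masking_constant_columns_leaves_matrix_unchanged(self, rng):
        n, L = 5, 30
        rows = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
        const = "A" * n  # a column identical across rows
        rows_aug = [r[:10] + const[i] + r[10:] for i, r in enumerate(rows)]
        # inserting a constant column shifts mismatch fraction; masking it back
        # must restore the original matrix exactly
        aln_aug = MultipleAlignment([f"s{i}" for i in range(n)], rows_aug)
        masked = apply_mask(aln_aug, ExclusionMask((10,)))
        m0 = p_distance_matrix(
            MultipleAlignment([f"s{i}" for i in range(n)], rows)
        )
        np.testing.assert_array_equal(p_distance_matrix(masked).values, m0.values)

    def test_symmetry_zero_diag_range(self, rng):
        rows = ["".join(rng.choice(list("ACGT-N"), 50)) for _ in range(8)]
        m = p_distance_matrix(
            MultipleAlignment([f"s{i}" for i in range(8)], rows),
            on_no_overlap="impute",
        )
        np.testing.assert_array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert np.all((m.values >= 0) & (m.values <= 1))
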