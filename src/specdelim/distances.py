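"""Column masking and uncorrected p-distances.

The p-distance between two aligned sequences is the fraction of mismatching
sites among the pairwise-comparable columns — columns where *both* rows carry
a determinate, unambiguous base (A, C, G or T). Gaps, ``?``, ``N`` and IUPAC
ambiguity codes are deleted pairwise, not across the whole alignment, which
preserves signal on ragged alignments. Ambiguity codes are treated as missing
rather than as partial matches — the simplest reading of an "uncorrected"
distance.

Edge masking reconstructs the common practice of excluding alignment columns
that mainly contain leading or trailing gaps before distance calculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, MaskError, MatrixError
from .io_formats import DistanceMatrix, MultipleAlignment

_GAP_CHARS = set("-?")


@dataclass(frozen=True)
class ExclusionMask:
    """A set of 0-based column indices to exclude from an alignment."""

    excluded: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.excluded)) != len(self.excluded):
            raise MaskError("mask contains duplicate column indices")
        if any(i < 0 for i in self.excluded):
            raise MaskError("mask contains negative column indices")
        object.__setattr__(self, "excluded", tuple(sorted(self.excluded)))

    def __len__(self) -> int:
        return len(self.excluded)

    @classmethod
    def from_one_based_ranges(cls, ranges: list[tuple[int, int]]) -> "ExclusionMask":
        """Build from 1-based inclusive ranges, the form used in prose.

        ``[(1, 10)]`` excludes the first ten columns (0-based 0..9).
        """
        cols: set[int] = set()
        for lo, hi in ranges:
            if lo < 1 or hi < lo:
                raise MaskError(f"invalid 1-based range ({lo}, {hi})")
            cols.update(range(lo - 1, hi))
        return cls(tuple(cols))


def apply_mask(aln: MultipleAlignment, mask: ExclusionMask) -> MultipleAlignment:
    """Drop the masked columns; row order is unchanged."""
    if mask.excluded and mask.excluded[-1] >= aln.length:
        raise MaskError(
            f"mask index {mask.excluded[-1]} out of range for {aln.length} columns"
        )
    if len(mask) == aln.length:
        raise AlignmentError("mask excludes every column; zero-length alignment")
    if not mask.excluded:
        return MultipleAlignment(list(aln.ids), list(aln.rows))
    keep = np.setdiff1d(np.arange(aln.length), np.array(mask.excluded))
    rows = ["".join(r[i] for i in keep) for r in aln.rows]
    return MultipleAlignment(list(aln.ids), rows)


def auto_edge_mask(
    aln: MultipleAlignment, min_nongap_fraction: float = 0.5
) -> ExclusionMask:
    """Columns failing the non-gap threshold within runs touching either edge.

    A column is a candidate when its fraction of non-gap characters is below
    ``min_nongap_fraction``. Only the maximal candidate runs starting at the
    first column or ending at the last column are masked; interior gappy
    columns are never excluded.
    """
    if not 0 < min_nongap_fraction <= 1:
        raise MaskError("min_nongap_fraction must be in (0, 1]")
    arr = np.array([[c in _GAP_CHARS for c in row] for row in aln.rows])
    nongap_frac = 1.0 - arr.mean(axis=0)
    candidate = nongap_frac < min_nongap_fraction
    cols: list[int] = []
    i = 0
    while i < aln.length and candidate[i]:
        cols.append(i)
        i += 1
    j = aln.length - 1
    while j > i and candidate[j]:
        cols.append(j)
        j -= 1
    return ExclusionMask(tuple(cols))


def p_distance_matrix(
    aln: MultipleAlignment,
    drop_ids: list[str] | set[str] | None = None,
    on_no_overlap: str = "error",
) -> DistanceMatrix:
    """Pairwise uncorrected p-distances with pairwise deletion.

    ``drop_ids`` removes sequences (e.g. short reads excluded from the
    distance calculation) before computing; it is always explicit, never
    inferred. A pair with zero comparable sites raises :class:`MatrixError`
    unless ``on_no_overlap="impute"``, which records 1.0 with a warning.
    """
    if on_no_overlap not in ("error", "impute"):
        raise ValueError("on_no_overlap must be 'error' or 'impute'")
    if drop_ids:
        aln = aln.drop(drop_ids)
    n = len(aln)
    if n < 2:
        raise AlignmentError("need at least 2 sequences after dropping")
    codes = aln.to_codes()
    valid = codes != 255
    d = np.zeros((n, n))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        compared = both.sum(axis=1)
        mism = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        empty = compared == 0
        if np.any(empty):
            culprits = [aln.ids[i + 1 + k] for k in np.flatnonzero(empty)]
            if on_no_overlap == "error":
                raise MatrixError(
                    f"no comparable sites between {aln.ids[i]!r} and {culprits}"
                )
            warnings.warn(
                f"no comparable sites between {aln.ids[i]!r} and {culprits}; "
                "imputing distance 1.0"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(empty, 1.0, mism / np.maximum(compared, 1))
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(list(aln.ids), d)
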