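"""(T, F) grid optimization of F-linkage clustering against reference partitions.

For each link fraction F on a coarse grid (default 0.00..1.00, step 0.05) the
distance threshold T is swept over a fine grid (default 0.0..1.0, step
0.0001); at every grid point the matrix is clustered and scored against a
reference partition with a Rand-type index. Per F the highest score, the set
of grid T values attaining it and their median are recorded — the machine
form of a clustering-optimization results table. The reference achieving the
largest global score wins concept selection, and its parameters are applied
to the complete data set.

The T sweep exploits that the clustering only depends on T through the link
set {(i,j): d_ij <= T}, which is constant between consecutive distinct matrix
values: each such interval is clustered once and its score assigned to every
grid T inside it, bit-identically to naive per-T evaluation (verified in the
test suite against the naive path, which is retained as ``method="naive"``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import VARIANTS, mri
from .clustering import ClusteringParams, cluster_link_matrix, f_linkage_cluster
from .errors import ClusteringError
from .io_formats import DistanceMatrix, Partition

__all__ = [
    "GridSpec",
    "FRecord",
    "OptimizationResult",
    "grid_optimize",
    "median_of_grid",
    "select_concept",
    "apply_global_best",
    "results_table",
]

_F_DEFAULT = tuple(np.round(np.arange(0, 21) * 0.05, 2))


@dataclass(frozen=True)
class GridSpec:
    """The (T, F) search grid.

    T values are exact integer multiples of ``t_step`` (accumulated as
    integer indices, never by repeated float addition), endpoints inclusive.
    """

    t_min: float = 0.0
    t_max: float = 1.0
    t_step: float = 0.0001
    f_values: tuple[float, ...] = _F_DEFAULT

    def __post_init__(self) -> None:
        if self.t_step <= 0:
            raise ClusteringError("t_step must be positive")
        if not self.f_values:
            raise ClusteringError("empty F grid")
        if self.t_max < self.t_min:
            raise ClusteringError("t_max < t_min")
        for f in self.f_values:
            if not 0.0 <= f <= 1.0:
                raise ClusteringError(f"F value {f} outside [0, 1]")
        for name, v in (("t_min", self.t_min), ("t_max", self.t_max)):
            if abs(round(v / self.t_step) * self.t_step - v) > 1e-9:
                raise ClusteringError(f"{name} is not a multiple of t_step")

    @property
    def i_min(self) -> int:
        return round(self.t_min / self.t_step)

    @property
    def i_max(self) -> int:
        return round(self.t_max / self.t_step)

    def t_of(self, i: int) -> float:
        return i * self.t_step

    def grid_boundary(self, v: float) -> int:
        """Smallest grid index i with v <= i * t_step, float-exactly.

        Float-exact means: consistent with evaluating ``v <= i * t_step`` in
        double precision for every grid i, so interval-cached sweeps agree
        bit-for-bit with naive ones.
        """
        i = math.ceil(v / self.t_step)
        while i > 0 and v <= (i - 1) * self.t_step:
            i -= 1
        while v > i * self.t_step:
            i += 1
        return i


@dataclass(frozen=True)
class FRecord:
    """Per-F summary: the highest score and the grid T values attaining it."""

    f: float
    best_mri: float
    best_t_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.best_t_values:
            raise ClusteringError("empty best-T set")

    @property
    def median_best_t(self) -> float:
        return median_of_grid(list(self.best_t_values))


@dataclass
class OptimizationResult:
    """Grid-optimization outcome for one reference partition."""

    reference_name: str
    variant: str
    n_reference_blocks: int
    f_records: list[FRecord]

    @property
    def global_best_mri(self) -> float:
        return max(r.best_mri for r in self.f_records)

    @property
    def tied_f_values(self) -> list[float]:
        """F values whose per-F best attains the global best."""
        g = self.global_best_mri
        return [r.f for r in self.f_records if abs(r.best_mri - g) <= 1e-12]

    @property
    def chosen_f(self) -> float:
        """Lower-middle of the tied F values (a documented convention)."""
        tied = self.tied_f_values
        return tied[(len(tied) - 1) // 2]

    @property
    def chosen_t(self) -> float:
        f = self.chosen_f
        rec = next(r for r in self.f_records if r.f == f)
        return rec.median_best_t

    def chosen_params(self) -> ClusteringParams:
        return ClusteringParams(T=self.chosen_t, F=self.chosen_f)

    def record_for(self, f: float) -> FRecord:
        for r in self.f_records:
            if abs(r.f - f) <= 1e-12:
                return r
        raise KeyError(f"no record for F={f}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference": self.reference_name,
            "variant": self.variant,
            "n_reference_blocks": self.n_reference_blocks,
            "global_best_mri": self.global_best_mri,
            "chosen_f": self.chosen_f,
            "chosen_t": self.chosen_t,
            "per_f": [
                {
                    "f": r.f,
                    "best_mri": r.best_mri,
                    "median_best_t": r.median_best_t,
                    "n_best_t": len(r.best_t_values),
                }
                for r in self.f_records
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def median_of_grid(values: list[float]) -> float:
    """Median of ascending grid values; even count -> mean of the middles."""
    if len(values) == 0:
        raise ClusteringError("median of empty grid-value set")
    vals = sorted(values)
    n = len(vals)
    if n % 2 == 1:
        return vals[n // 2]
    return (vals[n // 2 - 1] + vals[n // 2]) / 2.0


def _score_segments(matrix, reference, grid, variant, segments):
    """Cluster once per (segment, F) and spread scores over the grid."""
    n_grid = grid.i_max - grid.i_min + 1
    scores = {f: np.empty(n_grid) for f in grid.f_values}
    memo: dict[tuple[str, ...], float] = {}
    for i_lo, i_hi, link in segments:
        sl = slice(i_lo - grid.i_min, i_hi - grid.i_min + 1)
        for f in grid.f_values:
            part = cluster_link_matrix(matrix, link, f)
            key = tuple(part.assignment[l] for l in matrix.labels)
            if key not in memo:
                memo[key] = mri(part, reference, variant)
            scores[f][sl] = memo[key]
    return scores


def _segments_interval(matrix: DistanceMatrix, grid: GridSpec):
    """Maximal grid-index runs with a constant link set."""
    d = matrix.values
    vals = np.unique(matrix.offdiag())
    boundaries = sorted({grid.grid_boundary(v) for v in vals})
    cuts = [b for b in boundaries if grid.i_min < b <= grid.i_max]
    starts = [grid.i_min] + cuts
    ends = [c - 1 for c in cuts] + [grid.i_max]
    for lo, hi in zip(starts, ends):
        link = (d <= grid.t_of(lo)).astype(np.float64)
        np.fill_diagonal(link, 0.0)
        yield lo, hi, link


def _segments_naive(matrix: DistanceMatrix, grid: GridSpec):
    """One segment per grid T (the reference path for the cache)."""
    d = matrix.values
    for i in range(grid.i_min, grid.i_max + 1):
        link = (d <= grid.t_of(i)).astype(np.float64)
        np.fill_diagonal(link, 0.0)
        yield i, i, link


def grid_optimize(
    matrix: DistanceMatrix,
    reference: Partition,
    grid: GridSpec | None = None,
    variant: str = "mri",
    method: str = "interval",
    reference_name: str = "reference",
) -> OptimizationResult:
    """Optimize (T, F) for one reference partition over the full grid.

    The matrix must cover the reference's assigned IDs (drop lists are
    applied upstream); clustering runs on all matrix objects while scoring
    is restricted to the shared assigned IDs.
    """
    grid = grid or GridSpec()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if method not in ("interval", "naive"):
        raise ValueError("method must be 'interval' or 'naive'")
    assigned = set(reference.assigned_ids())
    missing = assigned - set(matrix.labels)
    if missing:
        raise ClusteringError(
            f"reference IDs missing from matrix: {sorted(missing)[:5]}..."
            if len(missing) > 5
            else f"reference IDs missing from matrix: {sorted(missing)}"
        )
    if len(assigned & set(matrix.labels)) < 2:
        raise ClusteringError("reference has fewer than 2 assigned shared objects")
    segments = (
        _segments_interval(matrix, grid)
        if method == "interval"
        else _segments_naive(matrix, grid)
    )
    scores = _score_segments(matrix, reference, grid, variant, segments)
    records = []
    for f in grid.f_values:
        s = scores[f]
        best = s.max()
        idx = np.flatnonzero(s == best) + grid.i_min
        records.append(
            FRecord(
                f=float(f),
                best_mri=float(best),
                best_t_values=tuple(grid.t_of(int(i)) for i in idx),
            )
        )
    return OptimizationResult(
        reference_name=reference_name,
        variant=variant,
        n_reference_blocks=reference.n_blocks(),
        f_records=records,
    )


def select_concept(results: list[OptimizationResult]) -> OptimizationResult:
    """Pick the reference (species concept) with the largest global best score.

    Ties go to the reference with fewer species (the broader concept), then
    to name order. The winner's chosen (F, T) follow the lower-middle-of-ties
    convention implemented on :class:`OptimizationResult`.
    """
    if not results:
        raise ClusteringError("select_concept needs at least one result")
    return min(
        results,
        key=lambda r: (-r.global_best_mri, r.n_reference_blocks, r.reference_name),
    )


def apply_global_best(
    full_matrix: DistanceMatrix, params: ClusteringParams
) -> Partition:
    """Cluster the complete matrix at the selected parameters.

    Clusters are numbered 0..k-1 by order of their lexicographically smallest
    member; the numbers are arbitrary identifiers implying no relatedness.
    """
    return f_linkage_cluster(full_matrix, params)


def results_table(results: list[OptimizationResult]) -> pd.DataFrame:
    """Per-F table across references: (highest score, median best T) columns."""
    if not results:
        raise ClusteringError("no results to tabulate")
    f_values = [r.f for r in results[0].f_records]
    data: dict[str, list[float]] = {"F": [round(f, 2) for f in f_values]}
    for res in results:
        data[f"{res.reference_name}_highest_mri"] = [
            round(rec.best_mri, 5) for rec in res.f_records
        ]
        data[f"{res.reference_name}_median_best_t"] = [
            round(rec.median_best_t, 5) for rec in res.f_records
        ]
    return pd.DataFrame(data)
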