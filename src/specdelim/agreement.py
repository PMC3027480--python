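"""Partition agreement via Rand-type indices.

Two partitions are compared over the intersection of their assigned
(non-UNASSIGNED) specimen IDs: every specimen pair is either co-clustered in
both partitions (n11), separated in both (n00), or co-clustered in exactly
one (n10, n01). The default agreement score is the modified Rand index

    MRI = 2 * RI - 1,        RI = (n11 + n00) / C(n, 2)

the linear transform of the plain Rand index whose range is exactly
[-1, 1]: 1 means full agreement and random partitions score about 0. The
Hubert-Arabie adjusted Rand index ("ari") is provided as an alternative
chance-corrected variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ClusteringError
from .io_formats import Partition

VARIANTS = ("mri", "ari")


@dataclass(frozen=True)
class PairCounts:
    """Pair-level contingency between two partitions over shared objects."""

    n11: int
    n00: int
    n10: int
    n01: int

    @property
    def total(self) -> int:
        return self.n11 + self.n00 + self.n10 + self.n01


def shared_assigned_ids(P: Partition, Q: Partition) -> list[str]:
    """IDs assigned (non-UNASSIGNED) in both partitions, sorted."""
    return sorted(set(P.assigned_ids()) & set(Q.assigned_ids()))


def pair_counts(P: Partition, Q: Partition) -> PairCounts:
    """Count specimen pairs by co-clustering status in P and Q.

    Computed from the label contingency table in O(n + |blocks P| * |blocks Q|);
    the O(n^2) pair enumeration is kept as an independent oracle in the tests.
    """
    ids = shared_assigned_ids(P, Q)
    n = len(ids)
    if n < 2:
        raise ClusteringError(
            f"need at least 2 shared assigned objects, got {n}"
        )
    p_labs = [P.assignment[i] for i in ids]
    q_labs = [Q.assignment[i] for i in ids]
    p_codes = {l: k for k, l in enumerate(dict.fromkeys(p_labs))}
    q_codes = {l: k for k, l in enumerate(dict.fromkeys(q_labs))}
    table = np.zeros((len(p_codes), len(q_codes)), dtype=np.int64)
    for pl, ql in zip(p_labs, q_labs):
        table[p_codes[pl], q_codes[ql]] += 1

    def comb2(x: np.ndarray) -> int:
        return int((x * (x - 1) // 2).sum())

    total = n * (n - 1) // 2
    n11 = comb2(table)
    n10 = comb2(table.sum(axis=1)) - n11  # together in P only
    n01 = comb2(table.sum(axis=0)) - n11  # together in Q only
    n00 = total - n11 - n10 - n01
    return PairCounts(n11=n11, n00=n00, n10=n10, n01=n01)


def mri(P: Partition, Q: Partition, variant: str = "mri") -> float:
    """Agreement between two partitions.

    variant="mri": 2*RI - 1 on [-1, 1] (default).
    variant="ari": Hubert-Arabie adjusted Rand index.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    pc = pair_counts(P, Q)
    if variant == "mri":
        return 2.0 * (pc.n11 + pc.n00) / pc.total - 1.0
    # Hubert-Arabie ARI from the pair counts
    num = 2.0 * (pc.n11 * pc.n00 - pc.n10 * pc.n01)
    den = (pc.n11 + pc.n10) * (pc.n10 + pc.n00) + (pc.n11 + pc.n01) * (
        pc.n01 + pc.n00
    )
    if den == 0:  # both partitions all-singletons or single-block: identical
        return 1.0
    return num / den
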