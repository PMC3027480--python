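"""Spore-morphometric summaries and UPGMA dendrograms.

Spore length/width pairs (µm) are averaged per specimen; the per-spore
length/width quotient is summarized as min/mean/max. Specimen means are then
clustered by unweighted average linkage (UPGMA) on euclidean distances in the
(mean length, mean width) plane — no standardization, so branch lengths stay
in µm. The dendrogram is exported as an ultrametric Newick tree with merge
heights halved into branch lengths.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .errors import FormatError
from .io_formats import MorphoTable

__all__ = ["specimen_spore_summary", "upgma_dendrogram"]


def specimen_spore_summary(table: MorphoTable) -> pd.DataFrame:
    """Per-specimen means and length/width quotient summary.

    The quotient is computed per spore, then aggregated; specimens without
    measurements are excluded with a warning.
    """
    rows = []
    for sid, ms in table.measurements.items():
        if not ms:
            warnings.warn(f"specimen {sid!r} has no measurements; excluded")
            continue
        arr = np.asarray(ms, dtype=float)
        q = arr[:, 0] / arr[:, 1]
        rows.append(
            (
                sid,
                len(ms),
                arr[:, 0].mean(),
                arr[:, 1].mean(),
                q.min(),
                q.mean(),
                q.max(),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "specimen",
            "n_spores",
            "mean_length",
            "mean_width",
            "quotient_min",
            "quotient_mean",
            "quotient_max",
        ],
    ).set_index("specimen")


def _newick_from_linkage(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    nodes: dict[int, tuple[str, float]] = {
        i: (_quote(labels[i]), 0.0) for i in range(n)
    }
    for k, (a, b, h, _) in enumerate(Z):
        sa, ha = nodes.pop(int(a))
        sb, hb = nodes.pop(int(b))
        depth = h / 2.0  # ultrametric depth of the merged cluster
        nodes[n + k] = (f"({sa}:{depth - ha:.10g},{sb}:{depth - hb:.10g})", depth)
    (tree, _), = nodes.values()
    return tree + ";"


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}:;, '\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def upgma_dendrogram(
    points: pd.DataFrame, annotations: dict[str, str] | None = None
) -> tuple[str, np.ndarray]:
    """UPGMA tree over per-specimen (mean length, mean width) points.

    ``points`` is indexed by specimen ID with two numeric columns.
    ``annotations`` optionally appends " [value]" to leaf labels (e.g. ITS
    cluster numbers). Returns the Newick string and the scipy linkage
    matrix. Output is ultrametric: every root-to-leaf path has equal length
    (half the root's merge height).
    """
    ids = [str(i) for i in points.index]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate specimen IDs in morphometric points")
    if len(ids) < 2:
        raise FormatError("need at least 2 specimens for a dendrogram")
    xy = points.to_numpy(dtype=float)
    if xy.shape[1] != 2:
        raise FormatError("points must have exactly 2 columns (length, width)")
    Z = linkage(pdist(xy, metric="euclidean"), method="average")
    labels = (
        [f"{i} [{annotations[i]}]" if i in annotations else i for i in ids]
        if annotations
        else ids
    )
    return _newick_from_linkage(Z, labels), Z
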