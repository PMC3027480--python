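"""External representations used by the species-delimitation pipeline.

Four in-memory containers (:class:`MultipleAlignment`, :class:`DistanceMatrix`,
:class:`Partition`, :class:`MorphoTable`) and the readers/writers for their
on-disk forms: FASTA alignments, labelled square CSV and PHYLIP square distance
matrices, two-column partition tables, Newick trees and spore-measurement CSVs.

All read/write pairs are identities at the declared numeric precision
(distances are written with 6 decimals; the optimization grid step is 1e-4, so
rounding at 1e-6 is safely finer). Parsers never silently drop records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, MatrixError, TreeError

#: Special partition label for specimens that could not be identified.
UNASSIGNED = "?"

# Residues that count as determinate, unambiguous bases in distance
# calculations.  Everything else (gaps, '?', 'N', IUPAC ambiguity codes) is
# treated as missing for the pair.
_DETERMINATE = "ACGT"
_ALLOWED = set("ACGTURYSWKMBDHVN-?")


@dataclass
class MultipleAlignment:
    """An aligned set of equal-length nucleotide sequences.

    Rows are stored uppercased with ``U`` mapped to ``T``.  IDs are unique and
    row order is meaningful (it is preserved through masking and distance
    computation).
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate sequence IDs: {dupes}")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        L = len(self.rows[0])
        if L < 1:
            raise AlignmentError("alignment has zero columns")
        for sid, r in zip(self.ids, self.rows):
            if len(r) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(r)}, expected {L}"
                )
            bad = set(r) - _ALLOWED
            if bad:
                raise FormatError(f"sequence {sid!r} contains invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.ids)

    def to_codes(self) -> np.ndarray:
        """Encode as an (n, length) uint8 array: A,C,G,T -> 0..3, missing -> 255."""
        lut = np.full(256, 255, dtype=np.uint8)
        for k, b in enumerate(_DETERMINATE):
            lut[ord(b)] = k
        raw = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.rows), self.length)
        return lut[raw]

    def drop(self, ids: set[str] | list[str]) -> "MultipleAlignment":
        """Return a copy without the given sequence IDs (order preserved)."""
        ids = set(ids)
        missing = ids - set(self.ids)
        if missing:
            raise FormatError(f"cannot drop unknown IDs: {sorted(missing)}")
        keep = [(i, r) for i, r in zip(self.ids, self.rows) if i not in ids]
        return MultipleAlignment([i for i, _ in keep], [r for _, r in keep])


@dataclass
class DistanceMatrix:
    """A labelled, symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    _tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise FormatError("duplicate matrix labels")
        if self.values.shape != (n, n):
            raise MatrixError(f"matrix shape {self.values.shape} does not match {n} labels")
        if n == 0:
            raise MatrixError("empty distance matrix")
        if not np.all(np.isfinite(self.values)):
            raise MatrixError("matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise MatrixError("matrix contains negative entries")
        asym = np.abs(self.values - self.values.T).max()
        if asym > self._tol:
            raise MatrixError(f"matrix asymmetric (max |d_ij - d_ji| = {asym:g})")
        self.values = (self.values + self.values.T) / 2.0
        if np.any(np.diag(self.values) != 0):
            raise MatrixError("matrix has nonzero diagonal entries")

    def __len__(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        """Restrict to the given labels, in the given order."""
        pos = {l: k for k, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise MatrixError(f"labels not in matrix: {missing}")
        idx = np.array([pos[l] for l in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def drop(self, ids: set[str] | list[str]) -> "DistanceMatrix":
        keep = [l for l in self.labels if l not in set(ids)]
        return self.submatrix(keep)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values as a flat array."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass
class Partition:
    """Assignment of specimen IDs to cluster/species labels.

    The label :data:`UNASSIGNED` marks specimens that could not be identified;
    such specimens are excluded from agreement scoring.
    """

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not isinstance(self.assignment, dict):
            self.assignment = dict(self.assignment)

    @classmethod
    def from_blocks(cls, blocks: dict[str, list[str]]) -> "Partition":
        assignment: dict[str, str] = {}
        for label, members in blocks.items():
            for m in members:
                if m in assignment:
                    raise FormatError(f"specimen {m!r} appears in more than one block")
                assignment[m] = label
        return cls(assignment)

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    def assigned_ids(self) -> list[str]:
        return [i for i, lab in self.assignment.items() if lab != UNASSIGNED]

    def blocks(self, include_unassigned: bool = False) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for i, lab in self.assignment.items():
            if lab == UNASSIGNED and not include_unassigned:
                continue
            out.setdefault(lab, []).append(i)
        return {lab: sorted(m) for lab, m in out.items()}

    def n_blocks(self) -> int:
        """Number of non-UNASSIGNED blocks."""
        return len(self.blocks())

    def restrict(self, ids: list[str] | set[str]) -> "Partition":
        ids = set(ids)
        return Partition({i: lab for i, lab in self.assignment.items() if i in ids})

    def relabel(self, mapping: dict[str, str]) -> "Partition":
        """Rename specimen IDs (values stay)."""
        return Partition({mapping.get(i, i): lab for i, lab in self.assignment.items()})

    def block_sets(self) -> set[frozenset[str]]:
        """The partition as a set of member sets — label-free equality."""
        return {frozenset(m) for m in self.blocks().values()}


@dataclass
class MorphoTable:
    """Per-specimen spore measurements: (length µm, width µm) pairs."""

    measurements: dict[str, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for sid, rows in self.measurements.items():
            for l, w in rows:
                if l <= 0 or w <= 0:
                    raise FormatError(
                        f"non-positive spore measurement for {sid!r}: ({l}, {w})"
                    )

    @property
    def ids(self) -> list[str]:
        return list(self.measurements)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sid, l, w)
            for sid, ms in self.measurements.items()
            for l, w in ms
        ]
        return pd.DataFrame(rows, columns=["specimen", "length", "width"])


# ---------------------------------------------------------------------------
# Alignments (FASTA)
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned multi-FASTA file.

    Rows are uppercased and ``U`` is mapped to ``T``; record order is
    preserved. Raises :class:`AlignmentError` on ragged rows and
    :class:`FormatError` on duplicate IDs.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return MultipleAlignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Distance matrices (labelled square CSV; PHYLIP square)
# ---------------------------------------------------------------------------

_DIALECTS = ("csv", "phylip")
_PRECISION = 6


def read_distance_matrix(path: str | Path, dialect: str = "csv") -> DistanceMatrix:
    """Read a square distance matrix.

    dialect="csv": labelled square CSV (header row + index column).
    dialect="phylip": PHYLIP square format (count line, then label + n values).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0)
        labels = [str(l) for l in df.index]
        if [str(c) for c in df.columns] != labels:
            raise MatrixError(f"{path}: row and column labels differ")
        return DistanceMatrix(labels, df.to_numpy(dtype=float))
    with open(path) as fh:
        tokens = fh.read().split("\n")
    lines = [ln for ln in tokens if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: bad PHYLIP header") from exc
    if len(lines) - 1 != n:
        raise FormatError(f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise FormatError(f"{path}: bad PHYLIP row: {ln!r}")
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels, np.array(rows))


def write_distance_matrix(
    m: DistanceMatrix, path: str | Path, dialect: str = "csv"
) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    vals = np.round(m.values, _PRECISION)
    if dialect == "csv":
        pd.DataFrame(vals, index=m.labels, columns=m.labels).to_csv(
            path, float_format=f"%.{_PRECISION}f"
        )
        return
    with open(path, "w") as fh:
        fh.write(f"{len(m.labels)}\n")
        for lab, row in zip(m.labels, vals):
            fh.write(lab + "  " + "  ".join(f"{x:.{_PRECISION}f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Partitions (two-column TSV/CSV)
# ---------------------------------------------------------------------------

def read_partition(path: str | Path) -> Partition:
    """Read a two-column (ID, label) table; tab or comma separated.

    An empty or ``"?"`` label marks the specimen as UNASSIGNED.
    """
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            parts = line.split(sep)
            if len(parts) > 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid = parts[0].strip()
            lab = parts[1].strip() if len(parts) == 2 else ""
            if not sid:
                raise FormatError(f"{path}:{lineno}: empty specimen ID")
            if sid in assignment:
                raise FormatError(f"{path}:{lineno}: duplicate specimen ID {sid!r}")
            assignment[sid] = lab if lab and lab != UNASSIGNED else UNASSIGNED
    return Partition(assignment)


def write_partition(p: Partition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in p.assignment.items():
            fh.write(f"{sid}\t{lab}\n")


# ---------------------------------------------------------------------------
# Trees (Newick, via dendropy)
# ---------------------------------------------------------------------------

def read_tree(path: str | Path, missing_lengths: str = "error") -> dendropy.Tree:
    """Read a Newick tree with branch lengths.

    missing_lengths: "error" (default) rejects edges without a length;
    "zero" assumes 0. Leaf labels are preserved verbatim (underscores kept).
    """
    with open(path) as fh:
        return tree_from_string(fh.read(), missing_lengths=missing_lengths, source=str(path))


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def tree_from_string(
    newick: str, missing_lengths: str = "error", source: str = "<string>"
) -> dendropy.Tree:
    """Parse a Newick string (same contract as :func:`read_tree`)."""
    if missing_lengths not in ("error", "zero"):
        raise ValueError("missing_lengths must be 'error' or 'zero'")
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"cannot parse Newick from {source}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if missing_lengths == "error":
                raise TreeError(f"{source}: edge without branch length")
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Morphometrics (CSV: specimen, length, width)
# ---------------------------------------------------------------------------

def read_morpho(path: str | Path) -> MorphoTable:
    """Read per-spore measurements; rows are (specimen ID, length µm, width µm)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty morphometrics file")
        return MorphoTable({})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (specimen, length, width)")
    df = df.iloc[:, :3]
    df.columns = ["specimen", "length", "width"]
    if df.empty:
        warnings.warn(f"{path}: no measurement rows")
        return MorphoTable({})
    measurements: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        measurements.setdefault(str(row["specimen"]), []).append(
            (float(row["length"]), float(row["width"]))
        )
    return MorphoTable(measurements)


def write_morpho(table: MorphoTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)
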