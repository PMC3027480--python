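"""Synthetic species complexes and noisy reference taxonomies.

The generator emulates the data regime the delimitation pipeline assumes: K
species whose members are tightly clustered in p-distance space (small
within-species divergence ``r_in``) and clearly separated from other species
(larger between-species divergence ``r_out``), plus competing "species
concepts" derived from the truth by lumping species pairs, splitting species
in two, and misassigning individuals at stated rates.

Sequences evolve in two steps from a uniform random root: each species
ancestor substitutes each site with probability ``r_out`` (uniform over the
three alternative bases), and each individual substitutes each ancestor site
with probability ``r_in / 2``, so the expected within-species p-distance is
approximately ``r_in`` (exactly 2q(1-q) + (2/3)q^2 with q = r_in/2, counting
back-substitution collisions). There are no indels or rate heterogeneity by
default; a block-structured distance-matrix generator is provided separately
for fast property tests that need no sequence stage.

All randomness flows from a single integer seed through numpy's seed-spawning
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SpecDelimError
from .io_formats import DistanceMatrix, MorphoTable, MultipleAlignment, Partition

_BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for a species complex and its noisy references.

    Defaults describe a well-separated complex of 5 species with 6
    individuals each: ITS-like sequences of 600 sites, within-species
    divergence 0.005 and between-species divergence 0.08, so a threshold
    near 0.02-0.05 cleanly separates species.
    """

    n_species: int = 5
    species_sizes: tuple[int, ...] | int = 6
    length: int = 600
    r_in: float = 0.005
    r_out: float = 0.08
    p_lump: float = 0.0
    p_split: float = 0.0
    p_mis: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise SpecDelimError("need at least one species")
        if self.length < 1:
            raise SpecDelimError("sequence length must be >= 1")
        if not 0 <= self.r_in < self.r_out <= 1:
            raise SpecDelimError("need 0 <= r_in < r_out <= 1")
        for name in ("p_lump", "p_split", "p_mis"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SpecDelimError(f"{name} must be in [0, 1]")
        if isinstance(self.species_sizes, int):
            object.__setattr__(
                self, "species_sizes", (self.species_sizes,) * self.n_species
            )
        if len(self.species_sizes) != self.n_species:
            raise SpecDelimError("species_sizes length must equal n_species")
        if any(s < 1 for s in self.species_sizes):
            raise SpecDelimError("every species needs at least one individual")

    def expected_within_p(self) -> float:
        """Closed-form expected within-species p-distance."""
        q = self.r_in / 2.0
        return 2 * q * (1 - q) + (2.0 / 3.0) * q * q

    def manifest(self) -> str:
        """Plain-text key=value record of the generative parameters."""
        items = {
            "n_species": self.n_species,
            "species_sizes": ",".join(map(str, self.species_sizes)),
            "length": self.length,
            "r_in": self.r_in,
            "r_out": self.r_out,
            "p_lump": self.p_lump,
            "p_split": self.p_split,
            "p_mis": self.p_mis,
            "seed": self.seed,
        }
        return "".join(f"{k}={v}\n" for k, v in items.items())


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with the given probability, uniformly over the
    three alternative bases."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    out[hit] = (out[hit] + 1 + rng.integers(0, 3, hit.size)) % 4
    return out


def simulate_species_complex(
    spec: SyntheticSpec,
) -> tuple[MultipleAlignment, Partition]:
    """Draw an alignment and its true species partition.

    Deterministic under ``spec.seed``. IDs are ``sp{k:02d}_i{j:02d}`` and the
    truth partition assigns each individual its species label ``sp{k:02d}``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    root = rng.integers(0, 4, spec.length)
    ids, rows, assignment = [], [], {}
    for k in range(spec.n_species):
        label = f"sp{k:02d}"
        ancestor = _mutate(root, spec.r_out, rng)
        for j in range(spec.species_sizes[k]):
            sid = f"{label}_i{j:02d}"
            seq = _mutate(ancestor, spec.r_in / 2.0, rng)
            ids.append(sid)
            rows.append("".join(_BASES[b] for b in seq))
            assignment[sid] = label
    return MultipleAlignment(ids, rows), Partition(assignment)


def perturb_reference(
    truth: Partition,
    p_lump: float = 0.0,
    p_split: float = 0.0,
    p_mis: float = 0.0,
    seed: int = 0,
) -> Partition:
    """Derive a noisy reference taxonomy from the truth.

    In order: randomly paired species are merged with probability ``p_lump``
    per pair; each (post-lump) multi-member species is bisected into random
    halves with probability ``p_split``; each individual moves to a
    uniformly chosen other label with probability ``p_mis``. Deterministic
    under ``seed``.
    """
    for name, v in (("p_lump", p_lump), ("p_split", p_split), ("p_mis", p_mis)):
        if not 0 <= v <= 1:
            raise SpecDelimError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    blocks = {lab: list(m) for lab, m in truth.blocks().items()}
    # lump: disjoint random species pairs merge
    labels = sorted(blocks)
    rng.shuffle(labels)
    for a, b in zip(labels[0::2], labels[1::2]):
        if rng.random() < p_lump:
            keep, gone = sorted((a, b))
            blocks[keep] = blocks[keep] + blocks.pop(gone)
    # split: bisect into random halves
    for lab in sorted(blocks):
        members = blocks[lab]
        if len(members) >= 2 and rng.random() < p_split:
            perm = list(members)
            rng.shuffle(perm)
            half = len(perm) // 2
            blocks[lab] = perm[half:]
            blocks[f"{lab}_b"] = perm[:half]
    assignment = {m: lab for lab, ms in sorted(blocks.items()) for m in ms}
    # misassign: move individuals to a random other label
    labels = sorted(set(assignment.values()))
    if len(labels) > 1:
        for sid in sorted(assignment):
            if rng.random() < p_mis:
                others = [l for l in labels if l != assignment[sid]]
                assignment[sid] = others[rng.integers(0, len(others))]
    return Partition(assignment)


def block_distance_matrix(
    n_species: int = 5,
    species_sizes: int | tuple[int, ...] = 6,
    within: tuple[float, float] = (0.0, 0.01),
    between: tuple[float, float] = (0.08, 0.2),
    seed: int = 0,
) -> tuple[DistanceMatrix, Partition]:
    """Directly draw a block-structured distance matrix and its truth.

    Within-species distances are uniform on ``within`` and between-species
    distances uniform on ``between``; useful for fast clustering property
    tests that do not need the sequence stage.
    """
    if isinstance(species_sizes, int):
        species_sizes = (species_sizes,) * n_species
    if within[1] >= between[0]:
        raise SpecDelimError("within and between distance ranges must not overlap")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ids, labs = [], []
    for k, sz in enumerate(species_sizes):
        for j in range(sz):
            ids.append(f"sp{k:02d}_i{j:02d}")
            labs.append(f"sp{k:02d}")
    n = len(ids)
    d = rng.uniform(*between, size=(n, n))
    same = np.equal.outer(labs, labs)
    w = rng.uniform(*within, size=(n, n))
    d[same] = w[same]
    d = np.triu(d, k=1)
    d = d + d.T
    return DistanceMatrix(ids, d), Partition(dict(zip(ids, labs)))


def simulate_spore_measurements(
    truth: Partition,
    n_spores: int = 10,
    length_range: tuple[float, float] = (10.0, 25.0),
    quotient_range: tuple[float, float] = (1.3, 2.0),
    noise_sd: float = 0.6,
    seed: int = 0,
) -> MorphoTable:
    """Synthetic per-spore measurements consistent with a species partition.

    Each species gets a mean spore length and length/width quotient drawn
    uniformly from the given ranges; individual spores add gaussian noise.
    Purely a synthetic stand-in so the morphometric stage can run end-to-end
    without real measurements.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    table: dict[str, list[tuple[float, float]]] = {}
    for lab, members in sorted(truth.blocks().items()):
        mean_len = rng.uniform(*length_range)
        mean_q = rng.uniform(*quotient_range)
        mean_wid = mean_len / mean_q
        for sid in members:
            lengths = np.clip(rng.normal(mean_len, noise_sd, n_spores), 1.0, None)
            widths = np.clip(rng.normal(mean_wid, noise_sd, n_spores), 0.5, None)
            table[sid] = list(zip(lengths.tolist(), widths.tolist()))
    return MorphoTable(table)


def write_manifest(spec: SyntheticSpec, path: str | Path) -> None:
    Path(path).write_text(spec.manifest())
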