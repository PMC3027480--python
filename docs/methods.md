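# Methods

## Problem and model

Molecular species delimitation assigns specimens to operational taxonomic
units by clustering pairwise genetic distances at a threshold T. Both T and
the *linkage stringency* are free parameters: in linkage clustering a "link"
is a pairwise distance d ≤ T, and an object (or cluster) may join a cluster
when at least a fraction F of its distances to the cluster's members are
links. F = 0 behaves as single linkage (one link suffices), F = 1 is
complete linkage (all distances must be links). Rather than fixing (T, F) by
convention, clustering optimization searches the (T, F) grid for the
parameters whose clustering partition agrees best with a *reference
partition* — a specimen-to-species assignment produced by a morphological
identification key. Running the search independently for several keys
(species concepts) and comparing the optima selects the concept most
consistent with the molecular data; the winning parameters are then applied
to the complete data set, and the resulting clusters are audited for
monophyly against a phylogeny.

## Distances

Uncorrected p-distances: the fraction of mismatching sites among columns
where both sequences carry a determinate, unambiguous base (A/C/G/T after
uppercasing and U→T). Gaps, `?`, `N` and IUPAC ambiguity codes are deleted
*pairwise*, not listwise — this preserves signal on ragged alignments and is
the common default for p-distances. Ambiguity codes are treated as missing
rather than as partial matches; this is the simplest reading of an
"uncorrected" distance and is the one implemented (a switch would be easy
but has not been needed). A pair with zero comparable columns is an error by
default; optionally the distance is imputed as 1.0 with a warning.

Edge masking (`auto_edge_mask`) reconstructs the usual pre-filtering of
alignment columns dominated by leading/trailing gaps: a column is a
candidate when its non-gap fraction falls below a threshold (default 0.5),
and only maximal candidate runs touching the first or last column are
excluded. Interior gappy columns are never masked. Excluded sets can also be
supplied explicitly, with a converter from 1-based inclusive ranges (the
form used in prose) to the 0-based indices used internally.

## F-linkage clustering

The link criterion does not by itself define a clustering; a merge schedule
is needed. This package uses greedy best-first agglomeration:

1. start from singletons;
2. for every active cluster pair (A, B) compute the link fraction
   L(A,B) = |{(a,b) ∈ A×B : d(a,b) ≤ T}| / (|A|·|B|);
3. a pair is *mergeable* when L(A,B) ≥ F **and** it has at least one link
   (the one-link floor makes F = 0 exactly single linkage, where the
   "fraction ≥ F" condition would otherwise be vacuous);
4. merge the mergeable pair with the largest L; break ties by the smallest
   mean inter-cluster distance, then by the lexicographically smallest
   member-label pair;
5. stop when no pair is mergeable.

This schedule is deterministic, independent of input order (label
permutation equivariance holds whenever the numeric tie-breaks are decisive,
which is almost surely the case for continuous distances), reduces to
connected components of the link graph at F = 0 and to a complete-linkage
partition (max within-cluster distance ≤ T) at F = 1. Links use d ≤ T, not
d < T. Floating-point comparisons of link fractions use an absolute
tolerance of 1e-12 so that algebraically equal fractions with different
denominators tie correctly. The inner loop is O(n³) per clustering and is
compiled with numba; at the study scale (n ≈ 165) one clustering takes
well under a millisecond.

Cluster labels in the output are "0".."k-1", numbered by each cluster's
lexicographically smallest member; the numbers are arbitrary identifiers
and imply no relatedness.

## Agreement

Partitions are compared over the intersection of their assigned
(non-UNASSIGNED) specimen IDs via pair counts n11/n00/n10/n01 computed from
the label contingency table (the O(n²) pair enumeration is retained as an
independent oracle in the tests). The default score is the modified Rand
index MRI = 2·RI − 1 with RI = (n11+n00)/C(n,2): the only linear transform
of the Rand index whose range is exactly [−1, 1], which is how the index is
characterized in the clustering-optimization literature this package
follows. Because that literature does not print the formula itself, the
Hubert–Arabie adjusted Rand index is provided as a switchable alternative
(`variant="ari"`, cross-checked against scikit-learn), and every
optimization result records which variant produced it.

## Grid optimization

Defaults: F ∈ {0.00, 0.05, …, 1.00} and T ∈ {0.0000, 0.0001, …, 1.0000},
endpoints inclusive. T values are manipulated as integer multiples of the
step, never accumulated by float addition. The clustering depends on T only
through the link set {(i,j): d_ij ≤ T}, which is constant between
consecutive distinct matrix values: the sweep therefore clusters once per
(interval × F) and assigns the score to every grid T inside the interval.
Interval boundaries are computed float-exactly (the smallest grid index i
with v ≤ i·step under double-precision comparison), so the cached sweep is
bit-identical to the naive per-T evaluation; the naive path is kept as
`method="naive"` and equality is asserted in the test suite.

Per F the records keep the highest score, the set of grid T attaining it and
its median (even-sized sets take the mean of the two middle grid values,
which is why published medians can end in half-steps). Concept selection
takes the reference with the largest global best score, breaking ties toward
the reference with fewer species (the broader concept) and then by name.
When several F values tie for the winner's global best, the chosen F is the
lower-middle of the tied values — a convention, documented as such, chosen
because the tied range is typically contiguous and the lower-middle avoids
the extremes — and the chosen T is that F's median best T.

Re-clustering at the chosen (F, T) reproduces the recorded best score
whenever the best-T set of the chosen F is contiguous (the usual case; for
pathological references whose best-T set is disconnected, the median may
fall outside it, which the per-record invariant — median within the closed
range of the set — still permits).

## Monophyly audit

Trees are Newick with branch lengths (dendropy objects internally). Midpoint
rooting is implemented in the package: the longest leaf-to-leaf path is
located (ties broken toward the lexicographically smallest leaf pair, for
determinism), a new root node is spliced into the edge containing the path's
midpoint, and the tree is rerooted there; degree-two remnants are
suppressed. A cluster is monophyletic iff the leaves under its members'
MRCA are exactly its members; singletons are trivially monophyletic.
Unrooted inputs (trifurcating base) are midpoint-rooted automatically before
the audit. The audit is a report, not a test: no constrained-topology
statistics are computed.

## Morphometrics

Spore length/width pairs (µm) are averaged per specimen; the length/width
quotient is computed per spore and then aggregated (min/mean/max), which is
not the same as the ratio of means. Specimen mean points are clustered by
unweighted average linkage (UPGMA) on raw euclidean distances — no
standardization, so branch lengths remain in µm — using scipy's
agglomeration; within-scipy tie order is accepted as-is, since ties only
arise on exactly equal distances and never affect merge heights. The
dendrogram is exported as Newick with each cluster's merge height halved
into ultrametric branch lengths.

## Synthetic data generator

`simulate_species_complex` draws a root sequence uniformly over {A,C,G,T},
derives one ancestor per species by substituting each site with probability
`r_out` (uniform over the three alternative bases), and each individual from
its ancestor with per-site probability `r_in/2`. The expected within-species
p-distance is 2q(1−q) + (2/3)q² with q = r_in/2 (two independent mutation
draws; the last term counts coincident substitutions to different bases),
which the tests verify by Monte-Carlo against the simulation. Defaults — 5
species × 6 individuals, 600 sites, r_in = 0.005, r_out = 0.08 — put the
within/between distance distributions on either side of a clear gap, the
regime in which threshold clustering of a barcode marker is meaningful and
which the real ITS data approximate (optimal T ≈ 0.026 there).

`perturb_reference` derives noisy taxonomies: random disjoint species pairs
are merged with probability `p_lump` each, each multi-member species is
bisected into random halves with probability `p_split`, and each individual
moves to a uniformly chosen other label with probability `p_mis` — applied
in that order (lump, split, misassign), all driven by one seed. The
competing-concept experiment uses the extremes (oversplit: p_split = 1;
lumped: p_lump = 1) against the unperturbed truth.

What the generator does *not* emulate: indels and alignment error (no indel
mode is enabled by default, so pairwise deletion is exercised through IUPAC
codes and explicit gap fixtures instead), rate heterogeneity across sites,
within-species genealogical structure (individuals are i.i.d. around their
ancestor rather than coalescent-correlated), and unbalanced divergence
between species pairs (all species are equidistant from the root in
expectation). Passing the synthetic recovery tests therefore demonstrates
the machinery is correct in the well-separated regime; it does not show the
method resolves real complexes whose within- and between-species
distributions overlap.

A direct block-structured distance-matrix generator (uniform within-block
and between-block distances with disjoint ranges) supports fast clustering
property tests, and `simulate_spore_measurements` draws per-species spore
dimensions (species mean length uniform in 10–25 µm, quotient in 1.3–2.0,
gaussian spore noise of 0.6 µm) so the morphometric stage can run
end-to-end; it is purely a synthetic stand-in.

## Problem sizes and numerical choices

The analysis drivers and the acceptance script run the synthetic study at
the default conditions above (30 sequences); the concept-recovery experiment
uses 100 replicate seeds, each sweeping the full 21 × 10001 grid for three
references via the interval cache. Distance I/O is written at 6 decimals
(the T grid step is 1e-4, so 1e-6 is safely finer); agreement values are
reported at 5 decimals. Distance-matrix symmetry is enforced within 1e-9 and
the matrix is symmetrized to the mean of the two triangles on input.

## Known limitations

- The greedy merge schedule is one reasonable realization of F-linkage;
  other schedules satisfying the same link criterion can produce different
  partitions at intermediate F, so medians of optimal T may differ slightly
  from implementations with other internal merge orders.
- MRI variant ambiguity: where only the range [−1, 1] is documented by a
  source, 2·RI − 1 is assumed; results can be recomputed under `ari`.
- Midpoint rooting assumes a unique (up to ties) longest path; all-zero
  branch lengths are rejected.
- Concept selection's fewer-species tie-break means a lumped reference can
  win a exact tie against the truth when a distance matrix happens to
  support both perfectly; this is visible as occasional (<5%) misselection
  in the recovery experiment.
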