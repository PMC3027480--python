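# specdelim

Species delimitation by clustering optimization of pairwise sequence
distances — built around the workflow used to revise the false-truffle genus
*Hymenogaster* from ITS barcodes, and generally applicable to any marker
whose distances show a within/between-species gap.

Taxonomically difficult groups often come with several competing species
concepts (identification keys that lump or split taxa differently). Instead
of clustering sequences at a conventional fixed threshold, this package
searches the parameters of *F-linkage clustering* — a distance threshold T
(a "link" is a pairwise distance d ≤ T) and a link fraction F (an object
joins a cluster when at least a fraction F of its distances to cluster
members are links; F = 0 ≈ single linkage, F = 1 = complete linkage) — for
the partition that agrees best with each reference taxonomy. Agreement is
the modified Rand index MRI = 2·RI − 1 ∈ [−1, 1] over specimen pairs
(Hubert–Arabie adjusted Rand available as a variant). The key whose optimum
is highest is the species concept best supported by the molecular data; its
(T, F) are applied to the complete data set, the resulting clusters are
audited for monophyly on a midpoint-rooted phylogeny, and spore
morphometrics (per-specimen means, UPGMA dendrogram in µm) support the
morphological interpretation of the clusters.

For whom: systematists delimiting species from single-marker data with
imperfect morphological references, and methodologists who need a
deterministic, testable reference implementation of threshold/linkage-
fraction clustering optimization.

## Worked example

```sh
python analysis/01_simulate.py            # 5 species x 6 individuals, L=600
python analysis/02_distances.py
python analysis/03_optimize_concepts.py
python analysis/04_apply_and_audit.py
```

prints (seed 1):

```
within-species p-distance:  max 0.0117 (mean 0.0045)
between-species p-distance: min 0.1183 (mean 0.1335)
separation gap: 0.1067 -> any T inside it delimits species perfectly
truth      ( 5 species): global best 1.00000
oversplit  (10 species): global best 0.84828
lumped     ( 3 species): global best 0.83448
selected concept: truth (F=0.5, T=0.0650)
T=0.0650, F=0.5: 5 clusters
all clusters monophyletic on the midpoint-rooted NJ tree
```

Reading this: the simulated complex has a clean barcode gap
(0.0117 < d < 0.1183 contains no pairs), so clustering at any T inside it
reproduces the true 5-species partition exactly (MRI 1.0). The oversplit
concept (every species halved) and the lumped concept (species pairs
merged) top out at MRI ≈ 0.85 and ≈ 0.83 — concept selection picks the
truth. Applying the chosen parameters (F = 0.5, the lower-middle of the
tied F range; T = 0.0650, the median optimal threshold at that F) to the
full matrix yields 5 clusters, all monophyletic on a midpoint-rooted
neighbor-joining tree built from the same distances.

The same stages are available as a CLI (`specdelim pdist | cluster | mri |
optimize | apply | audit | morpho | simulate | run`, where `optimize`
performs concept selection when given several references);
`specdelim run pipeline.cfg` executes the whole workflow from a flat
key=value config. `analysis/06_reproduce_study.py` reruns the published
*Hymenogaster* analysis (58-specimen optimization subset after dropping
four short sequences; 21 F × 10001 T grid; full-set clustering; monophyly
audit; *H. huthii* spore quotients) given the supplementary data files.

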