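# bcrstruct

Structural annotation and structural-diversity statistics for heavy-chain
B-cell-receptor (BCR) repertoires.

Ig-seq experiments read out antibody repertoires as amino-acid sequences,
but antigen recognition is a property of loop *shapes*. `bcrstruct` maps
every sequence in a repertoire onto known loop structures and then asks
repertoire-level questions: how structurally diverse is a repertoire, how
do B-cell types differ in the loop shapes they use, and which CDR-H3
shapes are "public" — over-represented across all individuals of a B-cell
type.

The pipeline, per sequence:

1. **Numbering and viability filters** — IMGT numbering against a germline
   V-gene reference; rejection of sequences with framework indels, missing
   conserved residues (Cys23, Trp41, Cys104, Trp/Phe118), chimeric halves,
   or missing CDR loops. CDR-H3 analysis is restricted to loop lengths
   5–16.
2. **Canonical classes** — CDR-H1/H2 assigned to canonical classes by
   per-class position-specific scoring matrices (PSSMs) with an UNASSIGNED
   fallback; divergence from the germline's own classes is a structural
   readout of affinity maturation.
3. **CDR-H3 template prediction** — each loop searched against same-length
   crystallographic templates, ranked by framework identity then by a
   substitution-score (ESS, BLOSUM62 by default) with per-length-bin
   cutoffs calibrated so retained predictions average better than 3 Å
   backbone RMSD (falling back to >15% coverage).

And per repertoire:

4. **Template clustering** — library templates within 0.6 Å backbone RMSD
   (Kabsch superposition; dynamic time warping across unequal lengths)
   collapse into structural clusters, the unit of all counting.
5. **Usage profiles and diversity** — cluster frequency vectors; structural
   coverage; subsampled cluster richness (10,000 sequences × 100 draws);
   Shannon entropy normalized to its theoretical maximum
   H/ln(richness); PCA embedding and a DBSCAN ε-sweep ordering repertoires
   by usage similarity to an antigen-unexperienced reference.
6. **Structural Stems** — for each (B-cell type, isotype) group,
   repertoire-matched randomized datasets (one million template draws from
   each repertoire's own observed templates, following its length
   distribution thinned by per-length modellability) give a null usage per
   cluster; a one-sided Mann–Whitney test at p = 0.05 calls each cluster
   STRUCTURAL_STEM (over-represented), UNDER_REPRESENTED, or
   RANDOM_USAGE.

A synthetic-data module generates every input — template library with 3D
backbone coordinates organized in separable shape families, germline
references, and labelled repertoires with planted usage structure — so the
whole pipeline runs and is tested with no downloads.

## Worked example

```
python examples/03_diversity_profiles.py
```

prints (abridged):

```
repertoire       coverage richness  H/Hmax join eps
naive_IGHM_00       0.995       36   0.931     0.03
naive_IGHM_01       0.996       36   0.935     0.03
naive_IGHM_02       0.995       36   0.937     0.03
plasma_IGHG_00      0.955       36   0.898     0.19
plasma_IGHG_01      0.974       34   0.873     0.23
plasma_IGHG_02      0.971       35   0.850     0.24
```

Coverage is the fraction of in-range sequences that received a CDR-H3
template; H/Hmax is normalized structural entropy; "join eps" is the
smallest DBSCAN ε at which a repertoire clusters with the naive
reference — naive repertoires share one public usage distribution and
merge almost immediately, while individualized plasma repertoires need a
much larger ε and show lower structural diversity. The other examples
(`examples/01_…` to `04_…`) walk the annotation, clustering and stem
stages the same way.

There is also a thin CLI (`bcrstruct synth | annotate |
cluster-templates | calibrate | profile | classify-stems | run`) over the
same functions.

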