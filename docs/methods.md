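# Methods

This note documents the models, numerical choices and limitations of
`bcrstruct`, in the order data flows through the pipeline.

## Sequence numbering and viability filters (`seqqc`)

Sequences are numbered by deterministic profile alignment against
per-V-gene IMGT-aligned references rather than a profile HMM. The package
works on a fixed-occupancy scaffold: V positions 1–104 (CDR1 = 27–38,
CDR2 = 56–65), CDR-H3 = 105–117 with insertion codes 111.x/112.x for
loops longer than 13, framework 4 from 118. The hot path is an ungapped
comparison of the sequence prefix against every germline, vectorized
across a whole repertoire; sequences below a 70% best-identity floor fall
back to an affine-gap pairwise alignment (BLOSUM62, open −10 / extend
−0.5) so indel-bearing reads are classified rather than dropped. The
framework-4 start is located by matching the J reference at the sequence
end (scanning fallback at ≥50% identity); the residues between IMGT 104
and the J start are the CDR-H3.

Filters, applied in order, with machine-readable rejection reasons:
`no_alignment`, `indel_in_framework` (any gap in a framework region;
CDR-length variation is absorbed by insertion codes), `missing_cdr`,
`chimeric`, `missing_conserved_residue` (Cys23, Trp41, Cys104, Trp/Phe
118; configurable), `x_in_cdr` (X makes loop scoring undefined) and
`too_many_x` (more than 2 framework X's). The chimera rule — not part of
any published filter set and therefore explicit and configurable here —
splits the V region at IMGT 52 and flags a sequence when the two halves'
best germlines differ and each wins its half by ≥10 identity percentage
points. CDR-H3 analysis keeps loop lengths 5–16 inclusive: shorter loops
are essentially template-free, longer ones too structurally free to
predict reliably.

## Canonical classes (`canonical`)

One PSSM per (loop, length, class): log-odds of per-position residue
frequencies (additive pseudocount 0.5) against a uniform 1/20 background.
A loop is scored against every length-matched class; the argmax wins if
its score reaches the class threshold (the minimum self-score of its
training members), else the loop is UNASSIGNED; ties break
lexicographically on class id. This reproduces the *contract* of a
canonical-class assigner (length-matched classes with an UNASSIGNED
fallback), not any published scoring function. At desk scale the database
is trained on the germline CDR-H1/H2 loops themselves, one class per
distinct germline loop. Germline canonical divergence counts a sequence
as diverged when either loop's class differs from its germline's entry;
UNASSIGNED sequence classes count as divergent when the germline class is
assigned (unassignable sequences are retained, not discarded). In the
canonical-usage embedding, UNASSIGNED is kept as an explicit category.

## Template prediction (`fread`)

The ESS is a sum of per-position substitution scores over the aligned
(equal-length, gapless) query and template loops. The default table is
BLOSUM62 restricted to the 20 standard residues — a symmetric,
diagonal-dominant stand-in chosen because the score's *calibration
machinery*, not its provenance, is the point; any symmetric 20×20 table
can be supplied from file. Candidates are ranked by framework sequence
identity first (the structure-free proxy for choosing a framework
template), then ESS, then template id; anchor-geometry checks of a full
knowledge-based loop search are out of scope.

Cutoff calibration uses structures of known backbone (leave-one-out on
the library): per length bin (5–12, 13–14, 15–16), the smallest cutoff on
the grid of observed top-hit scores whose retained predictions average
<3 Å RMSD; if unreachable, the largest cutoff keeping coverage >15%;
+∞ for empty bins. Precision is the percentage of retained predictions
within 3 Å, undefined (None) when nothing is retained.

## Backbone geometry (`loopgeom`)

`backbone_rmsd` is all-backbone-atom (N, CA, C) RMSD after optimal
rigid-body superposition (Kabsch via quaternion solution, proper
rotations only). `dtw_rmsd` aligns loops of unequal length: the moving
loop is superposed on the anchor residues (three terminal residues of
each end, backbone atoms), then dynamic time warping with symmetric steps
runs over squared CA distances; the result is the RMSD over matched pairs
on the minimum-cost path. For equal-length inputs the superposition is
instead the optimal all-CA fit, which makes the diagonal path reproduce
the CA-restricted rigid RMSD exactly and guarantees
`dtw_rmsd ≤ CA RMSD` (warping can only match or beat the diagonal);
mixing the two superposition rules is a deliberate choice so the
equal-length case is exactly comparable to `backbone_rmsd`.

Template clustering is deterministic leader clustering in lexicographic
template-id order at 0.6 Å: a template joins the first cluster whose
representative is within threshold (backbone RMSD if same length, DTW
otherwise), else founds a new cluster. Leader clustering was chosen over
linkage methods for order-stability and exact reproducibility; the
threshold, metric choices and anchors are configurable.

## Repertoire statistics (`profiles`)

Usage profiles are relative cluster frequencies over sequences with a
retained template prediction; structural coverage divides by all in-range
sequences. Quality rules: a repertoire is removed when its two most
redundant clusters exceed 80% of its sequences (PCR amplification
artefact; 0.80 exactly is retained) or when fewer than 10,000 sequences
carry predictions. Richness is averaged over 100 subsamples of 10,000
sequences drawn without replacement (multivariate hypergeometric, seeded).
Entropy is natural-log Shannon entropy over represented clusters,
normalized by ln(richness); the normalized ratio is base-invariant. A
single-cluster repertoire has normalized entropy 0 (zero diversity); the
degenerate empty profile is flagged and reported as 1 by convention.

The embedding is a two-component PCA of the mean-centred, unscaled
frequency matrix (frequencies are already commensurate; standardization
is optional). The ε-sweep runs Euclidean DBSCAN (min_samples 3) on the
raw frequency vectors — PCA is visualization only — over a strictly
increasing ε grid (default 0.01–0.60 step 0.01); each repertoire's
join-ε is the smallest ε at which it shares a cluster with the majority
of the designated reference repertoires.

## Structural Stems (`stems`)

For each (B-cell type, isotype) group, one randomized dataset per
repertoire: 10⁶ template picks with replacement, lengths following that
repertoire's CDR-H3 length distribution thinned by the group's
per-length modellable proportion, templates uniform over the set the
repertoire actually used. Randomized datasets are materialized as count
vectors (never as explicit records). Per cluster, two one-sided
Mann–Whitney tests on per-repertoire relative usage ("relative" because
repertoires differ in size) against the randomized profiles: over ⇒
STRUCTURAL_STEM, under ⇒ UNDER_REPRESENTED, neither ⇒ RANDOM_USAGE, at
α = 0.05 with no multiple-testing correction by default (a
Benjamini–Hochberg option exists). The exact permutation null is used
when both groups have ≤8 members and no ties (so complete 4-vs-4
separation gives p = 1/70 ≈ 0.014); otherwise the normal approximation
with continuity correction and midranks. The two one-sided calls are
mutually exclusive at any α < 0.5; this is asserted on every run. The
two tests are run jointly, not hierarchically.

## Synthetic data (`synthdata`)

Shape families are helical arcs sampled at ~3.8 Å CA spacing, with N/C
atoms at fixed local-frame offsets; family geometry (turn angle, rise) is
varied on a grid so that same-length families are >1.5 Å apart
(backbone RMSD) and cross-length families >1.0 Å apart under DTW — the
lower cross-length floor reflects that warping is inherently more
permissive, while both floors stay far above the 0.6 Å clustering
threshold; separation is verified at generation time and violations are
fatal. Members perturb the family backbone by Gaussian noise (σ = 0.04 Å,
well under 0.3 Å member spread) and differ by at most one loop
substitution from the family consensus.

Repertoires draw cluster usage from a Dirichlet with configurable
concentration — one shared vector per group for naive-like groups,
per-repertoire draws for differentiated groups — with planted stem
clusters multiplied by the enrichment factor and renormalized. Sequences
are germline V + template loop + J tail with independent per-residue
point mutations at the group's SHM rate; each sequence uses the germline
coupled to its template's framework, the way a clone keeps its framework
context. High SHM therefore degrades ESS scores and coverage, an
emergent check of the coverage-vs-maturation behaviour.

The default mini study (12 repertoires × 20,000 sequences over a
300-template, 60-family library; naive/memory/plasma groups with SHM
0.5%/2%/4%, stem enrichment 5×/3×/none) is sized so the full pipeline
runs in a few minutes on one CPU while every planted quantity is
comfortably recoverable. What the generator does *not* emulate: real
V(D)J recombination, indels, sequencing error profiles, realistic loop
conformations, or the true SHM positional bias — so passing tests
demonstrate that the pipeline's statistics recover planted structure
under its own generative assumptions, not performance on real Ig-seq
data. Real-data workflows (AIRR TSV in, annotation TSV out) are supported
but carry no accuracy claims here.

## Degenerate inputs and tie-breaks

Deterministic tie-breaks throughout: lexicographic class ids (canonical),
lexicographic template ids (prediction and clustering), first-maximum in
vectorized argmax scans. Empty length buckets predict NONE; empty
calibration bins get +∞ cutoffs; zero-modelled repertoires yield empty
profiles with coverage 0; clusters absent from both observed and
randomized data are RANDOM_USAGE with p = 1 and flagged. All stochastic
steps take explicit seeds; identical inputs and configuration give
byte-identical outputs.
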