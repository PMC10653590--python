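# Methods

This note documents the models and procedures implemented in `ormine`,
the parameter choices that matter, and the limits of what the test suite
establishes.

## Profile scan

Each OR family profile is a position-specific scoring matrix over the
amino-acid translation of its seed alignment. Columns with more than 50%
gaps are dropped (match-state selection); emissions are log-odds in bits
against a uniform background with a 0.5 pseudocount. Unknown residues
score 0; an in-frame stop in a translated genome frame scores −6 bits —
a strong penalty that still lets stop-disrupted pseudogenes be found.

Scanning works on all six reading frames of each contig, in profile
blocks of 50 columns. Blocks, rather than whole profiles, are the unit of
matching because disrupted loci (frameshift: match split across frames;
truncation: only a prefix present) never carry a full-length diagonal
match. Per block, every ungapped offset is scored; an offset is a hit
when its normal-approximation E-value (block score vs. the analytic
background mean/sd, Bonferroni-scaled by the number of scanned offsets)
is at most 1e−10. Two refinements were required in practice:

* **Non-maximum suppression.** TM columns are hydrophobic and
  self-similar, so a genuine match is surrounded by weaker matches at
  small shifts; only locally best offsets (radius = half a block) are
  kept.
* **Envelope from the best family only, one hit per block.** All
  families are homologous and co-hit each locus at slightly shifted
  offsets. Merged loci therefore take their boundaries from the
  best-scoring family, keeping only the single best match per profile
  block. Without this the envelope overflows by tens of nucleotides —
  enough to push a 600-nt truncated pseudogene past the 650-nt length
  rule.

Block hits on one contig/strand merge into a locus when they overlap or
lie within 60 nt; this also fuses the two frame-segments of a
frameshifted gene into one candidate. Hit sequences are strand-corrected;
coordinates are 0-based half-open (BED convention). Antisense partial
matches of TM-rich segments occasionally produce a short extra locus on
the opposite strand of a real gene; these classify as short pseudogene
fragments, which mirrors how real pipelines count fragments.

Redundancy merging is greedy and longest-first (ties by contig, start):
a candidate joins the earliest representative with global nucleotide
identity ≥ 0.98 (identity = matches / alignment columns), matching the
threshold used in the literature to fold alleles and assembly duplicates
into one gene. Order-fixing makes the clustering deterministic.

## Non-OR filter and family assignment

Profile search recovers close non-OR GPCRs (melanocortin, trace-amine,
serotonin receptors…). Each deduplicated candidate is placed on a
neighbour-joining tree (amino-acid p-distances, BLOSUM62 global
alignments) together with the full reference panel — verified OR
proteins (two per family) and non-OR GPCR outgroups. The tree is rooted
on the non-OR references; the candidate is kept iff its smallest
enclosing clade that contains a reference contains an OR-labelled one.
Distance methods park intermediate taxa on the stem between the two
reference clades; when that happens the attachment clade is an *entire*
label set and carries no information, so the verdict falls back to the
nearest reference's label. With that rule the panel self-test (each
reference held out and re-filtered) separates perfectly. NJ on
p-distances was chosen over per-candidate ML trees for determinism and
speed; `tree_builder` accepts a drop-in replacement.

Family assignment is best-profile scoring with chained block scores
(each block may jitter ±8 residues, negative blocks floor at 0). Ties
break lexicographically; calls below the score floor are `unassigned`,
flagged but never dropped.

## Functional classification

A candidate is a **pseudogene** iff it has a premature stop, a
frameshift, or length < 650 nt (inclusive bound: 650 passes — the
minimum length able to encode seven TM helices). Evidence is anchored on
the best family's seed CDS: a global nucleotide alignment with harsh gap
penalties (open −16, extend −4; a gap must reflect a real indel, not a
cheap escape from a mismatch run), terminal stop stripped from the
reference, and indels within 12 nt of the aligned core's ends ignored as
terminal raggedness. Interior indels with length ≢ 0 (mod 3) are
frameshifts. Premature stops are read codon-by-codon in the reference
frame, so post-frameshift stops are assessed in the biologically
relevant register. When no reference aligns at ≥ 0.50 identity per
alignment column (unrelated sequences align near 0.40 under these
penalties, homologs above 0.65) the evidence is unanchored and the stop
check falls back to the longest-ORF frame.

Disruption-free sequences are **functional** only with exactly seven
predicted TM helices, else **sub7TM**. The TM counter is a deterministic
Kyte–Doolittle hydropathy scan — window 19, threshold 1.6, helix runs
shorter than 15 discarded, gaps under 5 merged — and is a declared
stand-in for trained TM predictors; `classify_status(tm_counter=...)`
accepts any replacement. All TM tests use planted-helix synthetic
proteins, not real OR biology: a green test shows the scanner finds what
was planted, not that it matches deepTMHMM on real receptors.

Alignment-column trimming keeps a column iff its missing fraction
(gaps + unknowns) is ≤ 0.8, boundary inclusive; the operation is
idempotent and preserves rows.

## Repertoire tables

`summarize` produces species × (13 per-family functional counts, sub7TM,
pseudogene, removed-non-OR, totals, fractions). Two fraction conventions
are computed because both occur in the literature and differ whenever
sub7TM counts are non-zero: `fraction_functional` = functional / (functional
+ sub7TM + pseudogene) and `fraction_functional_fp` = functional /
(functional + pseudogene). Class I is families 51/52/55/56. Family
proportions divide by the species' functional total; optional column
rescaling to mean 1 gives each family equal weight for ordination and
multivariate fits. Medians use the mid-mean convention for even counts.

## Comparative models

All likelihoods profile the root state (GLS mean) and the rate σ²
analytically, so only one parameter is ever optimized numerically.

* **Pagel's λ** scales the off-diagonal phylogenetic covariance;
  bounded scalar optimization on [0, 1] (endpoints checked explicitly,
  boundary estimates flagged), LRT against λ = 0 on χ²₁. λ = 1
  reproduces the BM likelihood to numerical precision by construction.
* **BM** has the closed-form GLS solution; a rate indistinguishable from
  zero at double precision (constant trait) is reported as a flagged
  boundary with σ² = 0.
* **OU** uses the stationary form for ultrametric trees: tip covariance
  (σ²/2α)·exp(−α·d_ij) with tip expectation equal to the optimum of the
  tip's regime; α is optimized on a log scale over [1e−4, 1e3] in units
  of 1/tree-depth. Non-ultrametric trees are rejected (a non-stationary
  OU would be needed and is out of scope). AIC counts 2 parameters for
  BM and 2 + #regimes for OU.
* **Phylogenetic Tukey** contrasts are GLS group means under σ²C with
  the unbiased (n − g) variance denominator; all-pairs z statistics are
  adjusted single-step by seeded Monte Carlo on the contrast correlation
  matrix (50,000 draws by default; Holm available as a deterministic
  fallback). Adjusted p-values are clipped to never fall below raw ones.
  On a star tree the whole procedure reduces exactly to its OLS
  counterpart, which the tests exploit as an oracle.
* **Multivariate fits** use matrix-normal GLS: BM, single-optimum OU,
  one-factor regime OU, or an additive all-factors OU design; ranking is
  by AIC (the multivariate penalty counts mean parameters × traits plus
  the trait covariance; the criterion used is recorded on every fit —
  a generalized information criterion could be slotted in, but with
  n > p throughout, AIC is the default). The regime effect is summarized
  by a Pillai trace on GLS-whitened data with the asymptotic n·Pillai ~
  χ²(p·q) reference — adequate for ranking and description, not exact
  small-sample inference.
* **PCA** is the eigendecomposition of the (by default) correlation
  matrix; signs are fixed by making each component's largest-magnitude
  loading positive, so results are platform-reproducible.
* **Ancestral states** are BM BLUPs z₀ + c'V⁻¹(x − z₀) with the GLS
  root estimate plugged in; reported variances include the extra
  root-estimation uncertainty. A constant trait returns that constant
  everywhere with zero variance.

Species names are reconciled between trees and trait tables by exact
match after underscore normalization; any mismatch is an error, never a
silent drop.

## The synthetic world

The generator fixes one GPCR ancestor protein (310 aa: seven 25-residue
strongly hydrophobic TM blocks separated by strongly polar loops), from
which an OR ancestor and a non-OR ancestor diverge by 10% each; the 13
family templates and the 11 GPCR decoys then diverge another 10% from
their respective ancestors. The two-ancestor design makes the non-OR
references a genuine sister clade — with a basal decoy "star" the
NJ filter misplaced held-out decoys. TM-block substitutions are drawn
from hydrophobic residues only, so the hydropathy stand-in labels every
intact template functional; this coupling to the TM scanner is
deliberate and means TM tests validate the planted construction, not
real membrane-protein prediction.

Planted genes are independent *paralogs*: each plant back-translates its
family's template protein with its own synonymous codon draw (~70%
pairwise nucleotide identity), then applies the requested nucleotide
divergence and one operator. Without the per-plant codon draw, same-family
plants are > 98% identical at low divergence and the redundancy merge
collapses them — alleles and paralogs would be indistinguishable.
Divergence substitutions never create in-frame stops and keep TM
residues hydrophobic (the nucleotide-level analogue of purifying
selection on the reading frame and the membrane domains), so a plant's
intended status is preserved by construction at any divergence; operator
plants (stop/frameshift/truncate) take unconstrained divergence since
their intended status is pseudogene regardless. Genome background is iid
nucleotides at a stated GC (default 0.42) — sufficient to test
specificity, silent about repeats, isochores and assembly artifacts.

The canonical recovery suite plants 20 genes in 200 kb: 10 intact (3 on
the reverse strand), 4 stop-disrupted, 3 frameshifted (1-nt indels),
2 truncated below 650 nt, and 1 non-OR decoy. The pipeline recovers all
20 intended statuses at divergence 0 and ≥ 95% at 10% (in practice
20/20 across every genome seed tried).

Trait simulation is exact multivariate-normal sampling from the stated
covariance (BM with λ applied off-diagonal, or stationary OU), so
simulation-based tests check estimators against their own generative
law, with no discretization error.

## Known limitations

* The TM stage is a hydropathy heuristic; real sub7TM rates depend on a
  trained predictor and are not reproduced here.
* The non-OR filter's NJ trees are fast approximations of per-candidate
  ML trees; the stem-attachment fallback is a pragmatic rule, and the
  verdict of a representative is propagated to its cluster members.
* Frameshift detection needs an alignable reference (≥ 0.50 column
  identity); unanchored candidates can only be stop- and length-checked.
* The multivariate ANOVA χ² reference is asymptotic; p-values near
  thresholds should not be over-read at small n.
* Synthetic genomes contain no repeats, pseudo-exons, or sequencing
  error, so specificity results bound only the iid-background case.
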