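# Methods

## Data model

A screen is a set of records (gene, structure, optional domain, SWEP) over a
fixed ordered stage axis (default the four Hamburger–Hamilton stages HH18,
HH22, HH26, HH28; any K ≥ 1 ordered stages are supported and all downstream
math is written for general K). A SWEP is a length-K binary detection vector;
the all-zero vector is not a legal record — never-detected genes simply have
no records, and appear only in the gene-metadata table with category
`not-detected`. The expression category of a gene (`tissue-restricted`,
`ubiquitous`, `not-detected`) is taken from the supplied metadata, not
recomputed: in the assays this package targets, "ubiquitous" is an
annotator's judgement, and re-deriving it from scored structures would
silently change its meaning.

## Fill-in correction

Non-contiguous SWEPs (`1101`, `1001`, …) are interpreted as detection error
at the internal stages: every position strictly between the first and last
detection is set to 1. The operation is idempotent, never clears a detection,
and maps the 2^K − 1 non-empty patterns onto the K(K+1)/2 contiguous ones
(16 → 10 at K = 4). It is applied as one explicit pipeline step — never
silently on ingest — so the number of corrected records is reportable. The
correction cannot repair endpoint losses (a dropped first or last detection
shortens the run undetectably); the synthetic-data tests quantify exactly
this: the recovery shortfall equals the endpoint-dropout cases by
enumeration.

Percentages in the class summary are rounded half-up to one decimal, the
printed-table convention of this literature.

## Tissue–tissue distance

Counts per structure pair: N_A, N_B (genes expressed, domains collapsed by
positionwise union of domain SWEPs) and C_AB (genes expressed in both with
equal per-structure SWEPs). Three formulas are shipped, all satisfying
0 ≤ D ≤ 1, D = 0 ⇔ N_A = N_B = C_AB, D = 1 ⇔ C_AB = 0:

| name  | D(A,B)                    | default |
|-------|---------------------------|---------|
| dice  | 1 − 2·C_AB/(N_A + N_B)    | yes     |
| max   | 1 − C_AB/max(N_A, N_B)    |         |
| geom  | 1 − C_AB²/(N_A·N_B)       |         |

Dice is the default as the simplest symmetric form meeting all three
constraints; the constraints alone do not pin down a unique formula, so the
choice is a flag and the tests verify the constraints for every variant by
exhaustive sweep (counts 1..50). A structure with zero expressed genes has no
defined distance (the boundary conditions are vacuous there) and is an error,
not D = 1.

## Neighbor joining

Standard Saitou–Nei agglomeration: Q(i,j) = (n−2)d(i,j) − r_i − r_j, branch
lengths l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2)), distance update
d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2. Implemented in-package because the
pipeline pins behaviours generic NJ routines leave unspecified: ties in Q are
broken by the lexicographic order of the sorted pair of node labels (internal
nodes carry the sorted concatenation of their leaf labels), so output is
byte-deterministic; negative branch lengths are clamped to 0 with a warning
(raw mode available); n = 2 returns a single edge with the distance split
evenly; the final three nodes use the three-point closed form. The tree is a
scikit-bio `TreeNode` (trifurcating root = unrooted convention) and
serializes to Newick at configurable precision. Tests check exact recovery of
topology and branch lengths on random additive matrices (4–8 leaves) and
topological agreement with scikit-bio's independent NJ on generic matrices.

## Acquisition trends

Per structure, after fill-in: totals[s], newly_added[s] (first detection at
s) and pre_existing[s] (detected at s−1 and s). Contiguity guarantees
totals = newly_added + pre_existing for s ≥ 2; pre-existing at the first
stage is undefined and reported as absent. The trend classifier is an
explicit heuristic over the verbal trend descriptions, with fixed rule order
(first match wins) and one tunable θ (default 0.75, the fraction of the peak
below which the final total counts as "declined"):

1. accumulating — totals non-decreasing and newly_added non-decreasing over
   stages 2..K (stage 1 is excluded since newly_added[1] = totals[1] by
   construction; the gut-like archetype 5/9/20/34 with new 5/4/12/14 is the
   motivating case).
2. early_peak_decline — peak at stage 1 or 2 and totals[K] < θ·peak.
3. late_surge — newly_added[K] > newly_added[K−1].
4. mid_peak — peak at stage 3.
5. otherwise unclassified.

Whole-embryo profiles union each gene's SWEPs over all structures. Counting
genes vs distinct (gene, domain) patterns is a flag (`count_patterns`);
default counts genes.

## Co-expression and pathways

Breadth: per gene, distinct structures and distinct (structure, domain)
patterns. Co-expression cluster of a domain: its genes partitioned by SWEP,
largest class returned (tie → lexicographically smallest SWEP string), full
partition kept. Pathway distributions count a multi-category gene once per
category — multi-pathway membership is surfaced, not resolved — with
fractions over annotated genes only and the unannotated count reported
separately. The permutation enrichment test (uniform |set|-sized draws from
the background, p = (1+hits)/(1+n_perm)) is an optional extra, not part of
the core descriptive analysis; with a small-integer count statistic its
p-values are conservative (super-uniform) under the null, which is what the
tests assert.

## Synthetic screens

The generator emulates the statistical shape the analysis assumes:

- **Layout** — structures in germ-layer-like groups; default three groups of
  3+2+2 (ectoderm-like NS/OV/eye, mesoderm-like somites/limb, endoderm-like
  liver/gut), chosen so the clustering analysis has a planted truth to
  recover. Other layouts (e.g. adding an outlier heart-like structure) are a
  config away.
- **Composition** — ~25% tissue-restricted, 2% ubiquitous, 72.7% silent of
  400 genes by default, the composition reported for screens of this type.
- **Cohorts** — each restricted gene gets a home group and one true
  contiguous SWEP from its group's onset × persistence distribution
  (truncated at the window end); it is expressed with that SWEP in each
  home-group structure with probability 0.6 and each foreign structure with
  probability 0.1. The three groups' onset/persistence defaults are tuned to
  the three trend archetypes (early-peaking, mid-peaking, accumulating), and
  ubiquitous genes span all stages in all structures.
- **Noise** — each detected stage is dropped independently with probability
  0.05 (false negatives only; in this assay class spurious staining is far
  rarer than missed detection, and false positives are off by default).
  Records losing every stage vanish, as unscored observations would.

Everything is reproducible from one integer seed. What the generator does
*not* emulate: spatial signal, staining intensity, annotator disagreement,
correlated (batch) dropout, or any real gene-pathway association (the planted
pathway map is independent of cohorts). Passing tests therefore demonstrate
the pipeline's correctness and its robustness to independent stage-level
dropout — not performance on real screens with structured error.

## Problem sizes and empirical behaviour

The standard simulation (400 genes, 7 structures, 5% dropout) yields ≈ 270
records of which ≈ 1% need fill-in; NJ on the Dice matrix makes all three
planted groups monophyletic in ≥ 95 of 100 seeds, and the tests assert
exactly that. Trend-label recovery is noisier: with ~20–30 expressed genes
per structure the strict monotonicity required by "accumulating" is fragile
under sampling noise, so planted archetypes are reported per structure
rather than asserted globally. Recovery of individual SWEPs after fill-in
sits around 90% at 5% dropout, the shortfall being exactly the
endpoint-dropout cases fill-in cannot see.

## Known limitations

- The trend classifier is a heuristic; its labels depend on θ and on cohort
  size, and it is defined only for four-stage designs.
- The distance is undefined for structures with no expressed genes; callers
  must filter them (the pipeline does).
- Identical-SWEP matching is exact; near-miss timing (off-by-one onset) is
  counted as non-identical, which under dropout slightly inflates distances
  uniformly rather than biasing particular pairs.
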