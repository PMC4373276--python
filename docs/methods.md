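# Methods

## Voxelization of reported peaks

Published activation coordinates are points in MNI millimeter space; the
literature does not agree on a single rule for turning them back into
voxelwise "activation present/absent" calls. We stamp a hard sphere of
radius `sphere_radius` (default 10 mm) around each peak and mark every
in-mask voxel whose center falls inside any of a study's spheres. The
radius trades spatial specificity against tolerance for peak-reporting
variability; 10 mm matches common practice in coordinate-based
meta-analysis. A study's row in the activation matrix is the OR over its
peaks, so duplicate or reordered peaks are harmless. Analysis resolution
is a configuration knob (tests and the bundled demo use an 8 mm synthetic
ellipsoid mask so suites run in seconds; real corpora would use a 2 mm
MNI-space mask supplied as NIfTI).

## Reverse-inference maps

For a label ℓ and voxel v the 2×2 table counts studies by activation at v
and membership in ℓ. We use the Pearson statistic Σ(O−E)²/E with df = 1
and no continuity correction — the statistic is implemented directly so a
brute-force recomputation from marginals can serve as an exact oracle. A
zero row or column marginal means no test is possible; such voxels report
p = 1. If any expected cell count is below 1 the test is considered
unreliable and also voided (p := 1, logged). This guard interacts with
corpus size: a voxel active in a member studies of an n-study corpus with
m members has minimum expected count a·m/n when the voxel is exclusive to
the label, so very small corpora can void their own cleanest signal; the
bundled generator sizes labs (7 studies each, n = 48) to sit just above
the guard.

Multiple testing is corrected per map (each label's family is its own
in-mask voxel set) with Benjamini–Hochberg at q = 0.05, delegated to
statsmodels. Survivors with positive association (ad − bc > 0) are mapped
to positive normal deviates, z = Φ⁻¹(1 − p_raw/2); negative survivors are
zeroed by default because these are maps of *preferential* association
(a `signed=True` flag retains them with negative sign). The two-sided to
one-sided-positive conversion is a declared convention: it is invertible,
monotone in the evidence, and keeps all values finite (p is floored at
1e-300).

A term is "present" in a study when its relative frequency is ≥ 0.001
(configurable); an author is "present" when they appear at any position
in the author list. PI status is stricter: last author (highest position;
a single author counts as last) on at least two papers.

## The self-organizing map

Weights are initialized uniformly at random inside the per-voxel
bounding box of the training maps, then trained online: sample a term
map uniformly with replacement, find the Best Matching Unit by Euclidean
distance (ties break to the lowest (row, col)), and move every node whose
grid distance to the BMU is at most σ(t) = σ₀·exp(−t/λ) by the full
learning rate L(t) = L₀·exp(−t/λ). The flat within-neighborhood update is
the printed rule; a Gaussian falloff by grid distance is available behind
`kernel="gaussian"`. Each update is a per-coordinate convex combination,
so weights never leave the bounding box of initialization ∪ data — a
property the tests assert.

Schedule defaults: σ₀ = max(rows, cols)/2, n_iter = 500 × n_maps capped
at 20,000, λ = n_iter/ln σ₀ (so the neighborhood reaches unit radius at
the end of training), L₀ = 0.05. The neighborhood decay bottoms out at
the BMU: once σ(t) < 1 only the BMU is updated, and training continues to
n_iter. That BMU-only tail is load-bearing — on a two-node grid every
σ ≥ 1 neighborhood contains both nodes, so without the tail the nodes
could never specialize to distinct clusters. Grid size may not exceed the
number of training maps (each node should be reachable without
resampling) unless explicitly overridden; full-scale corpora would use a
22×23 grid, the demo uses 2×3.

## Matching, ranking, clustering

The match matrix C is the cosine of every author z-map against every node
weight vector (zeros retained in the author vector; an all-zero author
map yields a zero row and is flagged rather than an error). Standardized
scores pool all entries of C — Z = (C − mean)/sd with sample sd — because
node queries are defined against the distribution of *all* match scores
(Z > 1.96 ≈ top 2.5%), not per-node; per-column standardization is a
config option. Node queries rank by raw cosine and cap at 50 results.

M is the Euclidean distance between rows of C. Ranked lists start with
the author themself at distance 0, then ascend (ties by author id).
Clustering feeds M directly as the dissimilarity to complete-linkage
agglomeration (the default of the standard R implementation this
mirrors); cut-by-k uses the exact-k tree cut, cut-by-height groups
everything merged at or below the cut. Cuts are keyed "h:2.5" / "k:20".

## Collaboration network

Unordered PI pairs are counted over co-listed studies; an edge requires
≥ 2 joint papers (one joint paper is weak evidence of a working
relationship, and the same threshold defines "actual collaborator" for
red-circle marking in ranked lists; ≥ 1 is a config flag). Isolated PIs
remain as nodes. The same-group edge fraction — how often an edge joins
two PIs from the same similarity group — is reported as a diagnostic, not
asserted, since its value is an empirical property of a corpus.

## Synthetic corpora and what they do (not) show

The generator plants recoverable structure at desk scale: 48 studies
(7 regular per PI plus 6 planted joint papers), 6 PIs in two three-lab
cohorts, 8 peaks per study. Every PI owns an exclusive spatial focus
(isotropic Gaussian peaks, σ = radius/2 with radius 10 mm, truncated to
the mask; foci ≥ 24 mm apart within a cohort, cohorts ~63 mm apart, all
centers voxel-aligned so "the focus voxel" is well defined); a fraction
focus_fraction = 0.9 of peaks are focal, the rest uniform over the mask.
Terms span pairs of labs within a cohort — that overlap is what chains a
cohort together on the lattice, while each lab's exclusive territory is
what makes its author map recoverable; terms spanning a whole cohort
dilute their per-voxel counts below chi-square recoverability at this
corpus size, which is why the default term set is pairwise. Joint papers
draw peaks from both PIs' foci. Term frequencies for present terms are
uniform on [0.005, 0.05]; absent terms have no row.

Recovery is assessed as *dominance*: the label's focus voxel is
significant and the map's argmax lies within 2× radius of a planted
focus. Requiring the argmax to be exactly the focus voxel is too brittle
to be informative at 8 mm resolution — a single background peak from a
non-member study can add one count next to the focus and shift a tie by
one voxel without any loss of signal.

What passing does not show: the generator plants clean, well-separated,
isotropic signal with exact authorship and deterministic term membership.
Real corpora have correlated foci, author-name ambiguity, wildly uneven
productivity, coordinate-space mixtures and text-mining noise, so
recovery rates here are upper bounds on real-data behavior; the
generator validates the machinery, not the difficulty of the real
problem.

## Numerical and interface choices

* Chi-square direction is sign(ad − bc); zero marginals return
  (0, 1, 0) as an explicit "no test" signal.
* Optional Talairach→MNI conversion uses the classic piecewise affine
  (small pitch rotation with z-sign-dependent scaling), inverted; the
  default is to drop non-MNI rows with a logged count.
* Study order is sorted study_id everywhere, and author rows of C are
  sorted author id, making every matrix reproducible regardless of input
  row order.
* One global seed fans out to per-stage seeds through a seed sequence;
  pipeline outputs are uncompressed NIfTI plus CSV/TSV/JSON, and each
  stage directory carries its effective configuration and a sha256
  manifest, so reruns are byte-identical.
* Problem sizes in tests and the acceptance script (8 mm mask,
  ~2,700 voxels, 48 studies, 2×3 lattice, 20/10 seed replicates) were
  chosen so the full suite runs in well under a minute while keeping
  every statistical check at realistic operating points (e.g. expected
  cell counts near the validity guard).

## Known limitations

* Author identity is exact string match (with optional whitespace/case
  normalization); no disambiguation.
* The expected-cell guard voids tests rather than switching to an exact
  test; Fisher's exact test would be a natural extension for tiny
  corpora.
* The SOM is the classic online algorithm; batch or growing variants and
  toroidal grids are out of scope.
* Clustering significance is not assessed; cuts are descriptive.
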