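# Methods

This note documents the models and procedures netpharm implements, the
conventions and defaults it adopts where several are defensible, what
the synthetic generators do and do not emulate, and the known
limitations of the pipeline.

## Network topology and the R-statistic

Interaction data are treated as a simple undirected graph: reversed and
repeated edges collapse to one, self-loops are dropped (with a logged
count), and distances are unweighted hop counts.  Per-node statistics
follow the conventions of Cytoscape's NetworkAnalyzer:

* **Average shortest path length** (*Xᵢ*) is the mean BFS distance from
  a node to every *other* node of its own connected component.  For an
  isolated node the quantity is undefined and reported as missing.
  Restricting to the component is an assumption — with a global mean
  over a disconnected graph the statistic would be infinite or need an
  arbitrary imputation, and observed cohort values of exactly 1.00 are
  only possible on a component-restricted mean.
* **Betweenness centrality** (*Xⱼ*) is computed by Brandes accumulation
  with endpoints excluded and normalized by 2/((N−1)(N−2)), N being the
  node's component size, so values live in [0, 1] (components of ≤2
  nodes score 0).

The prioritization score for a cohort of candidate targets is

R = w·minmax(Xᵢ) + (1−w)·minmax(1/Xⱼ),  w = 0.5,

where minmax rescales to [0, 1] over exactly the cohort passed in, not
the full network; smaller R = more central = more important.  Two
numerical choices matter:

* **Betweenness floor.**  1/Xⱼ diverges at 0, so betweenness values are
  clamped below at `xj_floor` (default 1e−5, the order of the smallest
  betweenness a leaf-like target realistically shows on a ~400-node
  interactome).  The clamp preserves the ranking while keeping the
  min–max transform finite.
* **Degenerate cohorts.**  If a cohort is constant on one axis, that
  term contributes 0 for every record rather than 0/0.

Ranking is ascending in R with ties broken by larger betweenness, then
accession lexicographically; the sort is stable so fully tied records
keep input order.  Ties are not otherwise meaningful and the cohort
defines the scale, so R values from different cohorts are not
comparable.

A caveat documented rather than "corrected": in the packaged 48-target
table, a minority of printed R values (ALDH2, SERPINC1, CA1, MMP2 among
others) are not arithmetically consistent with the printed, rounded
topology columns — most plausibly they were computed from unrounded
values.  The test suite asserts only the arithmetically consistent rows.

## Over-representation and pathway impact

Enrichment of a query gene list in a GMT collection uses the one-sided
hypergeometric tail p = P[X ≥ k], X ~ Hypergeometric(M = |universe|,
K = |set|, n = |query|).  The universe defaults to the union of all
annotated genes in the collection — the annotation-restricted semantics
of over-representation tools — rather than the genome; query genes
outside the universe are dropped with a logged count.  Multiple testing
uses Benjamini–Hochberg FDR across all tested sets (the procedure behind
an "FDR" column when none is named); results are filtered at a nominal-p
cutoff (default 0.001) *after* FDR is computed over everything.

Pathway impact scores a set of matched metabolites on a pathway graph as
the matched share of component-normalized betweenness centrality, in
[0, 1].  When no node of the graph has positive betweenness (a single
edge, a triangle), the matched fraction of nodes is used instead so that
a fully matched pathway still scores 1.

## Spectral preprocessing

Bucketing sums grid intensities into half-open bins [left, left + w)
with w = 0.01 ppm over δ [0.50, 9.00), giving 850 raw bins; bins that
intersect an excluded interval (default the residual-water region
[4.5, 5.0), 50 bins) are dropped **before** normalization, leaving 800,
so residual water never distorts row sums.  The left-closed/right-open
convention is an adopted choice; the boundary placement only matters for
resonances sitting exactly on a bin edge.  Each retained row is then
normalized to unit total intensity (total-intensity normalization, the
standard defence against dilution differences).  Row normalization has a
known side effect (closure): if the changed metabolites are a large
share of total intensity, unchanged metabolites acquire an apparent
opposite change.  The synthetic default panel is therefore built with
large unchanged pools dominating the total; see below.

## PLS-DA and OPLS-DA

Class labels are dummy-coded 0/1 and centered; X columns are centered
and scaled — unit variance by default (the convention of the major
commercial package), with pareto and center available.  PLS components
come from NIPALS on the (X, y) pair with deflation of both blocks.
Reported diagnostics:

* **R²X, R²Y** — cumulative explained fraction of X and Y variance.
* **Q²** — 1 − PRESS/SS from 7-fold venetian-blind cross-validation:
  fold *f* holds out samples *f*, *f*+7, … in input order; scaling
  parameters are re-estimated on each training fold.  This matches a
  widely used software convention; Q² ≤ R²Y on every fit.  The
  implementation's Q² agrees with an independent cross-validated PRESS
  computed via scikit-learn's PLS on identical folds to machine
  precision.
* **VIP** — variable importance in projection, with mean(VIP²) = 1
  exactly by construction.
* Automatic component selection (`n_components="auto"`) keeps adding
  components while each raises Q² by more than 0.01, capped at 10.

OPLS-DA implements orthogonal signal correction: `n_orth` components
orthogonal to y are stripped from X, then one predictive component is
extracted.  Its VIP uses the predictive weights (Σ VIP² = p holds); the
S-plot reports, per variable, the covariance and correlation of the
predictive score with the centered, scaled variable.  R²X is split into
predictive and orthogonal parts.

**Permutation validation** refits the model under `n_perm` uniform
label shuffles (default 200; the accidental identity permutation is not
excluded — its probability is negligible) and declares the original
model valid only if every permuted R²Y *and* Q² falls strictly below the
originals.  Note that in-sample R²Y is the weaker of the two statistics:
at variable-to-sample ratios ≳2 a 2-component PLS fits *any* labels to
R²Y ≈ 0.95, so validation of a true but modest effect can fail on the
R²Y clause while Q² separates cleanly.  This is a property of the
criterion, not a defect of the fit.

## Differential-metabolite calling

Each metabolite's intensity is the sum of its assigned retained bins
(assignments map metabolite → chemical shifts; shifts that fall in
excluded regions are ignored, and a metabolite with no retained bins is
skipped with a warning).  A metabolite is called differential when the
maximum VIP over its assigned bins is ≥ 1 **and** a two-sided Student's
t-test (equal variances, per the study-design convention; Welch behind a
flag) gives p < 0.05.  Fold change is reported as the ratio of the
larger group mean over the smaller (≥ 1) plus an up/down direction for
treated vs control.

An operating-characteristic fact worth knowing: with ~800 bins of which
only a few carry class signal, the VIP ≥ 1 condition is implied by the
t-test condition (VIP ≥ 1 corresponds to a variable–class correlation
above the root-mean-square correlation, which is far below the t-test's
α = 0.05 threshold at these sample sizes).  The false-call rate of the
combined rule on truly unchanged metabolites is therefore essentially
the t-test's α, i.e. ≈5% — the benchmark study below measures it at
4.98% over 50 000 null trials.  Users needing stricter control should
lower α or apply BH across metabolites; the default mirrors common
practice.

## Synthetic data

`gen_ppi` wires named hub targets of chosen degree into a random
background interactome (preferential attachment by default, the
scale-free shape of real PPI networks; uniform pairing available).  Hubs
connect to distinct background proteins, so planted degrees are exact.

`gen_spectra` renders each sample as a concentration-weighted sum of
unit-height Lorentzian resonances — the natural solution-NMR line shape —
with half-width 0.002 ppm on a 0.001-ppm grid over [0.50, 9.00), plus
i.i.d. Gaussian noise floored at zero.  Treated-group concentrations are
the control concentration times the metabolite's ratio; ground truth is
the set of metabolites with ratio ≠ 1.  The default panel has 6
replicates per group (a typical cell-metabolomics design), 16 common
cell-extract metabolites at textbook shifts, effect magnitudes echoing
what an effective treatment does to glycometabolism and amino-acid
metabolism (up to ~5-fold), and large unchanged lactate/glucose pools so
that row normalization's closure effect stays small.

What the generator does **not** emulate: J-coupling fine structure,
chemical-shift drift and misalignment, baseline/phasing artifacts,
correlated biological variation between metabolites, and realistic
peak-overlap congestion.  Passing tests therefore demonstrate the
statistical machinery is correct under the stated model, not that the
pipeline is robust to alignment or baseline problems in real spectra.

## Benchmark studies (problem sizes)

The operating-characteristic studies are sized to run on a laptop-class
single core:

* **Recovery study** — 50 replicates of 6+6 spectra with 310 singlet
  metabolites (10 planted at 3× the bin-level noise SD, balanced
  up/down so the nulls are exactly null; 300 unchanged for a precise
  specificity estimate).  Measures sensitivity (~99%) and the false-call
  rate (~5%, the α knife edge discussed above).
* **Permutation study** — 100 replicates of 24 samples × 50 variables,
  with either 15 variables shifted 3 SD (planted) or pure noise, 100
  permutations each.  Planted data validate in ~100% of replicates;
  pure noise in ~1% (≈ the 1/(n_perm+1) chance that the unpermuted
  labels happen to score best).

## Known limitations

* The R-statistic is cohort-relative; adding or removing one candidate
  changes every score.
* Q² uses a single fixed fold scheme rather than repeated random CV;
  with very small cohorts the venetian-blind assignment can matter.
* The hypergeometric test ignores gene-set overlap structure and
  annotation hierarchy.
* Differential calling tests each metabolite marginally; no
  multiple-testing correction is applied across metabolites by default.
* The CLI's OPLS-based differential workflow assumes exactly two groups.
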