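# Methods

## Model and procedure

`corrnets` treats a feature table — *n* samples × *p* features, any
numeric values — as an i.i.d. sample from an unknown joint distribution
over features.  The object of inference is not the joint distribution
itself but the *thresholded rank-correlation network* it induces: the
undirected graph whose edges are feature pairs with |Spearman ρ| at or
above a threshold *t*, and seven summary statistics of that graph.
Because these statistics have no tractable sampling distributions, the
nonparametric bootstrap supplies them: resampling the *n* samples with
replacement *B* times and rebuilding the network each time yields an
empirical distribution for every statistic.

Each replicate is processed independently: Spearman matrix → threshold →
graph statistics.  Nothing is shared across replicates except the source
rows, so the replicate statistics are conditionally i.i.d. given the data
— the property the paired binomial comparison relies on.

## Statistics and conventions

* **Spearman correlation** is computed as the Pearson correlation of
  average (fractional) ranks, the tie-corrected convention of mainstream
  statistics software.  A constant column (common after resampling sparse
  counts) makes the coefficient undefined; such entries are set to 0 —
  they can never reach a positive threshold — and the feature is recorded
  on the matrix and in the run log.  The diagonal is always 1.
* **Thresholding** is boundary-inclusive (|ρ| ≥ t, with one-signed modes
  ρ ≥ t and ρ ≤ −t).  The default t = 0.8 targets strong associations;
  t is restricted to (0, 1].  The node set is the set of edge endpoints:
  isolated features are not nodes, so `n_nodes` varies across replicates
  and carries information.
* **Degree centrality** deg(v)/(N−1) is averaged over nodes.  The average
  equals density 2E/(N(N−1)) exactly — both are computed through the same
  expression so the identity holds to the last bit.
* **Transitivity** is 3·(triangles)/(connected triples), 0 when no
  connected triples exist.
* **Closeness** uses the Wasserman–Faust component correction,
  c(u) = ((k_u−1)/(N−1)) · ((k_u−1)/Σ_v d(u,v)), with k_u the size of u's
  connected component and d the unweighted shortest-path distance.  This
  keeps disconnected graphs — the rule, not the exception, near a high
  threshold — in [0, 1] and comparable with standard library output.
* **Betweenness** is computed with Brandes' single-source dependency
  accumulation over BFS shortest-path DAGs, then divided by (N−1)(N−2)
  (ordered-pair accumulation), equivalent to per-unordered-pair
  normalization by (N−1)(N−2)/2; 0 for N ≤ 2.
* Shortest paths are **unweighted**.  Correlation magnitude styles edge
  width in figures but does not define a metric on the graph; no distance
  transform of a correlation is self-evidently right, so none is imposed.
* All statistics of the empty graph are 0.

## Comparison test

For each metric, replicate *i* of project A is paired with replicate *i*
of project B (requiring equal B), exact ties are dropped (sign-test
convention — a tie is evidence for neither side, and integer metrics tie
often), and k = #{A_i > B_i} is referred to Binomial(n′, ½).  The
two-tailed p-value doubles the smaller tail and caps at 1.  Tail sums are
evaluated in log space via log-gamma binomial coefficients and
log-sum-exp, so the reported `log10_p` is finite even when p underflows
IEEE doubles (an all-wins outcome at B = 500 gives p = 2·(½)^500 ≈
6.1·10⁻¹⁵¹; larger B goes below 10⁻³⁰⁸, printed as "0.0 (below
representable minimum)" with the log10 value as the faithful record).
A metric where every pair ties is reported as untestable rather than
raising.  The direction field is set at two-tailed p < 0.05 with no
multiple-testing correction; all seven raw p-values are exported so any
correction can be applied downstream.

The statistic k/n′ measures *consistency* of a difference across
replicates, not its magnitude: a tiny but systematic difference yields a
statistic near 1 and an astronomically small p.  Bootstrap means and
standard errors (sample standard deviation of the replicate values,
denominator n−1) are reported alongside for magnitude.

## Synthetic data generator

The generator emulates the statistical skeleton the pipeline assumes in
real data: groups of co-varying features plus independent noise features.
Each block draws one standard-normal latent vector per sample; members are
sign·latent + N(0, σ²) with per-block noise σ (`latent_noise_sd`).  A +1
block loads all members identically (all C(m,2) pairs positively
correlated); a −1 block alternates loading signs, planting a mix of
strong positive and negative pairs.  Noise features are independent
standard normals.  Because Spearman is rank-based, Gaussian margins lose
no generality — any monotone marginal transform leaves every rank
correlation unchanged — and σ = 0 plants *exact* ±1 correlations that
survive any bootstrap replicate with ≥ 2 distinct rows.  An optional
exponentiation produces strictly positive, abundance-like tables for
exercising the clr transform.

Defaults, chosen once as realistic small-study conditions: n_samples = 30
(a typical per-group animal-study size), blocks of 4, σ = 0.3 for the
paired designs (within-block ρ comfortably above 0.8 at n = 30 but not
degenerate).  The standard paired fixture plants 12 strong pairs in
design A (two blocks of four) versus 6 in design B (one block), equal
totals of 12 features.  The self-comparison calibration fixture uses
σ = 0.55, placing within-block correlations near the 0.8 threshold so
edge counts genuinely vary across replicates and the comparison statistic
is informative rather than all-ties.

What the generator does **not** emulate: compositional closure,
zero-inflation, sequencing-depth variation, or taxon-specific dispersion
of real microbiome counts.  Passing tests therefore demonstrate that the
machinery recovers known rank-correlation structure and calibrates
correctly under clean conditions; they do not certify behavior under
compositional bias (for which clr preprocessing is provided but not a
cure-all).

A caveat on exact recovery: with several independent blocks and a small
sample count, a bootstrap replicate that retains very few distinct rows
can align two independent latents' tied ranks past the threshold by
chance, adding a spurious cross-block edge.  Exact recovery of *only* the
planted edges on every replicate is guaranteed for a single zero-noise
block; at the default n = 30 it holds for multi-block designs as well
because resamples retain ~19 distinct rows, making such coincidences
negligible.

## Preprocessing

CSV input has samples as rows (first column sample ids); a transpose flag
accepts the other orientation.  Metadata columns are removed only by an
explicit drop list — inferring them silently is error-prone.  Feature
labels are relabeled X1..Xp for legible figures, with the bijection
persisted as a two-column CSV.  The clr transform log(x+c) − mean log(x+c)
(default pseudocount c = 1.0 for counts) is offered as an explicit option
and never applied implicitly; the pipeline itself is agnostic to whether
the input was transformed.

## Reproducibility and numerics

One seed drives all B replicates through a single generator stream; the
CLI records the seed actually used (supplied or drawn from OS entropy) in
`run_config.json`, making every run directory self-reproducing.  In a
two-table comparison the B table resamples with a seed derived from the
A seed (+1 mod 2³¹) so the arms are independent.  Figure layout is a
force-directed embedding with a fixed default seed; identical inputs give
identical SVGs.  Correlation values are clipped to [−1, 1] and matrices
symmetrized to absorb last-bit float asymmetry.

## Problem sizes

Default analyses use B = 100; the package comfortably runs B = 500 on
tables of a few dozen features in seconds, and the bundled verification
(`scripts/acceptance.py`, seeded) exercises B = 500 comparisons, a
200-replicate recovery check, a 200-replicate null control, and 20
self-comparison repetitions at B = 200 per arm in under half a minute on
one CPU.

## Limitations

* No compositionality-aware correlation (e.g. proportionality measures);
  Spearman on clr-transformed data is the supported route.
* No correlation p-value filtering: edges are magnitude-thresholded only.
* Pairwise project comparisons only; no omnibus multi-group test.
* Unweighted shortest paths; no community detection or eigenvector
  centrality.
* Sequential execution; replicates are independent and would parallelize
  trivially, but no parallel backend is included.
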