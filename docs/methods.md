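# Methods

## The question and the model

Transcription factors (TFs) do not bind the genome independently of one
another: some pairs co-occur far more often than chance ("attraction"),
others far less ("repulsion"), both along the linear genome and across
3D chromatin contacts. `chromcooc` detects such pairs from two inputs: a
chromatin-contact map (ChIA-PET or Hi-C anchor pairs) and per-factor
binding evidence (ChIP-seq peaks, or motif instances when no binding data
exist).

The data are represented as two graphs:

* **Interaction network** — nodes are merged genomic regions, edges are
  long-range contacts. Anchors within 2 kbp (end-to-start gap) are merged;
  contacts between regions within 2 kbp are discarded as short-range;
  regions with degree > 20 or length > 30 kbp are removed as merge or
  population-average artifacts. These defaults are tunable
  (`merge_gap`, `min_span`, `max_degree`, `max_length`).
* **Binding map** — a bipartite assignment factor → set of regions bound
  (a peak overlapping a region by ≥ 1 bp creates a link; a midpoint rule
  is available).

Two co-occurrence statistics are counted per unordered factor pair:
**spatial** — for each contact edge (u, v), each ordered assignment of
(i, j) to the two endpoints with i binding one and j the other counts one
(0, 1 or 2 per edge; homotypic pairs count once per edge where the factor
binds both ends); **sequential** — the number of regions bound by both
factors (the diagonal holds each factor's bound-region count).

## The null model

Significance is assessed against binding maps randomized under
degree-class constraints. Each factor-region link is reassigned, from the
same factor, to a region of similar interaction degree: exactly equal
degree for d ≤ 5; within ±2 for 6 ≤ d ≤ 10; any region of degree > 10
otherwise (the class boundaries are a `DegreeClassRule`). The original
region is always a legal target, so classes are never empty. Factor
out-degrees are conserved exactly; a factor never binds the same region
twice within a replicate. Exact classes and the top class have disjoint
candidate pools and are drawn without replacement in vectorized calls;
window-class links (rare under realistic degree laws) are placed link by
link with collision checks, falling back to the original region (with a
warning) if a pool is exhausted. Replicate seeds derive from the master
seed and the replicate index alone, so ensembles are reproducible and can
be consumed as a stream; spatial and sequential analyses of one dataset
can share a single ensemble.

For each pair, two one-tailed empirical p-values are taken over R
replicates (default 1000): p_attract = #{null ≥ observed}/R and p_repel =
#{null ≤ observed}/R, both tails including equality (so their sum is
≥ 1 and p = 0 is possible). Benjamini–Hochberg q-values are computed per
tail across all pairs; a pair is called attracting if q_attract ≤ α
(default 0.05), repelling if q_repel ≤ α, neutral otherwise (a pair
significant in both tails — possible only in degenerate inputs — is
neutralized with a warning). For display, attracting pairs are encoded as
−q and repelling pairs as +(1 − q′), with rows ordered by average-linkage
clustering (the linkage choice is ours; any would do for display).

### Finite-ensemble estimator choices

Two well-known small-sample artifacts of empirical p-values are handled
explicitly rather than ignored:

* **p = 0 in the negative control.** With R replicates, the observed
  count strictly exceeds every null count with probability ≈ 1/R per
  pair-tail even under a perfect null; BH then turns that p = 0 into
  q = 0 and a spurious call. With hundreds of pairs and R in the
  hundreds, roughly half of all control runs would contain at least one
  such artifact. `negative_control` therefore defaults to the corrected
  estimator (k + 1)/(R + 1), which cannot return 0 and is a valid
  p-value at any R; `pair_statistics` keeps the raw fraction as its
  default (the corrected form is a flag) because with strong signals the
  distinction is immaterial and the raw fraction is the conventional
  definition.
* **Ties and uniformity diagnostics.** Co-occurrence counts are discrete;
  assigning ties to both tails makes the p-values superuniform, and a
  goodness-of-fit test against continuous U(0, 1) rejects even a
  perfectly calibrated pipeline (the empirical CDF steps by the modal tie
  mass). `negative_control` therefore also reports `p_*_uniform`
  columns using the randomized tie-breaking transform
  p = (#{>} + U·(1 + #{=}))/(R + 1), which is exactly uniform under
  exchangeability. These columns are calibration diagnostics only and are
  never used for inference.

One structural note: homotypic pairs are informative in spatial mode, but
in sequential mode count(i, i) equals the factor's bound-region count,
which the null conserves exactly — homotypic sequential pairs are neutral
by construction.

## Motif machinery

PWMs (per-position probabilities over A, C, G, T) are read from MEME
minimal files. The information content I = Σ_n (2 + Σ_b W_nb log2 W_nb)
selects one representative per (externally supplied) motif cluster; ties
break lexicographically by name. Window scores are log-likelihood ratios
in log2 units against a background (uniform by default); a pseudocount of
1e-4 is added and rows renormalized before taking logs (the raw matrix is
used for information content), so zero entries never give −∞. A peak's
motif score is the maximum window LLR over both strands.

Instance calling needs P(score ≥ s) under the background: the exact
window-score distribution is built by per-position convolution on an
integer grid (default 1000 bins across the score range, error ≤ L·ε/2
bits), and the hit threshold is the smallest score with p ≤ 1e-4 — the
conventional scanning default. A reader for externally produced FIMO TSV
output is provided for users who need bit-compatibility with that tool.

The strong-motif analysis asks whether peaks in spatially isolated
regions (no overlap with any network region, or a degree-0 region) carry
stronger motifs than peaks in interacting regions. "Strong" means at or
above the factor's own 90th score percentile (ties included; factors with
< 10 peaks are flagged as unstable). A refinement splits interacting
peaks by whether a spatial neighbour region is bound by the same factor.

## Downstream statistics

* 2×2 enrichment (PPI lists, domain-derived "potentially interacting"
  pairs, gene sets) uses the exact hypergeometric upper tail
  P(X ≥ a) with population a+b+c+d, successes a+b, draws a+c; degenerate
  margins return p = 1 with a warning. "Avoiding" means called repel
  (not merely not-attracting).
* Target genes: factor f targets gene g if f binds a region within 2 kbp
  of g's TSS, or binds a region with a contact edge to such a region. A
  gene is a group target when ≥ 5 distinct factors of one group and ≤ 3
  of the other target it (the stricter 3/0 variant is a parameter).
* TSS distances use the peak midpoint to the nearest TSS (nearest-edge
  distance is a flag; the anchor choice is ours).
* Shortest-PPI-path internal nodes: for each factor pair, a node is
  internal if it lies strictly between the endpoints on at least one
  shortest path (union over all shortest paths, computed from
  d(a,x) + d(x,b) = d(a,b); the union avoids arbitrary tie-breaking).
  Only nodes from a supplied annotated-TF list are counted, once per
  pair, aggregated by pair category.
* The consensus network keeps pairs called attracting in at least two of
  the supplied call tables (classically spatial/sequential × binding/
  motif).

GO-term and trait enrichment are not reimplemented: the per-group target
gene lists and background are emitted for external tools, whose term
databases are versioned services.

## Synthetic data: what it emulates and what it does not

The `synth` module generates complete, file-format-faithful datasets with
known ground truth.

* **Network**: regions on a synthetic chromosome with lengths 500–2000 bp
  (real Pol-II contact regions are mostly < 1 kb) and gaps > 2 kbp, so
  the construction filters are no-ops on re-ingestion; edges realize a
  degree law (Poisson(3) truncated at 20 by default; fixed-k and
  user-supplied sequences too) by stub pairing with swap repair, so
  degree sequences are met exactly.
* **Bindings**: the contact graph is partitioned into clusters of ≤ 20
  connected regions (randomized BFS); clusters are assigned to group 1 or
  group 2 until each covers 10% of regions. A group-g factor binds
  matching-cluster regions with probability p·attract_boost, opposing
  clusters *and regions in contact with them* with probability
  p·repel_damp/attract_boost (so the cross-group co-binding odds on a
  compartment contact are damped by repel_damp; without the contact halo,
  boundary edges would leak cross-group co-binding), and everything else
  at a baseline solved so the expected marginal is exactly
  p = base_bind_prob (0.05 by default — a factor binding ~5% of regions
  is a realistic ChIP-seq scale). Each factor's bound set is finally
  thinned or topped up to an exact Binomial(n, p) draw, pinning marginals
  while preserving the dependence structure. Two factors are left
  ungrouped by default as internal negative controls. With
  attract_boost = repel_damp = 1 the generator reduces to independent
  uniform binding (the null condition). The pair-level co-occurrence
  enrichment that results is an emergent quantity (a few-fold for the
  default boost of 8), checked by sampling, not asserted analytically.
* **Motif datasets**: equal numbers of isolated (degree-0) and pairwise-
  interacting regions over i.i.d. uniform sequence, with one exact
  consensus insertion per region at rate p_iso (isolated) vs p_int
  (interacting).

What passing tests on these data do **not** show: real chromatin has
distance-dependent contact probabilities, locus-specific sequence
composition, peak-calling noise, and binding that correlates with
accessibility rather than clean latent compartments. The synthetic
results demonstrate correctness and calibration of the statistics, not
biological performance.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise the statistics
meaningfully: 2000 regions / 20 factors with 200–500 randomization
replicates for calibration and recovery (the 1000-replicate default
remains for real analyses), 500-replicate audits on ~200-region toys, 20
negative-control runs, and 20–100 seeded motif-direction runs. Cell-line
scale results from the original datasets (tens of thousands of regions,
60+ factors) require the corresponding public downloads and are out of
scope for the bundled checks.

## Known limitations

* The ±2 degree window and the open > 10 class only approximately
  preserve the degree profile for high-degree links; factors whose
  binding is strongly degree-loaded inside those windows can acquire a
  small systematic bias (the exact classes, which dominate under
  realistic degree laws, are preserved verbatim).
* Empirical p-values are bounded below by 1/R; claims about q-values far
  below 1/R require proportionally larger ensembles.
* The single-pass degree/length filter does not re-check degrees after
  removal (an iterative flag exists); the order short-range-filter →
  degree-filter is a documented choice, as the construction is not
  order-invariant in general.
* Randomization-test calls respond to any realized correlation in the
  observed map, including chance alignment of an unplanted factor with
  planted structure; false-discovery control holds in expectation, not
  per realization.
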