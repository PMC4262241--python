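# Methods

## Model and assumptions

`netdriver` treats a global functional-coupling network as the prior on
which somatic alterations act. Its working assumption is that driver
alterations in one tumor genome perturb a small number of pathways, so
driver genes are (a) unusually connected to the *other* altered genes of
the same genome and (b) unusually connected to known cancer pathways,
whereas passenger alterations fall on the network at random given their
degree. All edges are treated as undirected, unweighted and equally
reliable above the chosen confidence cutoff; edge weights are used only as
a load-time filter.

The enrichment statistic for a query gene *i* against a gene set *G* is
the z-score of the observed link count against its distribution over
degree-preserving network randomizations. Conditioning on the degree
sequence is the crux: interactome degrees are heavy-tailed, and an
unconditioned null would declare every hub a driver. Two link metrics are
supported — direct edges (default) and shared neighbours summed over
query–member pairs, useful when the network is sparse and direct edges are
rare. The query is always excluded from the target set, so membership of
*i* in its own MGS or pathway never inflates the count.

## Null model

Randomization is by repeated double-edge swaps: two edges (a,b), (c,d) are
replaced by (a,d), (c,b) unless a self-loop or duplicate would result.
Each replica performs 100 successful swaps per edge (configurable), well
past the point where edge identities decorrelate (the edge-set Jaccard
overlap with the original is ~1.4% on a 1000-node scale-free graph); a
proposal budget of 10 attempts per requested swap guards against rigid
graphs (a star admits no swaps at all), where the walk stops with a
warning rather than spinning. The swap kernel operates on integer edge and
adjacency-slab arrays (numba-compiled) so that full cohort runs — 25
replicas of a several-thousand-edge network — complete in seconds.

Null moments use the sample mean and sd (ddof = 1) of the count over the
25 replicas (the default replica count; more reduce the Monte-Carlo noise
of the sd at linear cost). One replica ensemble per (network, seed) is
cached and reused by every test in a run, which both matches the
per-network character of the randomization and makes cohort-scale runs
tractable. When the null sd is zero (rigid toy graphs), z is defined as 0
if the observed count equals the null mean and as ±40 otherwise; the
normal tail of |z| ≈ 40 underflows double precision, so component p-values
are floored at 1e-300 (with a logged warning) before entering Fisher's
combination.

### Calibration and its limits

On a fully rewired network, z for random gene/set pairs should be roughly
standard normal. Two caveats, both visible in our calibration tests and
worth knowing when reading small p-values:

* the sd is estimated from 25 replicas, so z has t-like tails
  (P(|t₂₄| > 1.96) ≈ 6.1%, not 5%);
* when the expected link count is well below 1 (small target sets on
  sparse networks) the integer count makes z strongly right-skewed, and
  the |z| > 1.96 rate drifts to ~8–10%.

Calibration tests therefore use pathway-sized target sets (120–200 genes,
comparable to real cancer super-pathways), where the exceedance rate sits
at ~5–6%. For genuinely tiny sets the one-sided p should be read as a
ranking score rather than an exact tail probability — which is also how
the combined p-values are used downstream (ranking and prioritization,
with the BH-adjusted threshold as the confidence gate).

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `n_rand` | 25 | rewired replicas behind every null moment |
| `swap_factor` | 100 | successful swaps per edge per replica |
| `tau` | 0.35 | |log2 copy-number| call threshold (strict >, both tails) |
| `min_genomes` | 3 | genomes with a call needed for CNA eligibility |
| `MIN_MGS_SIZE` | 3 | mapped MGS genes required by the genome-local tests |
| `alpha_co` | 0.01 | raw-p gate of the CNA/point co-occurrence screen |
| `normalization_factor` | 10.16 | divisor of the summed cancer-pathway z |
| `z_cutoff` | 2.97 | normalized-z significance cutoff (≙ FDR 0.1) |
| `fdr_threshold` | 0.01 | BH-adjusted combined-p driver threshold (strict <) |

Design choices where the procedure was genuinely open:

* **Top-level combination.** The three CNA evidence streams (co-occurrence,
  combined 1CNA-vs-MGS, 1-vs-CPW) are combined with Fisher's formula, the
  same device used at every other level; components unavailable for an
  event (e.g. a too-small MGS) are dropped and the degrees of freedom
  shrink, rather than being imputed as p = 1 — a gene in a 2-mutation
  genome can still be called through its pathway connectivity alone.
* **Co-occurrence multiplicity.** The screen keeps the stated raw-p < 0.01
  gate; the reported `p_co` entering combination is the
  Bonferroni-corrected minimum over tested partners (candidate×partner
  pairs are many and correlated; Bonferroni is the conservative choice).
  CNA–CNA pairs are never tested: physically linked segments co-occur
  trivially.
* **Sidedness.** Enrichment is directional, so all NEA p-values and the
  co-occurrence test are one-sided upper tails by default; a two-sided
  convention is available. Both the z = 2.97 (one-sided p ≈ 0.0015) and
  z = 1.97 (two-sided p ≈ 0.049) thresholds are exposed, since the
  FDR-bridge convention differs between the pathway test and the benchmark.
* **Multiple testing.** "Adjusted" means Benjamini–Hochberg within each
  event class (point events; CNA genes), with a strict `<` at 0.01 — a
  BH-adjusted p of exactly 0.01 is not called.
* **CPW sum.** Negative per-pathway z-scores are included in the 1-vs-CPW
  sum by default; setting `floor_negative` clips them at zero. The 10.16
  factor is the regularization fitted for a heavily overlapping,
  15-pathway cancer collection; for collections with little overlap the
  summed-z mode is conservative, and the `superpathway_only` mode — one
  test against the designated umbrella pathway, directly interpretable —
  is the appropriate alternative (it is what the small-MGS rescue test
  uses).

## Network benchmark

Candidate global networks are compared by leave-one-out pathway-membership
recovery: each member's z against the rest of its set is paired with the z
of a degree-matched non-member (relative ±10% degree window, geometrically
widened only when empty; substitutes may repeat but never equal a member
of the tested set). The ROC sweeps decreasing z thresholds, terminates at
z = 1.97, and is summarized by Y/X at the first point where X/(X+Y) ≥ 0.1
— a deliberately conservative empirical FDR under the 1:1 paired design.
The area under the curve is not reported: the termination makes it
incomparable across networks. Perfect curves (X = 0) have undefined,
flagged ratios; when two networks are both flagged, ties break on the
true-positive count, so "more members recapitulated at equal purity" wins.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, not
tumor biology. Defaults (chosen once as a realistic desk-scale regime):
a 1000-node Barabási–Albert network (mean degree 6; heavy-tailed degrees
like real interactomes), 5 planted disjoint modules of 15 genes with
intra-module edge probability 0.6 (dense but not clique-like pathways),
50 genomes each drawing 5 drivers from one or two modules plus 20 uniform
non-module passengers (a mid-sized-exome mutation burden with a realistic
driver fraction), and per-module copy-number segments of 8 genes at
amplitude ±0.6 with N(0, 0.1) measurement noise, carried by 5 genomes
whose MGSs also receive 3 mutations among the driver's module partners (so
co-occurrence is detectable). All randomness derives from one master seed
with labelled per-stream derivation.

What it does **not** model — and hence what passing tests do not show
about real data: mutational signatures and hotspot effects, subclonality
and purity, gene length and replication-timing biases, overlapping
pathways, edge noise in the network, and identifier-mapping loss. The
planted modules are disjoint by construction, which is why the benchmark
and rescue analyses treat the module collection directly as the CAN
category.

## Numerical conventions and degenerate inputs

* Gene symbols are uppercased at load; unmapped query genes raise errors,
  unmapped set members are ignored (and reported by `mapped_members`).
* Duplicate and reversed edges collapse on load; self-loop lines are
  dropped with a warning; directed inputs are symmetrized.
* The CNA threshold is a strict inequality: |log2| = 0.35 is not a call.
* Fisher-combination components at 0 are floored at 1e-300; combined
  p-values are computed with the chi-square survival function.
* ROC ties are processed as one threshold step; curves never contain
  points below the termination z.
* BH adjustment and driver calling require a non-empty event list; empty
  networks, empty GMT sets and malformed table cells raise errors naming
  the offending line or coordinate.

## Known limitations

Randomization cost grows linearly in edges × replicas; very large
networks (millions of edges) would want a coarser swap factor or an
analytic null (the configuration-model expectation k_i·K_G/(2E) is used
here only as a test oracle, since it ignores the simple-graph constraint
and the sd). P-values from overlapping tests on one genome are treated as
independent by Fisher's method, which overstates joint significance;
combined values are correspondingly used for ranking, with calling gated
by the within-class BH threshold. The co-occurrence screen is
margin-sensitive: genes altered in nearly all samples cannot pass it.
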