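# Methods

## Model

A herb is represented by the union of the target genes of its compounds,
`H = {h_1..h_N}`, each gene carrying a weight `w_n` — the number of the
herb's compounds that target it. A disease is its gene set `D = {d_1..d_M}`.
Both are projected onto the largest connected component (LCC) of an
undirected, simple protein–protein interaction graph, on which `spl(a, b)`
denotes the unweighted shortest path length. Three proximity scores are
defined per (herb, disease) pair, all "smaller is stronger":

* `ASP = (Σ_n Σ_m spl(h_n, d_m)) / (N·M)` — the all-pairs average.
* `ACP = (Σ_n min_m spl(h_n, d_m)) / N` — each herb gene is matched to its
  nearest disease gene. The minimum runs over disease genes for each herb
  gene, so the measure is deliberately asymmetric: a herb gene need not be
  close to *every* disease gene, and disease genes not reached by the herb do
  not penalise it.
* `WACP = (Σ_n (1/w_n) · min_m spl(h_n, d_m)) / N` — ACP with each term
  scaled by the inverse weight. The inverse keeps the "lower = stronger"
  orientation: a gene hit by many compounds contributes a shorter effective
  distance.

Assumptions worth stating explicitly: interactions are unweighted and
undirected (direction, sign and confidence are ignored); disease genes are
assumed to be locally clustered on the interactome (the usual disease-module
hypothesis — without it proximity carries no signal); and compound
multiplicity is treated as a proxy for perturbation strength, with no
distinction between agonism and antagonism.

### Identities

`WACP ≤ ACP ≤ ASP` holds pointwise (`1/w ≤ 1` and min ≤ mean), with
`WACP = ACP` when all weights are 1. When `H ⊆ D` the closest-path measures
are exactly zero (each herb gene is its own nearest disease gene). ASP does
*not* vanish in that case — it still averages the nonzero cross-distances —
which is one reason the all-pairs average ranks poorly: it is dominated by
the bulk of the distance distribution rather than by the nearest contacts.

## Data handling

**Evidence filter.** Every association record carries the set of source
databases reporting it; records with fewer than `min_sources` (default 2)
distinct labels are dropped. Labels are opaque case-sensitive strings and the
filter counts distinct labels, never record multiplicity. The filter is
idempotent and `min_sources=1` is the identity.

**Profiles.** Disease profiles group the filtered disease–gene table by
disease. Herb profiles join herb–compound to compound–gene:
`w[g] = |{c in herb : (c, g) in compound_gene}|`. Herbs whose compounds
collectively target no gene are dropped with a warning — they have no
interactome footprint. Identifier joining is exact-string; no nomenclature
mapping is attempted.

**Graph restriction.** Genes absent from the LCC are silently dropped at
scoring time and `N`, `M` are the restricted counts; this is the standard
network-medicine convention, and the restricted counts are recorded per
entity in the score matrix. A pair whose restricted herb or disease set is
empty has no faithful finite value and is reported as `NA`; such cells are
excluded from every metric (numerator and denominator) with a logged count.

**Distances.** Exact breadth-first search, memoised per source gene. BFS runs
from disease genes, the smaller side of the query (hundreds of distinct
disease genes versus tens of thousands of herb genes), and the full matrix
computation vectorises the herb side over the cached distance rows. The
cache-direction choice affects performance only; values are exact either way.

## Evaluation

Pairs are ranked by score (ascending) against a gold standard of known
associations. AUROC uses the rank/midrank (Mann–Whitney) formulation — the
probability that a random positive outranks a random negative, ties counted
1/2 — equivalent to trapezoidal ROC integration. AUPRC uses step-wise
(rectangular) integration, i.e. average precision; trapezoidal interpolation
in PR space is optimistically biased, so it is avoided. The no-skill AUPRC
baseline `positives/total` is always reported alongside.

Per-herb (per-disease) AUROC is computed inside each matrix row (column) and
requires at least one positive *and* one negative defined cell; entities
failing this are omitted with a logged tally, since a single-class AUROC is
undefined. A Pearson correlation between per-entity AUROC and the entity's
number of known partners (two-sided t-test p-value) checks that performance
is not an artefact of annotation density; it is reported as undefined when
either axis has zero variance.

The FPR-anchored threshold is the largest score whose achieved false-positive
rate does not exceed the target (default 5%): a conservative guarantee — the
achieved FPR is never above the target, at the cost of possibly sitting below
it when score ties straddle the boundary.

**Discovery rules.** A herb is *reliable* when its per-herb AUROC exceeds
`auroc_min` (default 0.9), it has at least `min_known` (default 3) known
diseases with defined scores, and all those known scores fall below the
FPR-anchored threshold. For each reliable herb, a non-gold disease becomes a
candidate when its score is below the mean score of the herb's known diseases
and the disease's own AUROC exceeds the mean per-disease AUROC *of the
current run* — deliberately recomputed rather than fixed, because that mean
is a realisation of the dataset at hand. Candidates are disjoint from the
gold standard by construction.

**Rank-sum comparison.** The case-study helper compares known-disease scores
with all other scores by a two-sided Wilcoxon rank-sum (Mann–Whitney) test:
exact null distribution when both samples have at most 8 untied values,
normal approximation with continuity correction otherwise, midranks for ties.

## Synthetic data

The generator emulates the statistical shape of curated repositories at desk
scale; all randomness flows from a single seeded NumPy generator and
identical (config, seed) reproduces byte-identical files.

* **Interactome** — Barabási–Albert preferential attachment (default 500
  nodes, 4 edges per new node), giving the heavy-tailed degree profile that
  real interactomes show and that shortens typical path lengths; an
  Erdős–Rényi mode is available for comparison. The LCC is extracted exactly
  as in the real pipeline.
* **Disease modules** — the first `s` nodes of a randomised BFS from a random
  seed node, so modules are connected by construction; `s` follows a shifted,
  clipped geometric distribution (default range 2–74, mean ≈ 6.3).
* **Herbs** — compounds per herb follow a clipped lognormal (σ = 0.8, range
  1–80, mean ≈ 34.5); targets per compound are uniform on 1–8. Compound
  identifiers are unique per herb — real repositories share compounds across
  herbs, but sharing is irrelevant to the weight mechanism and omitting it
  keeps the generator simple.
* **Evidence** — each record's source set is a k-of-n database draw
  (default 4 databases, membership probability 0.5, floored at one), so
  roughly 69% of records survive the ≥2-database filter and both branches of
  the filter are exercised.
* **Planted signal** — a fraction of herbs (default 10%) is designated
  positive and assigned 1–3 gold diseases. Each target draw of a positive
  herb lands, with probability `module_locality` (default 0.8), inside the
  radius-1 ball of its gold modules; additionally `multiplicity_boost`
  (default 3) extra compounds per gold disease all target one small
  module-proximal focus set, raising those genes' weights well above the
  collision-level background weights of negative herbs. The association
  signal is thus partly *multiplicity-encoded*: the weighted measure
  separates positives better than the unweighted ones, which is the property
  the benchmark verifies (WACP beats ACP in 20/20 default-config seeds).
  With locality 0 and boost 0, positive herbs are generated identically to
  negatives and evaluation must sit at chance — the null calibration check.

What passing these benchmarks does **not** show: the generator plants exactly
the signal the weighted measure is designed to read, so it demonstrates
correctness of the machinery and internal consistency of the method, not that
real herbs behave this way. Real annotation bias (well-studied diseases have
more genes), shared compounds, literature-driven gold standards and
interactome noise are all absent.

## Numerical choices and edge cases

* Problem sizes: the default benchmark (500-node graph, 60 herbs, 12
  diseases, 20-seed sweep) makes a full sweep a matter of seconds while
  keeping ~700 scored pairs per seed; all sizes are config fields.
* LCC size ties break toward the component containing the lexicographically
  smallest node id; profile and matrix iteration is sorted by identifier, so
  outputs are independent of input row order and dict ordering.
* Score TSVs are written with `%.12g` formatting; rerunning a pipeline from
  the same manifest reproduces every output byte-for-byte (checked in the
  test suite).
* `threshold_at_fpr` accepts targets in (0, 1]; the degenerate point with
  threshold −inf (call nothing) is returned only when even one false positive
  would overshoot the target.
* Weights must be positive; zero or negative weights raise immediately
  rather than producing sign-flipped scores.
* The exact rank-sum branch is limited to ≤8 untied observations per sample;
  beyond that the normal approximation's error is far below the decision
  scale of the pipeline (verified against a 10^5-draw permutation oracle in
  the tests).

## Known limitations

* Edge direction, interaction type and tissue specificity are ignored; a
  tissue-aware interactome would likely sharpen disease modules.
* The measures cannot distinguish beneficial from harmful proximity
  (agonist vs antagonist) — a known blind spot of distance-only scoring.
* Evaluation treats unscored pairs as absent rather than worst-ranked; if
  many gold pairs fall outside the scored set, AUROC describes only the
  scorable universe.
* Degree-preserving randomisation z-scores (proximity relative to a null
  model) are out of scope; raw distances are compared only across pairs
  within one run.
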