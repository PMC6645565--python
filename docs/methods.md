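# Methods

## Problem setting

Three RNA-seq contrasts probe the switch from mitotic cycling to
endoreplication in *Drosophila*: two induced-endoreplication knockdowns in
cultured cells (CycA-like and Myb-like, each vs. a mitotic-cycling control)
and one developmentally endoreplicating tissue (salivary-gland cells vs.
mitotic brain/disc cells). `deconcord` quantifies the concordance of their
differential-expression (DE) results: which genes move together, whether the
sharing exceeds chance, and how a curated gene panel behaves across the
contrasts. The package consumes DE tables; read mapping and count-model
fitting are out of scope by design, so nothing here re-derives fold changes
or p-values from counts.

## DE calling

A gene is *up* if log2FC ≥ 0.5 with FDR-adjusted p ≤ 0.05, *down* if
log2FC ≤ −0.5 with FDR-adjusted p ≤ 0.05, else *unchanged*. Both boundaries
are inclusive — where source conventions differ between a strict `<` and an
inclusive `≤`, the inclusive form is adopted as the operational definition —
and both thresholds are configurable (`lfc_min > 0`, `fdr_max ∈ (0, 1]`).
The Benjamini–Hochberg step-up adjustment is implemented internally
(p·m/rank, cumulative minimum from the largest rank, capped at 1); it is
order-equivariant and monotone, and is cross-checked against statsmodels in
the test suite. When a table ships its own adjusted-p column it is used
as-is by default, because recomputing would silently change the adjustment
set the upstream tool used; `recompute_padj=True` overrides. Genes with
undefined adjusted p (NaN) are classified unchanged but remain in the
universe: a filtered gene was still tested.

The screen-candidate filter is separate and deliberately permissive:
log2FC ≤ −lfc_min in *both* knockdown contrasts with p-values ignored
entirely. Its output is invariant to any perturbation of p-values, which the
suite checks.

## Overlaps and universes

Directional overlaps intersect the up sets (or the down sets) of k ≥ 2 call
sets; up and down are always analysed separately (a pooled "any" direction
exists but is non-canonical, since it lets a gene moving up in one contrast
and down in another count as shared). Each gene in the union receives a
k-bit membership signature; the partition is complete over all 2^k − 1
non-empty signatures, its marginals reproduce the per-set sizes, and the
all-ones signature equals the observed overlap.

Contrasts are typically tested on slightly different universes (annotation
filters differ between experiments), so sets are restricted to a resolved
universe before intersection: the default policy is the intersection of the
per-contrast universes, with union and explicit-list overrides. The universe
size N feeds the null model directly, so an explicit N should be supplied
whenever the commonly tested gene list is known; the published fold
enrichments of the motivating study cannot be recomputed without its
post-filter universe, which was never printed — this is a documented gap,
not a package limitation.

## Permutation-null enrichment

Null model: k sets drawn independently and uniformly without replacement
from N labels, with the observed set sizes. For B null draws,

    p = (#{null overlap ≥ observed} + 1) / (B + 1),

the add-one estimator: never below 1/(B+1), conservative under the null
(verified by calibration: over 1,000 independent-null replicates at
N = 2,000 with sets of 200, the fraction of p ≤ 0.05 stays below 0.05).
At the study-scale B = 100,000 the floor is 1/100,001 ≈ 9.9999×10⁻⁶.

Every null draw also yields a fold enrichment `observed / null_b`. Where a
draw has zero overlap the fold is undefined; it maps to +∞ and the count of
such draws is reported (`zero_overlap_samples`). The median and 5%/95%
quantiles of the fold distribution therefore remain finite whenever fewer
than 50% / 5% of draws are zero; with very sparse nulls the summary is
legitimately infinite, as in the README example. Quantiles use the lower
empirical order statistic (type 1): the ceil(q·n)-th sorted value. For
`observed = 0` a draw with positive overlap gives fold 0 and a zero-overlap
draw still maps to +∞ (0/0 is tallied, not invented).

Sampling paths. The generic path draws whole sets and intersects them. The
fast path uses the fact that the intersection of the first i sets,
conditioned on its size, is itself a uniform random subset, so the k-way
intersection size is a chain of hypergeometric draws — distributionally
identical to the generic path (tested by chi-square homogeneity) and exact
for every k, not just k = 2. The same chain, convolved analytically, gives
the exact pmf of the intersection size; a brute-force enumeration
(first set fixed by exchangeability, guarded at 10⁷ configurations) serves
as an independent oracle at tiny sizes, and the k = 2 case reproduces the
closed-form hypergeometric pmf to machine precision.

Randomness: one `numpy` Generator per run, seeded explicitly; the seed is a
required part of every enrichment result and report. Sampling is serial and
vectorised, so identical inputs and seed give identical results
unconditionally; no per-permutation sub-streams are needed because there is
no parallel scheduling for results to depend on.

## Panel meta-analysis

A curated panel is looked up in each contrast's call set; each (gene,
contrast) pair receives exactly one of *increased*, *decreased*,
*unchanged*, or *untested* (absent from that contrast's universe). Untested
is kept distinct from unchanged because a gene the upstream pipeline never
tested carries no evidence of stability; folding the two together would
overstate concordant stability. Concordance counts tally panel genes sharing
a category across every contrast pair and the full set; counts are monotone
under subset inclusion and per-contrast categories sum to the panel size.

The packaged panel holds the 12 E2F1- and Myb-dependent mitotic gene symbols
(tum, pav, sti, Nnf1a, Kmn1, Klp67A, mad2, polo, msd1, msd5, nod, CG7341)
with their annotated functions as documentation-only categories. The larger
111-gene E2F1-dependent panel is not redistributed; any one-id-per-line file
can be supplied in its place.

## Synthetic data

The generator emulates the *table-level* statistics of the three-contrast
study — not counts, library sizes or dispersions, which the pipeline never
sees. Per gene and contrast, a latent z is standard normal noise, plus a
signed per-gene effect for module members: effect sizes are drawn once per
gene from N(effect_mean, effect_sd) and shared across that gene's member
contrasts (a strongly repressed target is strongly repressed everywhere it
responds). Then p = two-sided normal tail of z and log2FC = z·lfc_scale, so
sign and significance agree for strong effects while weak effects can be
discordant, as in real tables.

Defaults are the study conditions: N = 12,000 genes; contrasts CycA_iEC,
Myb_iEC, SG_devEC; planted modules of 47 genes down in all three contrasts,
25 genes down in the developmental contrast only, and 698 genes up in the
two knockdown contrasts; `effect_mean = 6`, `effect_sd = 0.5`,
`lfc_scale = 0.4`, seed 0. The effect scale was chosen to represent strong
direct-target repression: z ≈ 6 corresponds to a two-sided p ≈ 2×10⁻⁹ and
|log2FC| ≈ 2.4, i.e. the several-fold changes expected of direct targets of
a knocked-down regulator, with modest gene-to-gene spread. Under these
conditions the end-to-end pipeline (call → intersect → permutation test)
recovers ≥ 90% of the 47-gene module in the triple-down intersection with
the minimum attainable p at B = 10,000.

A separate noise-free constructor (`planted_overlap_tables`) reconstructs
the study-scale Venn structure exactly — 698 shared-up and 268 shared-down
genes between the knockdown contrasts, of which 158 and 109 extend to the
developmental contrast, plus the 25 developmental-only down genes — by
assigning planted genes log2FC = ±2 at p = 10⁻¹² and leaving everything else
exactly null. It is a synthetic stand-in for the study's real DE tables
(which are not redistributed here): it exercises the deterministic
set-algebra bookkeeping at realistic scale, and passing on it shows the
pipeline's arithmetic is right, not that the original data would reproduce
those counts.

What the generator does *not* emulate: correlated genes (co-expression
modules beyond the planted ones), signal-dependent variance, fold-change
shrinkage, filtered low-count genes (every gene has a defined p), or
differing per-contrast universes. Tests passing on synthetic data therefore
validate the statistical machinery, not any claim about a particular real
dataset.

## Numerical and scale choices

Problem sizes in the default test suite and acceptance script were chosen to
make every stochastic check decisive at interactive runtimes: B = 100,000
for the p-floor demonstration (fast path), B = 20,000 for the closed-form
agreement checks at n₁ = n₂ = 50, N = 500, B = 50,000 permutation draws
against the exact k = 3 pmf on N = 12, 1,000 replicates × B = 1,000 for
calibration, and B = 10,000 for the end-to-end recovery run. Monte-Carlo
comparisons use 4-standard-error bands plus a 1/B discreteness allowance.
Reports serialize to JSON with a schema version; ±∞ fold summaries are
encoded as the strings `"Infinity"`/`"-Infinity"` and round-trip exactly;
floats round-trip at full precision.

## Known limitations

- The null is uniform sampling of genes: no gene-length, expression-level or
  GC stratification. Enrichment against a structured background needs a
  different null than this package provides.
- Fold-enrichment summaries are undefined (infinite) when the null is
  sparse; interpret the median fold only when `zero_overlap_samples`/B is
  well below 0.5.
- The BH adjustment assumes the table's rows are the full tested set; tables
  pre-filtered to significant genes will produce misleading calls — supply
  the complete per-gene results.
- Gene identifiers are opaque strings; no ortholog mapping or identifier
  conversion is attempted, and panels must share the tables' namespace.
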