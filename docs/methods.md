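# Methods

This note documents the models, parameter choices and numerical
conventions behind `netanim`, and what the synthetic benchmark does and
does not demonstrate.

## Study design and contrasts

The pipeline assumes a two-factor factorial design — by default
`genotype` ∈ {WT, d_p23} × `treatment` ∈ {vehicle, hsp90i} — with r ≥ 2
replicates per condition. Expression values are contractually log2-scale
intensities; a `linear_input` flag log-transforms on load. The analysis
runs over an ordered list of pairwise contrasts, each annotated with the
regulator whose function is *lost* in the numerator condition relative
to the denominator. The default ("canonical") four contrasts are

| id | contrast | factor lost |
|----|-------------------------------|-------|
| c1 | d_p23.vehicle / WT.vehicle | p23 |
| c2 | WT.hsp90i / WT.vehicle | hsp90 |
| c3 | d_p23.hsp90i / d_p23.vehicle | hsp90 |
| c4 | d_p23.hsp90i / WT.hsp90i | p23 |

This is the unique natural ordering under which the consistent pattern A
(up, down, down, up — red, green, green, red in the animation) reads as
"Hsp90 activator, p23 repressor", and likewise for B, C, D. The order and
membership are fully configurable through a comparisons TSV; the
classifier works for any factorial design expressed this way, not only
2×2.

## Differential expression

Per contrast and gene, log2FC = mean(numerator) − mean(denominator) over
log2 replicate values, and a two-sample t-test on the same values. The
default test is the pooled-variance Student t: for balanced replicate
groups drawn from a common noise model its null p-values are exactly
uniform, which we verify by simulation (Kolmogorov–Smirnov on 5,000
no-effect genes). Welch's unequal-variance test is available
(`test="welch"`), but at triplicate scale its Satterthwaite
degrees-of-freedom approximation measurably distorts the null (KS
statistic ≈ 0.03 at n = 5,000, rejected at α = 0.01), so it is not the
default.

Calls: `U` iff FC ≥ `fc_threshold` (default 1.5, linear scale, boundary
inclusive) and p < `p_threshold` (default 0.05, raw — no multiplicity
correction by default, matching common volcano-filter practice; a BH
option exists for the enrichment stage where it is standard). `D` is the
mirror (FC ≤ 1/threshold), otherwise `N`. The boundary test is done on
the log2 scale with a 1e-9 absolute tolerance so that FC exactly equal
to the threshold survives the float round-trip through
2^log2(threshold). Conditions with a single replicate yield an absent
p-value and a conservative `N`.

The per-gene two-way ANOVA uses the classical sum-of-squares
decomposition for a balanced 2×2×r layout (where Type I and Type III
coincide), vectorised across genes, with F ratios against the residual
mean square. Genes with zero residual variance get p = 0 for effects
with nonzero SS and p = 1 otherwise, with a warning. Unbalanced designs
are rejected with a pointer to pairwise mode. The ANOVA gate on the
responsive set is off by default and independently switchable, since
volcano-only selection is equally defensible.

## Network assembly

PPI edges come from a BioGRID-tab or SIF table, deduplicated and
undirected, self-interactions dropped. The default subnetwork is the
induced subgraph on the responsive genes; `include_neighbors` adds
first-level interactors as `context` nodes. Coexpression edges connect
gene pairs with Pearson r ≥ `corr_cutoff` (default 0.9) between their
profiles. The default profile is the per-sample log2 vector across all
arrays (12 values in the default design) rather than the 4 condition
means or per-contrast fold changes — more degrees of freedom make the
0.9 cutoff meaningful; the per-contrast-FC profile is available
(`profile_mode="fc"`). Correlation is signed by default ("absolute" mode
keeps anti-correlated pairs too). Zero-variance profiles are skipped
with a warning (r undefined). Pearson r is computed per pair as a
normalised dot product of mean-centred rows, which makes the edge list
bit-identical under input row reordering. Both edge types are kept as
distinct typed parallel edges in a multigraph; GraphML export preserves
types and `pearson_r`, SIF export keeps topology only.

## Layered layout

Nodes map to one of seven horizontal bands (extracellular, plasma
membrane, cytoplasm, mitochondrion, ER/Golgi, nucleus, unknown;
configurable) via a synonym table over common GO cellular-component
labels; multi-localised genes resolve by a configurable precedence list
(default: band order). Within bands, a seeded random order is refined by
barycentric sweeps: each node's target x is the mean x of its neighbours
over all edge types, bands re-sort by target and are re-placed by a
priority rule — nodes in decreasing degree order land on their target x,
clamped so every pair of placed nodes keeps at least one minimum-gap
slot per intervening node (the feasible interval is provably never
empty). Isolated nodes therefore yield to connected ones. Sweeping stops
early when no band's order changes, and the snapshot with the smallest
total edge length is returned, so refinement never ends worse than the
seeded placement. The layout is deterministic for a fixed seed and
independent of input node order (canonical sort before seeding). This is
a functional stand-in for interactive cell-map layouts, not a
re-implementation of any particular tool: it guarantees only the
property the analysis needs — interconnected, co-localised nodes end up
near each other.

## Rendering and animation

Node colour is a linear interpolation from the neutral colour (default
black, the red/black/green microarray convention) to pure red for
positive and pure green for negative log2FC, clamped at
±`color_saturation` (default 2.0, i.e. 4-fold, so the 1.5-fold calling
threshold sits visibly inside the ramp). With a neutral colour whose red
and green channels are equal the map is odd under hue exchange.
Rendering is pure Pillow drawing — bands, then edges (PPI solid,
coexpression dashed), then nodes, then the contrast label — with no
global state, so identical inputs give byte-identical PNGs, and the GIF
holds one frame per contrast in animation order. The HTML flipbook
embeds the frames base64 and steps with the arrow keys, since repeated
manual inspection is the intended discovery mode. Pattern-region
overlays are deliberately not auto-drawn: the classifier output table is
the machine-readable equivalent.

## Pattern classification

Each gene's ordered call string is reduced to per-factor evidence by the
loss-of-function rule: `U` under loss of factor f ⇒ f repressed the gene,
`D` ⇒ f activated it. Unanimous evidence for both factors with no `N`
gives A (act, rep), B (rep, act), C (rep, rep) or D (act, act); any `N`
or conflict gives E with the conflicting factor marked ambiguous; all-`N`
genes are reported `unresponsive` rather than E, because E is reserved
for genes that responded somewhere but inconsistently. The classifier is
validated exhaustively against a brute-force enumeration oracle over all
3⁴ call sequences and satisfies sign-flip symmetry (negating every call
maps A↔B, C↔D, fixes E).

## Promoter motif analysis

Promoters are the `upstream_length` (default 1000 nt) bases upstream of
the TSS, strand-aware, truncated at contig bounds with a logged length.
Motifs are read from MEME minimal format; probabilities are regularised
with a 0.01 pseudocount per cell. Scanning computes the log-odds score
Σ log2(p(base)/bg(base)) for every window on both strands, skipping
windows containing N; the hit threshold defaults to 80% of each motif's
maximal achievable score, a common convention when no per-matrix cutoffs
are available. Over-representation uses presence/absence per promoter
(not hit counts), which keeps the 2×2 Fisher table well defined: ratio
of hit fractions, one-sided Fisher exact p, BH adjustment; output is
sorted by ratio (primary) then p. A motif with foreground hits but zero
background fraction reports an infinite ratio and sorts first; a motif
with no hits anywhere is dropped with a log message.

## Synthetic benchmark

The generator emulates the shape of a 2×2 yeast chaperone-perturbation
study: per gene a baseline ~ Normal(8, 1) log2 units, condition means
shifted by ±δ so the canonical contrasts reproduce the planted pattern's
call string, and replicate noise Normal(0, σ). Defaults: 50 genes per
class (A–E plus unresponsive), δ = 2 log2 units, σ = 0.25, r = 3 — an
effect-to-noise regime where a real 4-fold change on a clean array is
essentially always detectable, which is the point: the benchmark
verifies correctness of the machinery, not statistical power at the
margin. E genes are planted by flipping one contrast of a consistent
pattern; because four condition means always satisfy d1 + d3 = d2 + d4,
the flip requires solving contrast magnitudes over a small grid of
multiples of δ (all ≥ δ, so every planted call survives thresholding),
and the two alternating strings UDUD/DUDU are unrealisable from
condition means and never planted. PPI truth is cliques of five within
same-pattern groups plus an Erdős–Rényi background (p = 0.01) between
modules; localization is sampled per pattern group from fixed
compartment weights; promoters are i.i.d. AT-rich (A=T=0.31, C=G=0.19)
sequence with an STRE-like consensus (AAGGGGCG) planted once in each
pattern-C gene's promoter, with random decoy PWMs for the ranking test.

What passing does *not* show: robustness to probe-level artefacts,
intensity-dependent variance, batch effects, unbalanced designs or weak
effects near the 1.5-fold boundary — the generator idealises all of
these away on purpose, and conclusions about real microarray data need
the usual upstream QC and normalisation, which are out of scope here
(the pipeline starts at a normalised log2 matrix).

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale sizes chosen to
exercise every code path with comfortable margins: 81-sequence
exhaustive classifier enumeration; 300-gene studies over three seeds for
end-to-end recovery; 5,000 genes for null calibration; 50 random
instances for the t/ANOVA oracles; 10-gene fixtures (45 pairs) for the
Pearson oracle; 300 × 1 kb promoters for enrichment. Every stochastic
step takes an explicit seed (numpy `default_rng`), and all outputs —
tables, layouts, PNGs, GIF — are reproducible byte-for-byte given the
same inputs and seed; the provenance manifest records input checksums
and parameters to make that checkable.

## Known limitations

- The layered layout optimises a heuristic (barycentric) objective; it
  makes no edge-crossing guarantees.
- The 0.9 correlation cutoff on 12-sample profiles still admits chance
  correlations; the pipeline reports r to full precision but does not
  attach a significance estimate to coexpression edges.
- The motif stage does not map motifs to transcription-factor
  identities, and its default score threshold is a convention, not a
  calibrated cutoff.
- ANOVA requires a balanced design; unbalanced studies must use the
  pairwise path only.
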