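# Methods

## The analysis

The package reassesses diversity patterns of a fern/lycophyte flora from
three inputs: a trait-annotated taxon checklist, presence-only occurrence
records on Japan's 10-km secondary standard-area mesh, and a rooted rbcL
phylogeny with branch lengths in expected substitutions per site. From
these it builds per-cell map layers (taxon richness, Faith's PD, apomict
richness and proportion, red-listed richness), per-taxon range metrics,
trait-group comparisons, and flora-level summary proportions.

## Mesh arithmetic

A 6-digit code `PPQQRC` is decoded positionally: SW corner latitude
`PP/1.5 + R/12`, SW longitude `100 + QQ + C/8`; cells are 1/12° tall and
1/8° wide. Codes are strings (leading zeros are significant) and only the
6-digit secondary level is supported, since that is the occurrence data's
resolution. Parsing does not range-check the row/column digits; encoding
uses floor arithmetic with a 1e-9 guard against float representation
error, far below the grid's 1/12° resolution. Centroids are the canonical
per-cell coordinate: latitudinal breadth (max − min) is identical for
centroids and SW corners because the constant half-cell offset cancels,
which is asserted as a property test. The arithmetic was cross-checked
against four published cell codes whose localities are known islands or
areas (Yakushima, southern Wakayama, northern Okinawa, Iriomote).

## Faith's PD

PD of a taxon set is the summed branch length of the subtree connecting
the set's tips. "Excluding the root" is interpreted as rooting the pruned
subtree at the retained tips' MRCA and discarding any edge above it (the
common unrooted-PD convention); because the source procedure does not
define its trimming step precisely, the alternative convention — keeping
the MRCA-to-root path — is implemented behind `include_root_path=True` so
real data can arbitrate. The root's own edge length is never summed under
either convention.

Implementation: one postorder pass counts the selected tips below every
edge; with *k* selected tips, the MRCA-rooted spanning subtree consists
exactly of the edges whose count lies in [1, *k*), so PD is a masked sum.
The per-cell map vectorises the same counts as a chunked
(cells × tips) · (tips × edges) product. Correctness is established
against an independent brute-force oracle that marks edges on explicit
tip-to-MRCA paths, with exact agreement required over ≥1,000 random
(tree ≤ 20 tips, subset) instances including polytomies.

Taxa without a tree tip are dropped from PD (and logged) but still count
toward richness; PD is undefined — a value, not an error — when fewer
than two retained tips remain, matching the convention that a single
lineage has no shared branch length to sum.

## Statistics

Group comparisons of range metrics use, for three or more groups, a
classical one-way ANOVA (between/within decomposition, F with (k−1, N−k)
df) followed by Tukey's HSD, and for two groups Student's pooled-variance
t-test. Tukey uses the Tukey–Kramer statistic
`q = |m_i − m_j| / sqrt(MSW/2 · (1/n_i + 1/n_j))` so unequal group sizes
are handled; pairwise p-values come from the studentized-range
distribution, whose upper tail is computed by Gauss–Legendre quadrature
(72 outer nodes over the chi-scale density between its 1e-14 quantiles,
160 inner nodes over the sample-maximum location). The quadrature agrees
with an independent library implementation to better than 1e-6 across the
k and df used here. Letter displays use the insert-and-absorb algorithm;
groups sharing a letter are not significantly different at α (default
0.05, configurable).

Student's rather than Welch's t is the default because the source
comparisons name Student's test; Welch is available behind a flag since
the observed group variances are very unequal. Degenerate inputs are
defined explicitly: zero between-group variation gives F = 0, p = 1;
identical two-sample inputs give t = 0, p = 1; any group with n < 2 is an
error, and trait levels with fewer than two analysable taxa are dropped
with a warning before testing.

Trait-comparison denominators: hybrids are always excluded; `unknown`
trait values are excluded, never imputed; the ploidy comparison is
restricted to sexually reproducing taxa so the largely triploid apomicts
cannot masquerade as a polyploidy effect. Dual-mode taxa ("both") form
their own group in mode comparisons and count as apomictic-capable in the
apomixis rate by default; both numerator conventions are exposed because
published rates do not state which was used.

Percentages are printed at one decimal with round-half-away-from-zero,
implemented in exact decimal arithmetic; this convention reproduces every
published proportion checked from its printed counts.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the geography of Japan: the frame is a rectangular band of secondary
mesh cells (default 24–46°N × 123–146°E, 48,576 cells), each taxon
receives a latitudinal range centre (Normal(35, 3); apomicts shifted
2.5° south, seasonally green taxa 2.5° north) and a breadth drawn from
its group's distribution — Normal(7.62, 5.02) degrees for sexual,
Normal(5.93, 3.77) for apomictic taxa, the group means, SDs and sizes of
the study regime — and occupies each in-band cell independently with
probability 0.02. Default trait fractions likewise mirror the study: 721
native taxa plus 371 hybrids; 11% of natives apomictic (≈79), 1.1%
dual-mode (≈8), ~31% of unknown mode (≈413 known-mode sexual); ploidy
45% polyploid among sexual taxa; 74.5% evergreen; 2.1% of taxa withheld
from the Yule tree (97.9% rbcL coverage). Branch lengths are iid
exponential with mean 0.01 substitutions per site. All stages are
deterministic under a fixed seed, with independent CRC-derived substreams
per stage.

Two deliberate simplifications: occupancy has no spatial autocorrelation
and no coastline mask, and breadths are truncated below at one cell
height (1/12°). Truncation shifts realised group mean breadths up by
about +0.15° (sexual) and +0.10° (apomictic) relative to the configured
means; recovery tests therefore compare against the analytic clipped-mean
expectation and use tolerances covering the shift. Range centres are
clamped so the drawn band always fits inside the frame — otherwise edge
clipping would bias realised breadths downward and group means would not
converge to their configured values. Passing tests consequently
demonstrate correctness of the pipeline's bookkeeping and inference under
idealised sampling; they do not validate collection-effort, topographic
or autocorrelation effects present in real specimen data.

## Problem sizes used in tests

Replicate studies (detection power, null calibration) run the full
pipeline on a laterally scaled frame — longitude band 123–126°E with
occupancy density 0.15 — chosen so the per-row presence probability stays
≈0.98 (breadth recovery unaffected) while each replicate completes in
well under a second; group sizes and effect sizes remain at the study's
values (≈413 vs ≈79 taxa, 7.62 vs 5.93 ± 5.02/3.77 degrees). Type-I
calibration uses three Normal(0,1) groups of n = 20 over 2,000
simulations, with the acceptance band the 95% binomial interval around
the nominal 0.05. PD validation uses 1,000+ random trees of up to 20
tips, where the brute-force oracle is exact and cheap.

## Known limitations

- Only the 6-digit secondary mesh is supported; finer or coarser mesh
  levels are rejected by design.
- Presence-only semantics throughout: absence is never inferred, and the
  study-frame cell total (e.g. 4852 nationally) is configuration, not
  derived from data.
- PD is the only phylogenetic diversity metric implemented (no MPD, MNTD
  or phylogenetic endemism), and the tree is an input — no alignment or
  inference is performed.
- The generator's independence assumptions make its occupancy counts more
  regular than real specimen data; provenance-class distinctions among
  records (vouchered vs literature-cited) are not modelled.
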