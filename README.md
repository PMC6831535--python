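# pteridiv

Gridded diversity analysis for the ferns and lycophytes of the Japanese
Archipelago: species richness and Faith's phylogenetic diversity mapped on
the 10-km standard-area-mesh grid, trait-stratified range-size statistics,
and flora-level summary proportions — plus a synthetic-data generator so
the entire pipeline can be exercised and validated without the deposited
occurrence and checklist files.

## Who this is for

Researchers working with Japan's national fern/lycophyte datasets (a
trait-annotated checklist of 721 native taxa plus 371 interspecific
hybrids, a presence-only occurrence spreadsheet georeferenced to 6-digit
secondary mesh codes, and a rooted rbcL reference phylogeny), or with any
data shaped like them, who want reproducible richness/PD maps and
range-breadth comparisons rather than one-off scripts.

## What it computes

**Mesh geometry.** A 6-digit secondary mesh code `PPQQRC` decodes to a
cell of 5′ latitude × 7.5′ longitude (≈10 km × 10 km): SW corner at
latitude `PP/1.5 + R/12` and longitude `100 + QQ + C/8` degrees. Cell
centroids are the canonical coordinate for all latitude statistics.

**Faith's PD.** For a cell holding taxon set *S* with *k* ≥ 2 tips on the
reference tree,

&nbsp;&nbsp;&nbsp;&nbsp;PD(S) = Σ<sub>e ∈ T(S)</sub> ℓ(e),

where T(S) is the subtree connecting the tips of *S*, rooted at their most
recent common ancestor (the residual edge above the MRCA is excluded; an
`include_root_path` flag retains it instead). Cells with fewer than two
tips in the tree carry an explicitly undefined PD.

**Range statistics.** Per taxon: occupied-cell count and latitudinal
breadth (max − min occupied centroid latitude, degrees). Groups defined by
reproductive mode (sexual / apomictic / capable of both), phenology, or —
among sexual taxa only — ploidy class are compared with a one-way ANOVA
followed by Tukey's HSD (three groups, compact letter display) or
Student's pooled t-test (two groups). The statistics are computed from
their classical formulas; the studentized-range tail probability is
evaluated by Gauss–Legendre quadrature of its CDF.

**Flora summaries.** Percentages at one decimal, round-half-away-from-zero
(e.g. 487/721 → 67.5%), red-list category totals, and the apomixis rate
among known-mode native taxa under both numerator conventions (with and
without dual-mode taxa).

## Worked example

```python
import pteridiv as pv

cfg = pv.SimConfig(seed=42, n_taxa=400,
                   frame=pv.Frame(lat_min=28, lat_max=38, lon_max=130),
                   occupancy_density=0.08)
table, newick, tree, records = pv.gen_dataset(cfg, outdir="demo")

m = pv.load_occurrences("demo/occurrences.csv", table)
print("records:", m.provenance, "-> presences:", m.n_presences)

summary = pv.flora_summary(table)
print("native taxa:", summary["n_native"], "| hybrids:", summary["n_hybrid"])
print("apomixis rate (% of known-mode natives):",
      summary["pct_apomictic_excl_both"])

native = pv.filter_matrix(m, table, include_hybrids=False)
richness = pv.richness_map(m, table)
pd_layer = pv.pd_map(native, tree)
print("richest cell:", pv.top_cells(richness, 1)[0])
print("highest-PD cell:", pv.top_cells(pd_layer, 1)[0])

res = pv.compare_by_trait(m, table, metric="lat_breadth",
                          trait="reproductive_mode")
print(res.groups.round(2).to_string(index=False))
print("test:", res.test, "| P = %.4f" % res.p_value,
      "| letters:", res.letters)
```

Output:

```text
records: 214687 -> presences: 214687
native taxa: 400 | hybrids: 206
apomixis rate (% of known-mode natives): 17.6
richest cell: ('512561', 44.0)
highest-PD cell: ('512561', 2.3135854206100763)
    group   n  mean   sd
   sexual 232  6.61 3.25
apomictic  50  5.94 3.36
     both   2  9.92 0.00
test: anova+tukey | P = 0.1426 | letters: ['a', 'a', 'a']
```

Reading it: the generator produced 214,687 presence records over a
10°-tall synthetic band; the richest cell (code `512561`) holds 44 native
taxa and also maximises PD (2.31 expected substitutions per site of
summed branch length); apomictic taxa average narrower latitudinal ranges
than sexual ones (5.94 vs 6.61 degrees), but at this sample size the
Tukey comparison does not separate the groups (shared letter `a`). With
the full study-scale defaults (`pv.SimConfig(seed=...)` alone) the
difference is detected in most replicates — see the acceptance script.

The same pipeline is available as a shell tool:

```sh
pteridiv simulate --seed 42 --n-taxa 400 --outdir demo
pteridiv summarize --checklist demo/checklist.csv
pteridiv maps --checklist demo/checklist.csv \
    --occurrences demo/occurrences.csv --tree demo/tree.nwk --outdir maps
pteridiv rangestats --checklist demo/checklist.csv \
    --occurrences demo/occurrences.csv --outdir stats
```

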