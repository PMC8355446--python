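# Methods

## Model and procedure

`proximatch` tests whether a set of index SNPs (GWAS lead SNPs) lies
closer to a curated gene list than expected, using a resampling null
rather than a parametric one. The procedure:

1. **Lead-SNP selection.** Input SNPs are filtered by effect
   classification and chromosome. The defaults drop maternal-only loci
   (no direct fetal effect) and chromosome X, where dominant/recessive
   gene classification is ambiguous; sensitivity mode additionally drops
   unclassified loci, which may hide purely maternal effects.
2. **Gene lists.** A curated table of (symbol, allelic requirement)
   yields four lists: dominant = {monoallelic or dual}, recessive =
   {biallelic or dual}, recessive-only = recessive \ dominant, and their
   union. X-chromosome genes are excluded by default. A symbol appearing
   with both requirements is merged to "both", keeping
   |dominant| + |recessive-only| = |all|.
3. **Annotation.** Each SNP gets its nearest gene and distance
   (point-to-interval: 0 within a span, else distance to the closer
   boundary; ties broken by symbol) and, per window half-width `w`, the
   set of genes whose spans intersect `[pos − w, pos + w]` (closed
   intervals). Under these definitions the window gene sets are nested in
   `w`, and a nearest gene at distance ≤ w is always in the w-window; a
   nearest gene *can* lie outside the smallest window, which the worked
   example exhibits.
4. **Matching.** For each index SNP, the candidate pool is the set of
   panel SNPs with MAF in [0.9 m, 1.1 m] and either nearest-gene distance
   within ±10% of the index SNP's (nearest mode) or exactly the same
   within-window gene count (window mode). Intervals are closed, with a
   1e-12 relative slack on the bounds so that decimally-exact boundary
   values are not excluded by floating-point representation. The index
   SNP itself is excluded from its own pool by default. An empty pool is
   a hard error naming the SNP and the binding constraint; `relax_steps`
   opts into widening the MAF factors by 0.05 per step with a prominent
   warning — silent relaxation would invalidate the matching claim.
5. **Null sampling.** `n_lists` lists are drawn, one matched SNP per
   index SNP per list, uniformly from each pool. Per-column generators
   are spawned from a single seed, so the result is a pure function of
   (pools, n_lists, seed) and independent of execution order. Within a
   list, panel SNPs are kept distinct (synchronized redraw rounds): the
   observed index SNPs are distinct loci, and allowing duplicates would
   deflate the gene-level null whenever pools overlap — measurable at
   desk-scale panels, negligible at reference-panel scale. Cells whose
   pool holds a single SNP cannot be redrawn and may leave duplicates
   (warned).
6. **Statistics and p-values.** Gene-level (distinct list genes proximal
   to ≥ 1 SNP) and SNP-level (SNPs with ≥ 1 proximal list gene) counts
   are computed for the observed list and every null list, each null SNP
   contributing its own annotation exactly as the observed SNPs do. The
   empirical p-value is the fraction of null lists whose statistic is at
   least the observed one (upper tail; ties in the numerator, which makes
   p = 1 attainable). With zero exceedances the default estimator reports
   the floor bound `<1/n_lists`; the (r+1)/(n+1) estimator is available
   behind a flag. No multiple-testing correction is applied; the results
   table carries raw empirical p-values only.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| MAF factors | 0.9 / 1.1 | closed multiplicative MAF matching band |
| distance tolerance | 0.10 | relative band for nearest-gene distance |
| window half-widths | 19, 94, 138, 258 kb | gene-window sizes (bp) |
| `n_lists` | 10 000 | null lists; resolution of p is 1/n_lists |
| panel `min_maf` | 0.001 | panel MAF floor (imputation-panel convention) |
| `exclude_self` | true | drop the index SNP from its own pool |
| `relax_steps` | 0 | opt-in MAF-band widening on empty pools |

The default window set is the package constant; `derive_window_sizes`
reproduces the derivation from a vector of SNP-to-gene distances as the
lower quartile, median, mean and upper quartile (linear interpolation
between order statistics, rounded to whole bp, sorted, de-duplicated).
Which summary produced which published size is not recoverable from the
sorted set, so the constant is provided explicitly.

## Synthetic data: what it emulates, what it does not

`simulate_inputs` generates non-overlapping, uniformly placed genes on a
multi-chromosome genome; a reference panel with uniform positions and
Beta-distributed folded MAFs floored at 0.001; a curated gene table with
a configurable dominant fraction (plus a small dual-inheritance fraction,
3.6%, mirroring curated lists); and an index SNP set. Defaults emulate
the study conditions at desk scale: 156 index SNPs, ~7% of genes curated
with 35% dominant, gene density proportional to a ~20k-gene genome, and a
50k-SNP panel standing in for a full imputation panel. Planted enrichment
is positional — a fraction of index SNPs is placed uniformly within a
maximum distance of a dominant-labelled gene — because positions and MAFs
are all the method sees.

Not emulated: linkage disequilibrium (lead SNPs are assumed independent),
recombination-rate or gene-density heterogeneity beyond random
fluctuation, MAF–position correlation, and genome-build details. Passing
tests on this generator therefore show the *inferential machinery* is
correct and calibrated when its assumptions hold; they do not show
robustness to LD structure or annotation error in real data.

## Validation harnesses and their problem sizes

* **Worked example** (packaged fixture): the two statistics reproduce the
  published counts (14/15 nearest; 13/25/36 gene-level at 19/94/258 kb;
  37 SNP-level at 258 kb). Two cells of the printed source table are
  internally ambiguous, so only the unambiguous aggregates are asserted.
* **Oracle equivalence**: 1000 random small fixtures check nearest-gene,
  window, candidate-pool and statistic computations against naive linear
  scans and exhaustive enumeration (integer-exact interval arithmetic in
  the oracle).
* **Matched-null validity**: 100 random configurations; every sampled
  entry re-checked against its recomputed pool — zero violations.
* **Calibration**: 50 index SNPs drawn from a 50k-SNP panel on a 400 Mb /
  4000-gene genome, gene-level statistic at 258 kb, 1000 null lists, 500
  replicates each redrawing the index SNPs and random 50% gene labels.
  The empirical p is uniform (Kolmogorov–Smirnov) and the fraction below
  0.05 is near nominal. Replicates with an infeasible exact-count pool
  are skipped; feasibility depends only on the matching profile, so this
  does not break observed/null exchangeability. Both the index set and
  the labels must be redrawn: with a fixed SNP set, the positional luck
  of that one draw (how many window-gene collisions it happens to have)
  shifts every replicate's p in the same direction.
* **Power**: 50 replicates with 30% of 50 index SNPs planted within 5 kb
  of dominant genes and a panel 100× the index-set size detect the
  enrichment at p ≤ 0.01 in every replicate (window mode; a matching
  failure would count as a miss).
* **Determinism**: identical inputs and seed produce byte-identical
  results files, including the floor rendering.

Problem sizes were chosen so the full suite runs in a few minutes on one
CPU; they are stated here so results can be read at the scale they were
computed.

## Numerical and design choices

* Coordinates are 1-based inclusive internally; BED is converted at the
  boundary and round-trips exactly. MAFs above 0.5 are folded with a
  warning (panel files often store ALT frequency); table round-trips are
  bit-exact (`%.17g` on write, round-trip parsing on read).
* One span per gene symbol (union of transcripts): the only gene model
  under which "nearest gene" and window membership compose consistently.
* Nearest-mode matching needs a dense panel: a ±10% band around a small
  distance is only a few tens of base pairs wide, so desk-scale panels
  frequently cannot populate it. The window-mode analyses are the
  recommended harness at small panel sizes (the CLI exposes
  `--skip-nearest`), and empty pools fail loudly rather than silently
  relaxing.
* Equidistant nearest-gene ties are broken by symbol; all randomness
  flows from a single integer seed through spawned generators.

## Limitations

Real-data results depend on the annotation build, the panel version and
the curated list vintage; this package deliberately reproduces the
method, its worked-example arithmetic and its operating characteristics,
not any full-cohort values. The empirical p resolution is 1/n_lists;
conclusions at the floor bound are bounds, not point estimates. LD-aware
matching (e.g. on LD score or genotyping-array membership) is out of
scope.
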