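# Methods

## Problem

Single-cell datasets routinely carry several categorical annotations of the
same cells — manual labels, reference-mapping calls, clustering results,
annotations derived from different modalities (RNA vs surface proteins in
CITE-seq). These frequently disagree, and the disagreement itself is
informative: it may reflect genuine biology one modality cannot resolve, or
mere method idiosyncrasy. `annoflow` quantifies which cells flow between
which labels (a cross-annotation contingency structure rendered as a Sankey
diagram) and explains a chosen disagreement by scoring which markers
actually separate the two cell populations, per modality.

## Cross-annotation flows

`build_crosstab(dataset, left, right)` counts cells per (left-label,
right-label) pair. Cells carrying the missing token (default `"NA"`) in
either column are excluded — a flow needs both endpoints — and the excluded
count is logged.

`filter_links(table, min_cells=20)` removes links with fewer than
`min_cells` cells, recomputes each node's total from its *surviving* links,
drops nodes below the threshold together with their links, and iterates to
a fixed point. Two deliberate choices here:

* **Fixed-point iteration.** Dropping a node orphans links, which changes
  other nodes' totals; a single filtering pass can leave nodes below
  threshold and its result depends on processing order. The fixed point is
  the only order-independent semantics, and it is idempotent by
  construction (verified exhaustively in tests).
* **Node totals from surviving flow, not raw label counts.** Displayed node
  sizes then always equal the visible flow through them, which is the only
  self-consistent Sankey rendering.

When everything is filtered away the error carries the largest threshold at
which anything would survive, so a user can immediately pick a viable value.
The default of 20 cells is a noise floor for visual interpretation and is
freely adjustable.

`merge_labels` adds a `<annotation>__grouped` column rather than rewriting
the original, so grouped and ungrouped views coexist. Merging then
cross-tabulating is exactly equivalent to cross-tabulating then summing rows
by the mapping (tested as an invariant).

## Marker relevance

The central numerical convention: **Cohen's d** between cell groups is

    d = (mean(x) − mean(y)) / sqrt((var(x) + var(y)) / 2)

with *population* variances (denominator n). If both variances are zero the
groups are point masses: d is 0 for equal means, otherwise ±∞ with the sign
of the difference. Infinities are legitimate values here (they mean "perfect
separation") and are ordered beyond all finite values when medians are
taken; the degenerate even-count median whose two middle values are −∞ and
+∞ is defined as 0 (balanced separation in both directions).

Two display-marker strategies, dispatched on dimensionality:

* **Low-dimensional** (feature count ≤ `high_dim_threshold`, default 1000 —
  e.g. a ~30-feature ADT panel): every feature is a candidate, ranked by
  absolute difference in mean normalized expression between the two
  selected populations. Both directions of difference are relevant, hence
  the absolute value.
* **High-dimensional** (strictly more than 1000 features — e.g. RNA):
  ranking thousands of mostly uninformative genes by raw mean difference is
  noisy and slow, so candidates are pre-selected per annotation group. For
  each feature and each ordered pair of groups the pairwise d is computed;
  each (feature, group) is summarized by the **median** of that group's d
  against every other group; each group contributes its top `k = 10` most
  upregulated features (strictly positive median d, ties broken by feature
  id ascending). The candidate set is the union of these top-k lists over
  every annotation referenced by the two selections' provenance — the
  inclusive reading, so either annotation's discriminative genes can
  surface. Effect tables are cached per (modality, annotation, k).
* **Prefiltered bypass**: a matrix the user has already restricted to
  markers of interest skips pre-selection entirely (`prefiltered=True`).

Groups with fewer than two cells have undefined variance and are dropped
from effect tables with a warning. `n_display` defaults to 8 markers;
user-`required` markers are always included, first, in their given order,
on top of the ranked picks. Median-only summarization (no min/max/mean of
pairwise effects, no p-values) is intentional: the ranking is an effect-size
screen, not a hypothesis test.

## Comparison payloads

For a selected pair of populations (nodes or links of the Sankey):

* **bars** — raw mean normalized expression per selection per panel marker;
  nothing hidden.
* **rose** — per-feature min–max scaling of the displayed means onto [0, 1]
  (min → 0, max → 1, all-equal → 0.5), so every petal of a radial plot is
  comparable across markers with different dynamic ranges. This scaling is
  invariant under affine transforms of a feature's expression. The radial
  scale is this package's documented choice of normalization for the rose
  display.
* **UMAP** — a 2-D embedding of the active (possibly subset) view over
  *all* features of a modality, seeded and single-threaded
  (`random_state` fixed, `n_jobs=1`), so identical invocations are
  bit-identical. Determinism is deliberately bought at the price of speed:
  reproducible exports are a headline feature. Cells are tagged sel1 /
  sel2 / both / background, background drawn first.

A report's `params.json` records every setting used (selections, markers,
strategy, seeds, neighbor counts), and rebuilding a report from params +
dataset reproduces every CSV byte-identically (tested).

## Export as code

`export` writes a bundle containing the report's primary data (raw bars,
UMAP coordinates, panel, params) plus `regenerate.py`, a plain-text script
that recomputes the derived table (the rose scaling) and re-renders every
figure from the bundled CSVs. Round-tripping regenerates the derived CSV
byte-identically. The CSVs, not the SVGs, are the canonical numeric record;
SVGs are still rendered reproducibly (fixed hash salt, no embedded date).

## Synthetic data generator

The generator emulates a CITE-seq-like experiment: a low-dimensional ADT
modality and a high-dimensional RNA modality over shared cells, planted
population structure, planted differential markers, and annotation schemes
with controlled disagreement (identity, merge, label noise ε, splits).

* **ADT is simulated directly on the normalized scale**: baseline + planted
  shift + Normal(0, σ), defaults baseline 1.0, σ = 0.5. The tool consumes
  normalized ADT, so post-normalization values are the faithful test
  target, and a planted shift δ between two populations is an exact true
  Cohen's d of δ/σ.
* **RNA is simulated as counts**: negative binomial via a gamma–Poisson
  mixture with per-gene mean drawn log-normal(log 2, 1) (typical droplet
  magnitudes) and dispersion φ = 0.5 (variance m + φm²), then log-CP10K
  normalized by the package's own `lognorm_counts` (natural log,
  pseudo-count 1, scale 10⁴ — the convention of standard scRNA
  normalization). Planted differential genes receive a log-fold shift on
  the NB mean. Because the standardized effect on the *normalized* scale is
  what downstream scoring sees, the ready-made scenarios calibrate that
  shift semi-analytically: the mean and variance of log1p(s·C) under the NB
  law are computed by direct pmf summation and the log-fold change solved
  by root finding so the true d equals the requested value (planted genes
  are given a fixed base mean of 4 so one calibration applies to all). At
  n = 500 cells/group the empirically recovered d is within ±0.1 of the
  2.0 target.
* Cell-to-population assignment is multinomial by proportion; everything is
  driven by one `numpy` Generator, so a seed fixes the dataset bit-for-bit.

Two ready-made scenarios define the test conditions used throughout:

* `differential_scenario`: 4 groups × 100 cells, 2000 genes, 5 planted RNA
  markers per group (and 2 ADT markers per group) at d = 2; schemes: truth
  and a noisy copy (ε = 0.05).
* `isoform_scenario` (500 cells): "naive-like" (40%) and "memory-like"
  (40%) share an identical RNA mean profile but are separated (d = 2) in
  two anti-correlated planted ADT features, `CD45RA_like` and
  `CD45RO_like` — the protein-isoform situation in which two T-cell states
  differ at the surface-protein but not the transcript level. A third
  "other" population (20%, genuinely RNA- and ADT-distinct) keeps both
  annotation schemes at ≥ 2 labels; the `rna_based` scheme merges the two
  subpopulations into one "central-memory-like" label, producing the
  characteristic two-links-into-one-node crosstab.

**What the generator does not emulate**: batch effects, doublets, ambient
RNA, modality-specific dropout structure, per-modality cell subsets, or
realistic gene–gene correlation. Passing tests on this generator
demonstrate the comparison machinery's correctness and calibration on data
with known truth; they do not certify performance on real data with
structured noise.

## Numerical choices and degenerate inputs

* Population (ddof 0) variances everywhere in effect sizes; ±∞ for
  zero-variance separated groups; ties in rankings broken by feature id
  ascending, so every ordering is total and deterministic.
* Problem sizes in tests and in the acceptance script (500 random oracle
  datasets ≤ 50 cells; 50–100 generator seeds per recovery property; 30×15×3
  effect-table oracles) were chosen to make sampling margins comfortable
  for the planted effect sizes while keeping the default suite quick.
* Empty subsets, empty selections, all-filtered link sets, NaN matrices,
  square MTX orientation ambiguity, and unknown names all raise dedicated
  typed errors rather than returning empty structures.
* The MTX writer emits 17 significant digits so float64 values round-trip
  exactly.

## Known limitations

* One dataset in memory; no on-disk backed matrices.
* All modalities must share the full cell set (no per-modality subsets).
* R serialization (RDS) input is out of scope; convert upstream (see
  README).
* Node selection ignores link filtering: selecting a node selects every
  cell with that label, whether or not some of its links were filtered out
  of the diagram.
* The interactive web layer of comparable tools is out of scope; this
  package is the scriptable, testable core.
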