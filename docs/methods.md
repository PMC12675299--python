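# Methods

This note records the models, parameter choices and numerical conventions
behind `plaquemap`, and what the synthetic benchmarks do and do not
demonstrate about real tissue.

## Scope and data model

The package analyses imaging spatial transcriptomics (MERFISH-style) data of
cortical microglia around amyloid plaques. Its inputs are: a cells × genes
panel count matrix; per-cell metadata (centroid in µm, segmented volume in
µm³, sample id, optional cluster label); a plaque table of four perimeter
points per plaque; a traced region polygon (e.g. the cortex); and a nuclear
PU.1 intensity table. Expression values carry an explicit layer tag
(`raw → sample_scaled → per_um3 → lognorm`) and each operation checks the
layer it requires, so normalization steps cannot be silently reordered.

## QC and normalization cascade

The stage order is fixed: transcript/volume filter → sample scaling → volume
normalization → unique-gene filter → log normalization.

* Cells with fewer than 40 total transcripts or a volume below 100 µm³ are
  removed; both comparisons are strict (a cell at exactly 40 transcripts or
  exactly 100 µm³ survives). Cells detecting fewer than 11 unique genes are
  removed after volume normalization; since scaling preserves positivity,
  the unique-gene count is identical on any layer (asserted by test).
* Sample scaling multiplies every cell of sample *s* by
  `mean_s'(mean per-cell total of s') / mean(per-cell total of s)` — the
  unweighted grand mean of per-sample means. This is the simplest reading of
  "equalize total transcripts per cell across samples"; rescaling to a
  reference sample would differ only by a global constant, which the later
  per-cell log normalization cancels anyway. The applied factors are
  recorded in the QC report.
* Log normalization is `x = ln(1 + 10^4 · v / Σv)` per cell (natural log;
  the base and scale factor are recorded in the output metadata). The
  invariant `Σ(eˣ − 1) = 10^4` holds per cell to float precision and is
  enforced by test at 1e-6 relative tolerance.
* Non-finite values anywhere are a hard error; nothing is coerced.

## Plaque geometry and proximity

Each plaque's four recorded perimeter points are re-ordered
counter-clockwise about their centroid, which yields a simple quadrilateral
for any non-degenerate input; collinear or duplicated points raise. The
distance from a cell centroid to a plaque is 0 on or inside the outline and
otherwise the minimum Euclidean distance to the four boundary segments
(shapely). Measuring to the segments rather than only to the four vertices
is the natural reading of an "edge defined by four perimeter points"; a
`vertices_only` flag provides the alternative for sensitivity analysis.

Classification uses the nearest plaque (ties to the smallest plaque id):
`d ≤ 15 µm` → plaque-associated, `d > 15 µm` → distal. The boundary value
15 µm itself is assigned to the associated class — measure-zero in practice
but fixed for determinism. Cells outside the region polygon are excluded
from classification and from downstream group assignment; boundary points of
the region count as inside (even-odd rule). A 5 µm cutoff variant (the
process-contact convention used for volumetric image quantification) is
available as `--cutoff-um 5` on the same centroid distance; true
process-surface geometry is out of scope.

Distal density divides the distal count by region area minus summed plaque
areas — the two-dimensional analogue of normalizing to cortex volume minus
plaque volume; the output records the dimension (cells/µm²).

## Differential expression

`find_markers` mirrors the standard single-cell marker workflow: genes are
pre-filtered (`max(pct1, pct2) ≥ min_pct`, default 0.01, and
`|log2FC| ≥ 0.25`), then tested, then adjusted over the tested set (the
denominator is recorded in the output metadata). The fold change is computed
on de-logged means with pseudocount 1:
`log2((mean(eˣ−1)+1) / (mean(eʸ−1)+1))`, consistent with the lognorm layer
and the conventional threshold scale. Benjamini–Hochberg is the default
adjustment with a Bonferroni option; rank order of p values is preserved and
outputs are capped at 1.

The Wilcoxon rank-sum test uses midranks. For tie-free samples with
`n1 + n2 ≤ 12` it enumerates all C(n, n1) group assignments and reports
`P(|W − E W| ≥ |w − E W|)` exactly; otherwise it uses the normal
approximation with tie correction and a 0.5 continuity correction (verified
to 1e-9 against an independent implementation). Exhaustive comparison shows
exact and approximate p agree within 0.05 for groups of at least three; with
groups of two the approximation can deviate by up to 0.088, which is
irrelevant in practice because the exact path is reported there. If all
pooled values are identical the test returns p = 1.

## Module scores and categorization

The score follows the control-gene-bin construction: genes are ranked by
mean expression and cut into 24 equal-frequency bins; each signature gene
draws 100 control genes from its own bin (seed-controlled), excluding
signature genes, without replacement when the bin allows; the per-cell score
is mean(signature) − mean(pooled controls). Two numerical choices differ
from the textbook description and are recorded in the result parameters:
controls are drawn with replacement when a bin is smaller than the request,
and the pool widens to neighbouring bins when a bin contains only signature
genes — both are inevitable on a few-hundred-gene panel where nine lymphoid
genes can fill an entire bin. The score is invariant to adding a constant to
the matrix and is zero on a constant matrix.

Bundled signature sets: lymphoid (9 genes: *Cd28*, *Cd274*, *Pdcd1*,
*Ctla2a*, *Cd5*, *Sox5*, *Cd48*, *Cd52*, *Cd72*), interferon (15 genes,
de-duplicated), DAM (*Cst7*, *Apoe*, *Lpl*, *Itgax*) and homeostatic
(*Cx3cr1*, *Tmem119*, *P2ry12*, *Csf1r*, *Hexb*, *Sall1*, *Selplg*); all
user-overridable.

Cluster categorization compares mean DAM vs mean homeostatic module score
within each cluster. Because module scores can be negative, a literal score
*ratio* is ill-defined; the mean difference decides (tie → homeostatic, the
null category) and the ratio is reported alongside for reference. DAM
clusters split into lymphoid⁺/lymphoid⁻ by the sign of the mean lymphoid
score — a threshold choice, recorded as such.

## PU.1 intensity states

The classifier is a stored calibration: fold change `f = 1.25`, measured
once as mean PU.1 signal of PU.1-high reference nuclei over PU.1-low
reference nuclei, applied around the population mean `m` of each
experiment/batch (per `sample_id` by default): low < `m/f`,
high > `m·f`, medium in `[m/f, m·f]` (values exactly at a cutoff are
medium — "between the cutoffs"). Recomputing `f` from reference tables is
supported but optional. Classification is invariant under joint rescaling
of intensities and references; widening `f` only grows the medium class.

## Synthetic tissue generator

The generator's defaults define the study conditions all recovery tests run
under. They were chosen once, by design, to emulate a cortical window of an
8–10-month 5xFAD section at desk scale:

| parameter | default | rationale |
|---|---|---|
| panel size | 398 genes | the MERFISH panel scale; 30 program genes + 15 interferon background genes + generic panel genes |
| cells | 6,000 (+15 injected QC failures) | a realistic microglia count for a 1 mm² window; gives ~550 plaque-associated cells |
| plaques | 40, radii 10–20 µm | high cortical plaque burden at this age |
| state fractions | 0.65 homeostatic / 0.25 DAM / 0.10 lymphoid-DAM | DAM abundant, lymphoid-DAM a minority subset of DAM |
| proximity enrichment | ×10 odds for DAM and lymphoid-DAM within 15 µm | encodes the premise that these states concentrate at plaques; the logistic-odds form is a modelling choice |
| counts | NB (gamma–Poisson), shared dispersion 2, baseline 1 count/gene | minimal model adequate for rank-based DE; ~400 counts/cell |
| program effect | log2FC = 2 on each program's genes | marker-scale effects; lymphoid-DAM cells activate both the DAM and lymphoid programs |
| gene baselines | program genes flat at baseline; background genes lognormal, mean 1, log-sd 1 | real panels span orders of magnitude; flat baselines would make expression bins degenerate. Keeping program-gene baselines flat balances per-state totals so library-size normalization does not bias program log2FC estimates |
| sample structure | 2 samples, capture depth ×1.0 / ×1.3 | exercises sample scaling |
| volumes | lognormal, median 300 µm³, log-sd 0.35, floored at 105 µm³ | the floor keeps the volume filter's expected survivor count exact: only injected cells fail QC |
| intensities | three lognormals, log-sd 0.08, adjacent means a factor 1.25² apart; lymphoid-DAM → low, homeostatic → medium, DAM → high | plaque-associated microglia split into PU.1-high and PU.1-low subsets while the homeostatic bulk is medium. The 1.25² spacing places the f = 1.25 cutoffs at the geometric midpoints between components, so a mixture with near-symmetric weights is recovered cleanly |
| QC failures | 5 cells each: < 40 transcripts, < 100 µm³, < 11 genes | injected with known ids so filter tests have exact expected outcomes |

One `SeedSequence` per dataset is split hierarchically into per-stage
streams (plaques, cells, states, gene baselines, counts, intensities), so an
identical config + seed reproduces every artifact byte for byte, and each
stage is individually reproducible.

What the generator does **not** emulate: optical crowding and segmentation
errors (counts are conditionally independent NB given state), cell-type
mixtures beyond microglia, spatial autocorrelation of expression within a
state, 3-D geometry, or intensity saturation. Passing recovery tests
therefore shows the analysis chain is correct and calibrated under its own
assumptions — not that those assumptions hold in any particular tissue.

## Numerical conventions and degenerate inputs

* Exact ties: proximity 15 µm → associated; intensity at a cutoff → medium;
  DAM = homeostatic mean score → homeostatic; nearest-plaque tie → smallest
  plaque id.
* Degenerate geometry (duplicate/collinear plaque points, zero-area
  regions), empty groups, zero-total cells reaching log normalization,
  non-finite values, p values outside (0, 1] — all hard errors naming the
  offending records.
* The pipeline report contains stage counts, resolved config and artifact
  checksums but no timing, so identical config + seed yields byte-identical
  reports; wall-clock goes to the log.
* CSV round-trips use `float_precision="round_trip"` parsing; the default
  pandas parser can be one ulp off, which would break byte-identical
  re-serialization.

## Benchmark sizes

The test suite and acceptance script scale simulations to desk size: the
geometry oracle uses 1,000 random point/plaque pairs against a 10⁵-point
boundary sampling; type-I calibration pools 10 null datasets of 2,000 cells
× 100 genes; effect recovery uses 20 datasets with 500 vs 500 cells;
proximity-enrichment recovery uses 20 default datasets; mixture recovery
uses 5,000 nuclei. These sizes give the comparisons enough resolution
(3 binomial SE bands of roughly ±2 percentage points) while the whole suite
runs in about a minute.

## Known limitations

* The sample-scaling formula and the DE adjustment method are reasonable
  conventions for steps whose exact original form is underdetermined; both
  are configurable and recorded in outputs.
* Module-score control draws on a small panel depend on bin occupancy;
  cross-implementation agreement (scanpy) is rank-level (Spearman > 0.9 at
  398 genes), not value-level.
* The PU.1 multiplicative cutoff rule assumes the pooled mean lies between
  the low and high populations; for strongly skewed mixtures the medium
  class absorbs a neighbouring component. This is a property of the
  published rule, not of the implementation.
* Proximity uses 2-D centroid-to-edge distance; soma/process geometry and
  3-D distances are out of scope.
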