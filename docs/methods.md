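# Methods

This note records the statistical model behind `pasqc`, the design
decisions embedded in its defaults, the semantics of the synthetic-study
generator, and the recipe for applying the pipeline to a real expression
study.

## Pathway activation scoring

For case line *l* and pathway *p* with member genes *n*:

```
PAS_pl = Σ_n  ARR_np · BTIF_nl · lg(CNR_nl)
```

* **CNR** (case-to-normal ratio): expression of gene *n* in line *l*
  divided by the geometric mean of the control lines' expression. On the
  log₁₀ scale this is simply `lg(x_nl) − mean(lg x over controls)`.
* **BTIF** (beyond-tolerance-interval flag): 1 iff
  `|lg CNR_nl| > max(k·SD_n, floor)` with `SD_n` the control group's
  per-gene log₁₀ SD (n−1 denominator; 0 for a single control line).
  Defaults: `k = 2.0`, `floor = 0.1` log₁₀ units (≈ 1.26-fold). The
  `k·SD` term adapts the band to each gene's control variability; the
  floor guards genes whose control variance is spuriously small. The
  comparison is strict, so values exactly on the band do not count.
* **ARR** (activator/repressor role): a discrete weight in
  {−1, −0.5, 0, 0.5, 1} encoding whether the gene activates or represses
  the pathway and how strongly.

Missing pathway genes (not on the chip) are skipped with a warning by
default (`missing_genes="warn"`); `"strict"` raises instead.

**Reference policies.** The pooled reference aggregates all control lines.
Under `leave_one_out` (the default in the high-level model), each control
line is scored against a reference rebuilt without that line, so no line is
ever compared to a reference containing itself. Non-control lines always
use the pooled reference.

**Preprocessing.** Replicate arrays are averaged on the linear intensity
scale per cell line before scoring. Optional quantile normalisation maps
each sample to the common distribution of row-wise means of the
column-sorted matrix; ties receive the mean reference value across the tied
ranks (deterministic and rank-preserving; exactly idempotent on tie-free
data).

## Per-pathway statistics

**Group test.** The default per-pathway test is a two-sided one-sample
t-test of the group's PAS values against 0, with Benjamini–Hochberg
adjusted q-values across pathways (step-up,
`q_(i) = min_{j≥i} m·p_(j)/j`). This is fast and standard, but it treats
the group's lines as independent given the reference. With few control
lines the reference's own estimation error is shared by every case line,
which correlates their PAS and makes the t-test measurably anticonservative
(false-positive rates up to ~0.17 instead of 0.05 on null pathways of the
synthetic generator's default study).

**Permutation alternative.** `permutation_group_test` shuffles the
case/control label assignment and rebuilds the reference (mean, SD and
tolerance band) from each permuted control set, using the group-mean PAS as
the statistic and the `(exceedances + 1)/(permutations + 1)` p-value. This
propagates reference uncertainty and is the test used by the
parameter-recovery validation; the t-test remains the default elsewhere.

**Variability and deviation.** Pathway variability within a group is the
sample SD of PAS across the group's lines (rank 1 = most variable; ties
broken by name). `shared_top` counts the overlap of two groups' k most (or
least) variable pathways. `deviation_correlation` is the squared Pearson
correlation between two groups' per-pathway SD vectors — high R² indicates
the groups share one variance structure over pathways.

## Quality corridor

The ESC group defines, per pathway, the corridor
`[mean − width·SD, mean + width·SD]` of PAS across ESC lines
(`width = 1` by default). By default the corridor is restricted to pathways
significantly dysregulated in the ESC group (q < 0.05) — these are the
pathways that carry the pluripotency program and where "looking like an ESC
line" is informative. Bounds are inclusive. A case line passes when its PAS
lies inside the corridor on at least 50% of corridor pathways; lines below
the threshold are flagged, worst first.

## Sparse signature

An L1-penalised logistic regression on standardised per-pathway PAS
features separates fibroblasts (class 1) from iPSC lines (class 0). The
penalty λ (the optimisation is `min ‖w‖₁ + (1/λ)·Σ log-loss`) is chosen by
inner leave-one-out cross-validation over a log-spaced grid, ties going to
the larger (sparser) λ. Constant features are dropped with a warning; when
the penalty removes every coefficient the model predicts the training
majority class. Reported accuracy uses an outer leave-one-out loop that
refits the full procedure — including λ selection — per fold. The solver is
liblinear with an effectively unpenalised intercept.

## Synthetic studies

The generator produces a study of ESC, iPSC, fibroblast (FIB) and
embryoid-body (EB) lines with replicates, a disjoint-gene pathway
collection (default 271 pathways of 8–25 genes, ≈ 4 500 gene roles),
and known ground truth. On the log₁₀ scale, each gene's intensity is:

```
baseline_g + groupshift_g + η_lp·ARR_g + linenoise_gl + impair_gl + measnoise_glr
```

* `baseline_g ~ Normal(2.5, 0.5²)`.
* **Stem program:** 70% of pathways are designated stem-program pathways;
  ESC and iPSC lines shift every member gene by `δ·ARR` (δ = 0.5), pushing
  those pathways' PAS to ≈ `δ·Σ ARR²` against the fibroblast reference. EB
  lines receive the shift attenuated (×0.3); fibroblasts sit at baseline.
* **Pathway variability profile:** each pathway carries a multiplier
  `f_p ~ LogNormal(0, 1.2²)` scaling the line-to-line noise of its member
  genes in the pluripotent groups. This is what makes some pathways
  reproducibly "most variable". Fibroblast controls — a homogeneous somatic
  cell type — keep unscaled baseline noise; scaling the controls too would
  make the tolerance band proportional to the signal being measured and
  censor the variance structure the deviation analysis estimates. With
  `shared_variance_profile=False`, ESC and iPSC draw independent profiles.
  The spread 1.2 was calibrated once from a ceiling analysis: the
  deviation-correlation R² between two groups' SD estimates is bounded by
  SD-estimation noise at the study's group sizes (n = 20/12), and the
  profile heterogeneity must dominate that noise for the shared-profile
  R² ≥ 0.9 recovery property to be achievable at all.
* **Coherent activity effect:** per line and pathway,
  `η_lp ~ Normal(0, (0.1·f_p)²)` applied as `η_lp·ARR` to every member
  gene. Per-gene noise alone averages out at the pathway level
  (`Var ∝ Σ ARR²`); genuine line-to-line pathway activation differences
  scale with `(Σ ARR²)²` and are what the variability analyses measure.
* **Planted impaired lines:** selected iPSC lines shift a random 60% of
  the stem-program pathways by ±3 corridor half-widths. The half-width
  (SD of PAS across ESC lines) is known analytically,
  `hw_p² = σ_eff²·ΣARR² + (σ_act·f_p·ΣARR²)²` with
  `σ_eff² = (σ_line·f_p)² + σ_meas²/replicates`, and is converted to a
  per-gene log₁₀ shift `s = shift·hw_p/ΣARR²`, so the planted PAS
  displacement is exact in expectation. Impaired pathways are drawn from
  the stem program, whose genes already sit beyond the tolerance band, so
  the displacement is not silently absorbed by the flag.
* Per-gene line noise `Normal(0, (0.05·f_p)²)` and per-replicate
  measurement noise `Normal(0, 0.05²)` complete the model.

Everything is driven by one seed; ground truth records group membership,
the stem-program set, and each planted line's expected per-pathway PAS
displacement.

### Validation scenarios

* **Impaired-line recovery:** on the default design (20 ESC, 12 iPSC with
  3 planted impaired, 6 FIB), the planted lines receive the lowest quality
  scores and fall below the 50% threshold in ≥ 19 of 20 seeds.
* **Deviation structure:** with shared variance profiles and no planted
  impairments (planted impairments deliberately violate the shared-profile
  assumption), the ESC-vs-iPSC deviation R² over fibroblast-referenced PAS
  restricted to ESC-significant pathways averages ≥ 0.9 over seeds;
  independent profiles give R² ≪ 0.5.
* **Signature recovery:** on a cleanly separable 12-vs-6 design
  (between-class pathway effect ≥ 10× the within-class SD:
  `pathway_noise_spread = 0`, `activity_sd = 0.04`, 60 pathways), LOOCV
  accuracy is 1.0 and every selected pathway is a planted stem-program
  pathway, for 10/10 seeds.

## Applying the pipeline to a real study (e.g. GSE25970)

The pipeline is data-source-agnostic; no downloads are performed by the
package. To reproduce a compendium-style analysis on a public series such
as GEO accession GSE25970 (human ESC, iPSC, fibroblast and EB arrays):

1. Export the series' normalised expression matrix as a genes × samples
   TSV of strictly positive intensities, and build the sample table
   (`sample_id`, `line_id`, `group` with groups `ESC`/`iPSC`/`FIB`/`EB`),
   mapping replicate arrays of one line to one `line_id`.
2. Supply your own pathway database as a `pathway  gene  arr` TSV (or
   import plain gene sets from GMT with a uniform ARR via `import_gmt`,
   losing repressor information). Gene identifiers must match the
   expression matrix rows.
3. Score against fibroblasts:
   `pasqc score --expression expr.tsv --samples samples.tsv
   --pathways db.tsv --reference-group FIB --quantile-normalize --out scored`.
4. Quality-screen the iPSC lines against the ESC corridor:
   `pasqc qc --pas scored/pas.tsv --samples samples.tsv --out quality.tsv`.
5. Fit the fibroblast-vs-iPSC signature:
   `pasqc signature --pas scored/pas.tsv --samples samples.tsv --out sig`.
6. For the ESC-referenced variant of the deviation analysis, score with
   `--reference-group ESC --policy leave_one_out` so each ESC line is
   compared against the other ESC lines only, then correlate the ESC and
   iPSC per-pathway SD vectors (`deviation_correlation`). Note that under
   the adaptive `k·SD` tolerance band an ESC reference absorbs part of the
   very dispersion being measured, so the fibroblast-referenced
   configuration is the better-behaved default for this statistic.

This recipe is documentation only; the test suite runs exclusively on the
synthetic generator.

## Limitations

* The t-test default is anticonservative when the control group is small;
  prefer `permutation_group_test` for calibrated error rates.
* PAS values are unnormalised sums over member genes, so scores are
  comparable across lines within a pathway but not across pathways of
  different size or topology weight.
* The quality threshold (50% of corridor pathways) and corridor width
  (1 SD) are conventions, not fitted quantities; both are parameters.
* The generator's pathways are gene-disjoint; real pathway databases share
  genes across pathways, which correlates PAS between pathways in ways the
  synthetic validation does not exercise.
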