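# Methods

## The screening model

The pipeline operationalizes a two-dataset temporal contrast. In a
scarless wound-healing course (single arm, baseline at 0 h, replicated
arrays at each post-injury timepoint), "transient induction" is defined
by three gates applied per gene:

1. **Induction**: fold change FC(t) ≥ `induction_fold` (default 2.0,
   inclusive) at every induction timepoint (default 12 h and 24 h — an
   all-timepoints policy; an `any` policy is available but off).
2. **Significance**: two-sided p < `alpha` (default 0.01) at every
   induction timepoint. The gate defaults on; it can be disabled, since
   a plain fold-change screen is also a defensible reading of the
   criterion.
3. **Baseline return**: FC at the return timepoint (default 72 h = 3
   days; "3 days" is normalized to hours at config load) within
   [1 − band, 1 + band], band = 0.20, both ends inclusive on the linear
   fold-change scale. The band is tested at the return timepoint only;
   later timepoints are reported but not gating.

Genes passing gates 1–2 but failing 3 are `INDUCED_NOT_RETURNED`;
everything else is `NOT_INDUCED`. In the two-arm fibrosis course,
`SUSTAINED_UP` requires FC ≥ `sustained_fold` and p < alpha at **every**
treated timepoint, each treated group compared to its timepoint-matched
control when present, else to the pooled control arm (the fallback is
logged per run). The candidate list is the set intersection over shared
gene ids, ranked by descending maximum wound fold change then gene id.

### Numerical and statistical choices

* **Central abundance** is the geometric mean of replicates (arithmetic
  mean in log2). This matches the multiplicative error model of array
  abundances; the alternative (arithmetic mean of linear values) inflates
  fold changes under skewed noise.
* **Tests** run on log2 values: Welch's unequal-variance t (default) or
  Mann–Whitney U (exact null distribution when samples are small and
  tie-free, otherwise the tie-corrected normal approximation). No
  multiple-testing correction by default — the screen is a fixed-threshold
  filter, not an FDR-controlled discovery list; a Benjamini–Hochberg
  per-timepoint option (`fdr_correction`) is available.
* **Degenerate tests.** With replicate noise exactly zero, within-group
  variance vanishes and the t statistic is undefined. Zero variance in
  *both* groups is resolved as the limiting case: p = 1 for equal means,
  p = 0 for unequal means, flagged as degenerate. A test that cannot be
  formed at all (fewer than 2 replicates per group for Welch) yields
  p = NaN and fails the significance gate when the gate is on. Group
  constancy is detected by zero range (max − min), not by computed
  variance, which can be ~1e-15 for bit-identical replicates due to
  rounding in the mean.
* **Positivity floor.** Cells ≤ 0 (possible in background-subtracted
  matrices) are raised to half the smallest positive value in the matrix
  before the log transform; the count is reported as a warning.
* **Tie-breaks.** Result rows sort by (class label, −max fold change,
  gene id); intersection hits by (−max wound fold change, gene id).
* **Serialization.** Floats are written with `repr` (shortest round-trip
  form), so matrix and results files are byte-deterministic and
  write→read is lossless.

## The synthetic-data generator

Each gene g draws a baseline abundance `2^B_g`, B_g ~ Normal(7.0, 1.5²)
in log2 units (abundances centred near 128 with ~3 decades of spread,
typical of normalized array intensities). Its expected trajectory is a
per-timepoint fold multiplier from a class template; a replicate
measurement is

```
x_{g,t,r} = 2^(B_g) · m_g(t) · 2^ε,   ε ~ Normal(0, noise_log2_sd²)
```

Multiplicative log-normal noise (default sd 0.2 log2 units, a replicate
CV of ≈15%) keeps values strictly positive and makes log2 replicate
values Gaussian, the regime both tests assume.

Templates anchor the contract-bearing timepoints exactly — TRANSIENT:
peak fold (default 10, the amphiregulin scale) at 12–24 h and exactly 1
at ≥ 72 h; SUSTAINED: peak at every post-injury timepoint; LATE and
REPRESSED as controls; FLAT ≡ 1 — with log-linear interpolation at grid
timepoints between anchors. Class counts are apportioned by largest
remainder so they sum exactly to `n_genes`, and assigned blockwise in the
order the proportions are declared. Per-gene RNG streams are spawned
deterministically from the dataset seed (wound and fibrosis courses use
distinct spawn keys), so a given seed is bit-reproducible and enlarging
the gene panel never perturbs earlier genes' draws.

The default wound grid (0/6/12/24/72/120/168/240 h, n = 3) is a
configuration choice emulating a multi-timepoint injury course, not a
claim about any particular public accession; the fibrosis course is
two-arm (control "PBS" vs treated "BLM") over its own grid.

**What the generator does not emulate:** probe-level effects, count
(negative-binomial) sampling noise of RNA-seq, batch effects, correlated
genes, or baseline-dependent variance. Passing the recovery tests
therefore demonstrates the correctness of the screen's arithmetic and
decision logic under its assumed noise model — not its operating
characteristics on real accession data, where normalization and batch
structure dominate.

## qPCR (comparative Ct)

`ΔCt(s) = mean Ct_target(s) − mean Ct_reference(s)`; `ΔΔCt = ΔCt(s) −
ΔCt(calibrator)`; `RQ = 2^(−ΔΔCt)`. Replicate Cts aggregate by
arithmetic mean with no outlier rejection; amplification efficiency is
fixed at 2.0 (the method's assumption; standard-curve efficiency
correction is out of scope). The calibrator sample is always an explicit
argument — there is no defensible default. The ΔCt replicate SD combines
target and reference SDs in quadrature. Plausible Ct range defaults to
[0, 45] cycles.

## Verification design

Unit oracles are independent re-implementations: a plain-Python
per-gene/per-timepoint loop for fold changes and Welch p-values
(agreement 1e-12 relative on FC, 1e-9 absolute on p), exhaustive
enumeration over all 70 rank splits for the n = 4 Mann–Whitney exact p,
and hand scalar arithmetic for ΔΔCt. Property tests cover threshold
monotonicity (stricter criteria can only shrink the transient set),
permutation invariance of labels under row/column shuffles, group-swap
symmetry of p-values, RQ shift invariance, and largest-remainder
apportionment.

Recovery benchmarks use a 500-gene design (10% transient at peak fold
10, 10% sustained, 80% flat, n = 3): recovery is exact at zero noise; at
noise sd 0.2 a 20-replicate pilot (seeds 100–119) observed transient
sensitivity 0.82–1.00 (mean 0.92) and precision 1.00 throughout, and the
test bounds were frozen at ≥ 0.80 / ≥ 0.95. The sensitivity loss is
intrinsic to the ±20% return band: the sampling sd of log2 FC(72 h) at
n = 3 is ≈ 0.163, versus a band half-width of log2(1.2) ≈ 0.263, so
~10% of true transients drift out of band. These problem sizes keep the
full suite under a few seconds.

## Known limitations

* The screen tests each timepoint marginally; no trajectory model
  (splines, autocorrelation) and no moderated-variance (empirical-Bayes)
  testing — deliberate, to keep the classifier identical to the
  fold-threshold rule it implements.
* With n = 3 replicates, Welch's t at alpha 0.01 has limited power for
  fold changes near the threshold; the planted fold-10 effects are far
  from this regime.
* The intersection treats the two datasets as independent screens; no
  joint model or cross-dataset normalization is attempted.
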