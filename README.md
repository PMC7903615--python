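# fibroscreen

Fibrosis is a pathological wound-healing process; oral-mucosa wound
healing is scarless. A gene that is **transiently induced** during
scarless wound healing but **persistently upregulated** during skin
fibrosis is a candidate driver of the fibrotic process — the pattern by
which amphiregulin (*Areg*) was singled out as critical for
bleomycin-induced skin fibrosis, a hallmark of scleroderma.

`fibroscreen` implements that cross-dataset temporal expression screen as
a tested, reusable pipeline for computational biologists working with
time-course expression matrices (microarray or bulk RNA abundance):

* **synthetic data** — paired wound-healing and fibrosis time-course
  matrices with planted temporal classes and known ground truth, so every
  stage runs without any download;
* **screen** — per-gene fold changes versus baseline with per-timepoint
  significance tests, transient/sustained classification, and the
  cross-dataset intersection;
* **qpcr** — comparative-Ct (ΔΔCt) relative quantification for validation
  plates;
* **cli** — `fibroscreen` subcommands wiring simulate → screen →
  intersect with reproducible seeds and a run manifest.

## The screen

For gene *g* at timepoint *t*, the fold change versus baseline is the
ratio of geometric means over replicates,

```
FC_g(t) = geomean(x_g at t) / geomean(x_g at baseline)
```

with a two-sided Welch *t* test (or Mann–Whitney) of the log2 replicate
values giving `p_g(t)`. A gene in a single-arm injury course is

* `TRANSIENT_INDUCED` if `FC ≥ 2` at **both** 12 h and 24 h, `p < 0.01`
  at both, and `FC(72 h) ∈ [0.80, 1.20]` (returned to baseline ± 20%);
* `INDUCED_NOT_RETURNED` if induction passes but the return test fails;
* `NOT_INDUCED` otherwise.

In a two-arm (control vs treated) fibrosis course, a gene is
`SUSTAINED_UP` iff `FC ≥ 2` with `p < 0.01` versus timepoint-matched
controls at **every** treated timepoint ("upregulated throughout").
The candidate list is the intersection: transient in the wound course
AND sustained in fibrosis. All thresholds are configurable
(`ScreenCriteria`).

qPCR validation uses the comparative-Ct method: `ΔCt = Ct_target −
Ct_reference` (reference *Gapdh* for mouse), `ΔΔCt = ΔCt(sample) −
ΔCt(calibrator)`, `RQ = 2^(−ΔΔCt)`.

## Worked example

A 60-gene tutorial run (`examples/tutorial.yaml`): zero replicate noise,
one gene aliased `Areg` planted transient (peak fold 10) in the wound
course and sustained in the fibrosis course.

```sh
fibroscreen run --config examples/tutorial.yaml --out out/
# 1 candidate hit(s); manifest at out/manifest.json
cat out/candidates.tsv
```

```
gene_id  wound_class        fibrosis_class  max_wound_fc        min_fibrosis_fc
Areg     TRANSIENT_INDUCED  SUSTAINED_UP    10.000000000000002  9.999999999999996
```

The planted gene is the sole hit: it rose 10-fold at 12–24 h and returned
to baseline by 72 h in the wound course, yet stayed 10-fold above
timepoint-matched controls throughout the fibrosis course. The manifest
records the gate counts — of 60 genes, 12 passed the 2-fold induction
gate at both early timepoints, 6 of those returned to within ±20% of
baseline by 72 h (`TRANSIENT_INDUCED`), and exactly 1 of the 60 was
sustained in the fibrosis arm:

```
screen_transient: {genes_in: 60, induced: 12, significant: 12, returned: 6,
                   TRANSIENT_INDUCED: 6, INDUCED_NOT_RETURNED: 6, NOT_INDUCED: 48}
screen_sustained: {genes_in: 60, SUSTAINED_UP: 1, NOT_SUSTAINED: 59}
intersect:        {hits: 1}
```

(The 6 `INDUCED_NOT_RETURNED` genes are the planted sustained-in-wound
class — induced but still high at 72 h.)

Each stage is also independently invocable (`fibroscreen simulate`,
`fibroscreen screen transient|sustained|intersect`,
`fibroscreen qpcr rq`); see `--help`.

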