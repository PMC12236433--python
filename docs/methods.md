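# Methods

## Study design being modelled

Two adjacent mesoscale eddies of opposite polarity are sampled
identically: a high-resolution depth survey of 15 samples at 5 m
intervals centred on each eddy's deep chlorophyll maximum (DCM), and a
diel Lagrangian series of 18 DCM samples per eddy at ~4 h spacing. The
default DCM depths are 100 m (cyclone) and 120 m (anticyclone), a ~20 m
displacement typical of the isopycnal uplift in cyclones. Filtered
volumes are 1–2 l per sample. All defaults live in
`eddyomics.simulate` and `eddyomics.config`.

## Statistical primitives (`eddyomics.stats`)

All four tests are implemented in the package and cross-checked in the
test suite against independent references (scipy, statsmodels, brute-force
enumeration, large-count normal approximations).

* **Pearson correlation** with the exact two-sided t transform
  `t = r sqrt((n−2)/(1−r²))`, n−2 df. Chosen over bootstrap/permutation
  because the screen runs on ~30 depth samples where the t reference is
  standard; constant inputs are rejected rather than returned as r = 0.
* **Kruskal–Wallis H** with midranks and the tie-correction divisor
  `1 − Σ(t³−t)/(N³−N)`; p from χ²(k−1). The χ² approximation is adequate
  at the design's n = 18 per group; an exact two-group permutation null
  (complete enumeration) is available via `exact=True` for tiny samples.
  Tie correction is always applied and is exercised by a dedicated
  hand-computed example. All-identical data return H = 0, p = 1.
* **Benjamini–Hochberg** step-up, stable-sort tie handling, capped at 1.
  Applied once per analysis over the full feature universe (all tested
  taxa; all transcripts of all tested taxa), never per flag direction.
* **Two-group negative-binomial Wald test** (`nb_wald_matrix`): per-group
  means on size-factor-scaled counts; a per-feature dispersion α by pooled
  method of moments, `α = (s² − μ)/μ²` averaged over the two groups and
  floored at 1e-8; Wald statistic on `log μ_b − log μ_a` with the
  delta-method standard error `Var(ȳ_g)/μ_g²`,
  `Var(ȳ_g) = μΣ(1/s_i)/n² + αμ²/n`, against a standard normal. No
  dispersion shrinkage, no independent filtering — the contract is a
  plain Wald test plus BH. Features zero in both groups return
  log2FC = 0, p = 1; a group that is all-zero (but not both) receives a
  half-count continuity correction on its mean so the fold change stays
  finite. Empirical type-I error at the design size (dispersion 0.1,
  n = 18/18) measures ≈ 0.05–0.065 at α = 0.05 in the suite's
  simulations.

## Spike-in calibration (`eddyomics.ercc`)

Per sample, the correction factor is the forced-origin least-squares
slope of observed spike counts on spiked molecules,
`f = Σ(m·c)/Σ(m²)` (counts per molecule), so `molecules = counts/f`.
Two conventions were genuinely open and are exposed as flags with these
defaults:

* **Regression orientation**: counts on molecules, making f the sample's
  physical capture efficiency (the alternative, molecules on counts,
  merely inverts the factor).
* **Undetected standards** (count 0) are *included* in the fit — a zero
  observation is informative in a through-origin regression; a
  detected-only variant is behind `detected_only=True`.

The detection limit is the smallest spiked molar amount observed in that
sample. Per-ml values are `count / f / volume_ml`. Entries whose molecule
estimate falls below the detection limit are **flagged, not zeroed**:
downstream stages exclude them by default (`exclude_below_detection=True`
in taxon summation and within-taxon normalization) but the values remain
available, keeping the pipeline lossless.

## Depth-profile enrichment (`eddyomics.profiles`)

Relative abundances per sample, then a two-group Kruskal–Wallis test on
one feature inside a DCM-relative depth window. The default window is
*at or above the DCM, inclusive* (depth ≤ DCM), which with the 15-depth
grid gives 8 samples per eddy; exclusive or arbitrary windows are
available via `WindowSpec("custom", lo, hi)`. Direction is the sign of
the median difference, consistent with the rank test.

## KO trait screen (`eddyomics.traits`)

Correlations are computed across the *pooled* depth samples of both
eddies — pooling is what makes eddy-differential KOs track
eddy-differential ecotypes. The ecotype vector is the per-sample mean RPB
over the ecotype's reference sequences. The difference/total ratio
`D = (C − A)/(C + A)` uses the same at-or-above-DCM window for both
eddies. Pass criteria (defaults): r > 0.5, correlation p < 0.01,
D > 0.5. A log2 ratio with a unit pseudocount is reported alongside D but
does not enter the pass decision. No multiple-testing correction is
applied on the correlation screen; this mirrors the screening convention
the thresholds come from and is a documented caveat — the acceptance
surface is label recovery, not FDR control, at this stage. Reports are
sorted by total windowed RPB, with `top(k=20)` for the headline table.

## Taxon differential representation (`eddyomics.taxa`)

Per-ml transcript values are summed to species/genus per sample
(below-detection entries excluded by default), fold change is the ratio
of group means (anticyclone over cyclone), significance from
Kruskal–Wallis with BH over all taxa having at least one nonzero sum.
Flags use **strict** inequalities (FC exactly 3 is not flagged). Fold
changes are computed on per-ml values; because all samples carry their
own filtered volume, this differs from volume-free ERCC-corrected counts
unless volumes are equal — the per-ml route is the fixed default.
Cyclone mean 0 with positive anticyclone mean yields FC = +∞ (reported);
both-zero taxa are dropped before testing so they cannot dilute the BH
correction.

## Within-taxon differential expression (`eddyomics.expression`)

Each transcript is first normalized to its taxon's total per-sample
expression, isolating regulation from cell abundance. The NB Wald test
needs counts, so fractions are scaled by 1e6 and rounded to
pseudo-counts with unit size factors (normalization is already in the
fractions); the scale only sets the quantization floor (1e-6 of a taxon's
expression). The raw per-ml route (cell-abundance-confounded) is kept
behind `use_fractions=False`. BH runs once across all transcripts of all
tested taxa. Sides need q < 0.05 **and** |log2FC| > 2, strictly.

Category summaries drop transcripts whose eggNOG annotation has
significant members on both sides (ambiguous annotations), then group by
COG letter (multi-letter annotations contribute to each letter) or by
pathway; pathway mode keeps only categories with more than two retained
transcripts. Pathway merges (e.g. folding related excision-repair maps
into one) are a user-supplied mapping applied before retention, not
hard-coded.

## Synthetic data generator (`eddyomics.simulate`)

The generator is the test bed: its defaults *are* the study conditions.

* **Ecotype profiles**: Gaussian-in-depth peaks with multiplicative
  lognormal noise (σ = 0.2 by default). HLI peaks 10 m above the cyclone
  DCM at 3000 RPB but only 300 RPB in the anticyclone; HLII is
  DCM-centred and anticyclone-dominant (4000 vs 1500 RPB); LLI sits 20 m
  deep and is eddy-neutral. Gaussian peaks match the unimodal depth
  maxima of real ecotype profiles and keep closed-form checks.
* **KO tables**: enriched KOs are β·(ecotype RPB)·lognormal(0, 0.5) with
  β log-uniform in [0.5, 2]; null KOs are flat baselines (log-uniform
  10–1000 RPB) with the same noise.
* **Transcriptomes**: negative-binomial counts (dispersion 0.1, a typical
  metatranscriptome overdispersion) whose means are
  per-ml-abundance × volume × per-sample capture efficiency — the
  efficiency (uniform 0.2–0.8 counts/molecule) and volume are exactly
  what spike-in calibration must undo. Planted signals: 12 taxa with
  anticyclone/cyclone FC ∈ {4, 1/4} plus 100 null taxa (6 transcripts
  each); one focal cyclone-enriched taxon carries 5 differentially
  expressed transcripts (|log2FC| = 3, alternating sign) among 200 nulls.
* **Spike-ins**: Poisson(efficiency × molecules) per standard, with a
  noise-free rounded variant for exact checks. The packaged reference is
  a synthetic 92-standard table log-spaced over six decades
  (10–10⁷ molecules) — fixture data, not measured mix concentrations.
* **Determinism**: one global seed; each stage draws from a substream
  keyed by (seed, stage name), so rerunning a stage alone reproduces it.

What the generator does **not** emulate: diel periodicity in expression,
compositional coupling between taxa, read-level noise (mapping,
multi-mapping, length bias), GC/length-dependent spike capture, and
front-station samples with intermediate properties. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the declared noise model, not performance on real sequencing data.

## Problem sizes and numerical choices

Simulation-based checks use 1000 null features per stage for type-I
calibration, 50 seeds (test suite) or 25 seeds (acceptance script) for
label recovery, and 500 replicates for calibration error — sizes at which
the binomial noise on the measured rates is well inside the asserted
bands. Ties in BH are resolved by stable sort; KO/taxon aggregation and
all set operations preserve first-appearance order, making outputs
bit-reproducible. Degenerate inputs (constant rows, all-zero samples,
empty groups) raise diagnostics naming the offending feature/sample
rather than propagating NaNs, except where a flagged NaN record is the
documented contract (constant KO rows in the correlation screen).

## Known limitations

* The NB Wald test's method-of-moments dispersion is noisy at n = 18 and
  mildly anti-conservative (~0.06 at nominal 0.05); shrinkage estimators
  would tighten it but are deliberately out of scope.
* The correlation screen's thresholds (r, p, D) are conventions, not
  calibrated error rates; interpret pass counts accordingly.
* FC = +∞ taxa are reported but cannot be ranked by |log2FC|; they sort
  last.
* The exact Kruskal–Wallis permutation null is two-group only and limited
  to small pooled N by enumeration cost.
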