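# Methods

`pai1dms` models a deep-mutational-scanning (DMS) experiment on a
phage-displayed serpin (PAI-1) whose active conformation spontaneously
converts to an inactive latent state.  Because only active molecules form a
covalent complex with their target protease (uPA), selecting a mutant phage
library for complex formation at successive times turns the latency
transition into a sequencing-readable kinetic signal.  The package contains
the forward model (library + selection simulator), the read-level counting
stage, the two analysis stages (enrichment scoring and per-variant half-life
deconvolution), and reporting.

## The kinetic model

Loss of inhibitory activity is first-order.  A clone with effective rate
constant k (h⁻¹) has active fraction

    y(t) = (1 − c)·e^(−k t) + c,       t½ = ln 2 / k

where c ∈ [0, 1) is an asymptotic offset.  The amplitude-normalized form
above satisfies y(0) = 1, which is required when trajectories are normalized
to their 0 h value; the textbook form `y = e^(−kt) + c` (y(0) = 1 + c) is
selectable with `form="as-printed"` for fitting raw activity data.  Fits use
bounded trust-region least squares (k ∈ (0, 50] h⁻¹, c ∈ [0, 1)), 5
log-spaced multi-starts, an analytic Jacobian and a short projected
Gauss–Newton polish; ties are broken by lowest RSS then lowest k.  Fits are
flagged unconverged when the optimizer fails, k sits on a bound, or the
fitted amplitude (1 − c) is below 0.01 — in the last case the data are
essentially constant and k is unidentifiable.

The reference WT latency half-life is 2.1 h; the corresponding rate is
ln 2 / 2.1 ≈ 0.33 h⁻¹.

## Synthetic libraries (what the generator emulates)

* **Effects.** Every non-WT substitution receives a planted half-life and a
  functional flag.  Functional effects are half-normal in log half-life
  around WT (σ = 0.55, truncated to [0.5, 15] h): 15 % of substitutions are
  stabilized (t½ > 2.1 h), 55 % destabilized, 30 % nonfunctional (no
  protease inhibition at all), remainder neutral.  This places the bulk of
  functional variants within ~2-fold of WT with a long stabilized tail to
  ~13–15 h, the regime the measured library statistics (median ≈ 2.6 h,
  slowest measured variant ≈ 13 h) describe.  All fractions, σ and the
  truncation band are configurable.
* **Clones.** Substitution counts per clone are Poisson(4.2) — the printed
  library SD (±1.8) is close to Poisson's √4.2 ≈ 2.05 and no distribution is
  stated — with positions uniform without replacement and mutant residues
  uniform over the 19 alternatives.  A clone's rate constant composes
  multiplicatively over rate ratios, k_eff = k_WT·Π(k_sub/k_WT), the neutral
  log-additive choice when epistatic effects are assumed to average out; an
  additive-in-rate alternative is available.  Clones carrying any
  nonfunctional substitution never appear in selected samples.  Abundances
  are flat-Dirichlet (uniform optional).
* **Selection and sequencing.** In the default expected-fraction mode,
  selected-sample counts are multinomial draws of `depth_per_sample` reads
  with clone probabilities ∝ abundance × active fraction; input samples use
  abundance alone.  A bernoulli mode draws per-phage survival in a finite
  pool first.  Optional layers: lognormal noise on the aggregate recovery
  curve (`recovery_noise_sd`), gamma-multinomial overdispersion
  (`count_dispersion`), and a deterministic `count_model="expected"` used by
  noiseless oracle tests.  Each sampled genome is observed on every
  amplicon, so per-position totals equal the sample depth.
* **Reads.** Optionally, each clone draw is emitted as amplicon-length FASTQ
  reads (codon changes applied at minimal Hamming distance, uniform
  substitution errors, constant Phred).  The default panel is 12
  overlapping 150 bp amplicons tiling the coding sequence.

Defaults the experiment leaves unstated and we fixed once: 3 replicates and
10⁶ reads per sample.

What the generator does **not** emulate: PCR chimeras and indels,
quality-score-dependent error profiles, clone-specific display efficiency,
epistasis (effects compose exactly), and cofactor (vitronectin) binding.
Passing tests therefore demonstrate correctness of the analysis given the
stated stochastic model, not robustness to those real-data artifacts.

## Counting

Reads are compared gaplessly, codon by codon, to the reference over the full
codons of their amplicon window.  Nonsynonymous differences become variant
calls; synonymous differences support WT at their position.  Reads with more
than `max_mismatch_codons` (default 6 ≈ mean 4.2 + 1 SD) changed codons are
rejected as artifacts, as are length-mismatched reads; all rejections are
tallied in a QC report.  A read supports WT at position p whenever its codon
at p is synonymous with the reference regardless of other positions
(`wt_mode="positional"`); a strict whole-window mode exists.  Overlap
positions keep per-amplicon tallies; downstream collapses to the covering
amplicon with the highest mean depth (ties: earliest start).

## Enrichment scoring

At the selection endpoint (48 h), samples are depth-normalized with
median-of-ratios size factors (variants with any zero count excluded from
the reference set; factors rescaled to geometric mean 1; library-size
fallback with a warning when no variant is observed everywhere).  Per
replicate,

    log2fc_v = log2[(selected_norm + 0.5) / (input_norm + 0.5)]

and the functional stability score is the variant's replicate-mean log2fc
minus that of the WT identity at its position (within the covering
amplicon), making the WT score exactly 0.  Significance uses a Wald z on the
score with SE² = replicate variance/n plus a delta-method count floor
(1/count terms of both the variant's and the WT reference's normalized
counts); p-values are two-sided normal and Benjamini–Hochberg adjusted
across tested substitutions.  Substitutions depleted at 0 h (mean log2fc
below −1, i.e. >2-fold depletion without any latency incubation) are called
nonfunctional and excluded before testing.  Classification: `increased`
when score > 0, p_adj < 0.05 and base mean > 10 (strict, matching the
printed threshold); `decreased_or_equal` for the significant rest;
`not_scored` otherwise.

This stage is a deliberately self-contained analogue of the DESeq2-style
analysis: median-of-ratios normalization and a dispersion-aware Wald test,
without negative-binomial dispersion estimation or shrinkage.  Scale
invariance under per-sample rescaling holds exactly up to the pseudocount's
effect on near-zero counts (the median-of-ratios pseudo-reference itself
scales, exactly as in DESeq2).

## Massively parallel half-lives

For each substitution v, the variant trajectory is

    y_v(t) = F_lib(t) × [count_v(t) / total position counts(t)],

normalized to 1 at t = 0, with replicates normalized individually and
averaged point-wise.  F_lib is the library's **measured** fractional
activity at each time point (replicate-mean recovered fraction); using the
one-phase fit of the aggregate instead is available
(`library_curve="fitted"`) but distorts raw per-variant fits whenever the
aggregate is multi-phase.  The denominator is the total reads covering the
variant's position on its covering amplicon (WT-at-position plus all
substitutions there) — amplicons are sequenced separately, so per-amplicon
fractions are the natural choice; a run-wide mode would only rescale by a
sample constant that cancels at normalization.

Each trajectory is fitted with the one-phase model; the WT-at-position
trajectory at every position is fitted identically, and

    t½(normalized) = t½(raw) × 2.1 h / t½(position WT)

so the WT identity at every position reads exactly 2.1 h.  This positional
renormalization absorbs the average mutational background at each position
(clones carry ~4 substitutions, so both variant and WT reads decay faster
than their focal residue alone would).  QC: a substitution needs a
replicate-mean selected count ≥ 10 at 0 h and ≥ 4 finite trajectory points;
failures are flagged `ND` with a reason code (`zero_t0`, `low_t0_count`,
`too_few_points`, `fit_failed`, `fit_not_converged`, `no_wt_at_position`)
and never dropped silently.

### Known limitations of the deconvolution

* **Background variance at desk scale.**  The renormalization corrects the
  *mean* background, not its clone-to-clone variance.  With 10⁵ clones and
  200 positions each substitution is carried by ~110 clones (~35 functional),
  so per-variant background averages are noisy; the planted-vs-recovered
  Spearman correlation plateaus near 0.89 even with noiseless expected
  counts, and recovered values are compressed toward WT (regression slope
  well below 1 — the same attenuation the validation regression against
  individually measured variants shows).  Background averaging improves as
  ~1/√(clones per variant); a library of ~10⁶–10⁷ clones recovers ranks
  almost perfectly but is out of desk-scale test budgets.
* **Saturation.**  Half-lives at or beyond the 48 h window are
  systematically under-recovered (little decay is observed, and the free
  asymptote absorbs part of the signal); the test suite verifies the bias's
  direction by sign test.
* **Fast variants.**  Half-lives well below the first nonzero time point
  rest on one or two informative points and inherit their counting noise.

## Numerical and design choices

* Residue numbering is 1-based with a configurable offset (serpin mature
  numbering); amplicon coordinates are 0-based half-open on the CDS.
* All stochastic stages consume `numpy` Generator seeds; the pipeline spawns
  per-stage child seeds from one master seed, so identical configs and seeds
  reproduce byte-identical outputs.
* Degenerate inputs: constant trajectories → unconverged flag; fewer than 4
  points or values outside [−0.1, 1.5] → `InsufficientDataError` (ND at the
  pipeline level); empty FASTQ → empty dataset with a warning; single
  replicate → p ≡ 1 with a warning rather than silent significance.
* The validation regression (`compare_half_lives`) is OLS of parallel (y) on
  individually measured (x) half-lives, with the reverse direction reported
  alongside; heatmap matrices use a fixed alphabetical residue order and the
  sentinels WT > NONFUNCTIONAL > ND > MISSING.

## Scales used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely from seeded
simulations at desk scale, chosen to finish in minutes on one CPU: WT-only
recovery fits (8 time points, 1 % noise), a 10⁵-clone generator-calibration
draw, a 10⁵-clone / 100-residue run for the slow-variant (13.1 h) recovery,
a 10⁵-clone / 200-position end-to-end recovery run, a ~570-substitution
classification-oracle run, and a 50-variant saturation-bias run.
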