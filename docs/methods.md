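# Methods

`dsrt` reimplements, as a tested library, the analysis chain behind a
medium-scale drug sensitivity screen on a cancer cell-line panel:
plate-level viability scoring with quality control, time-lapse
growth-kinetics calls, growth-rate-corrected dose-response (GR50)
fitting, and expression-biomarker discovery. Every stage can be
exercised end to end on synthetic data with known ground truth; this
note records the models, the parameter choices, and their limits.

## Screen scoring

Raw luminescence on a 384-well plate is normalized per plate to the
control medians,

    v = (signal − median(BzCl)) / (median(DMSO) − median(BzCl)),

where benzethonium chloride (BzCl) wells anchor full kill and DMSO
vehicle wells the untreated level. Normalized viabilities are *not*
clipped at this point: over-unity or negative wells remain visible to
QC and are only constrained by the smoothing step, so the published
clip-before-vs-after ambiguity is resolved in favour of auditability.

Plate quality uses the standard window statistics on control means and
sample SDs: z′ = 1 − 3(σ_pos + σ_neg)/|μ_neg − μ_pos| (acceptance bar
z′ > 0.5) and SSMD β = (μ_pos − μ_neg)/√(σ_pos² + σ_neg²) (|β| ≥ 3).
The SSMD sign convention puts a strong kill control at large negative
β. Medians summarize controls for normalization; means/SDs enter z′
and SSMD because that is how those statistics are defined.

Each compound × cell-line five-point profile is made consistent with
the qualitative prior — viability non-increasing in dose and bounded
in [0, 1] — by least-absolute-deviation antitonic regression
(pool-adjacent-violators with block medians on the reversed sequence,
then clipping). At five support points this is the limiting behaviour
of a constrained quantile smoothing spline with negligible roughness
penalty; the median (τ = 0.5) quantile makes the fit an L1 projection,
which tests verify against an exhaustive dynamic-programming oracle on
the full grid of 11⁵ profiles. The fit is idempotent and leaves
already-feasible profiles untouched. A penalty-based spline variant is
a possible extension hook but is irrelevant at k = 5.

The profile score is the trapezoidal area under viability over log10
concentration. With five 10-fold doses (1 nM – 10 µM) each panel has
unit width, so the score lives in [0, 4]: 0 = kill at every dose,
4 = no effect, and the half-effect profile [1, 1, 0.5, 0, 0] scores
exactly 2. (The same three anchor values are also produced by the
"sum of viabilities" reading; the trapezoidal integral is used because
it is an area under the curve and matches all anchors.) Hits are
compounds with AUC ≤ 2 (inclusive) in at least one cell line, ranked
by minimum AUC, ties broken by the number of qualifying lines. Missing
matrix cells mean "not tested" and are ignored throughout.

## Growth kinetics

Confluence series are sampled every 3 h; window endpoints (40–72 h,
96–120 h) are located by linear interpolation.

*Growth-reducing concentration* — lowest dose whose 40–72 h confluence
gain is significantly below the vehicle's. The one-way layout is
fitted by least-square means: group means with a pooled residual
variance, dose-vs-vehicle t contrasts, one-sided for decrease, Holm
adjusted at α = 0.05. Holm was chosen over Dunnett as conservative and
distribution-table-free. With zero residual variance (noise-free
input) a contrast is significant iff the dose mean is strictly below
the vehicle mean. The call enforces dose-response coherence: the
returned dose is the lowest member of the contiguous significant run
containing the highest significant dose, so an isolated "significant"
low dose disconnected from the high-dose run is treated as the type-I
noise it almost surely is under a monotone dose effect. Without this
rule the call's familywise error rate (~α) falls entirely on spurious
low-dose calls.

*Growth-arresting concentration* — lowest dose whose median-across-
replicates 96–120 h gain is below 3 percentage points ("less than 3%"
read as percentage points of confluence, the unit of the series). The
late window makes arrest a stable state rather than a transient dip.

*Reversibility* — after drug withdrawal at 120 h, a condition is
reversible when it regains ≥ 3 points of confluence within 72 h. No
numeric criterion exists in the source analysis; the 3-point/72 h rule
mirrors the arrest criterion for symmetry.

Apoptosis summaries classify strictly: strong above 15 percentage
points over control, moderate above 5, otherwise none; cell-cycle
entries are kept when any phase rises by more than 5 points. These
operate on pre-summarized fractions only — no flow-cytometry event
processing.

## GR transform and GR50

Relative-viability IC50s conflate drug effect with the control growth
rate. The endpoint-form GR value

    GR(c) = 2^( log2(x_c/x0) / log2(x_ctrl/x0) ) − 1

is 1 for untreated growth, 0 at cytostasis, and approaches −1 as the
treated endpoint goes to zero; it is invariant to rescaling all three
measures. GR values over ≥ 4 distinct doses are fitted with the
four-parameter log-logistic sigmoid GR(c) = GRinf + (1 − GRinf)/(1 +
(c/GEC50)^h), upper asymptote fixed at 1, by bounded least squares:
GRinf ∈ [−1, 1], h ∈ [0.1, 5], GEC50 optimized on the log10 scale
within [min dose/100, max dose·100], multi-start over a log-spaced
grid with an early exit once a start reaches an essentially exact fit.
Replicates enter the loss jointly, without pre-averaging. An F-test
(α = 0.05) against the constant model guards against overfitting flat
data; when it cannot reject, the fit collapses to the mean GR and GR50
is the +∞ sentinel. GR50 solves GR(c) = 0.5 in closed form,

    GR50 = GEC50 · ((1 − GRinf)/(0.5 − GRinf) − 1)^(1/h),

finite iff GRinf < 0.5; crossings outside the tested range are
reported as sentinels rather than extrapolated.

A derivable property worth recording: at the GR50 concentration the
relative viability equals 2^(d·(log2 1.5 − 1)) after d control
doublings, which is below 0.5 whenever d > 1/(1 − log2 1.5) ≈ 2.41.
For the default assay geometry (72 h, 24 h doubling, d = 3) the
uncorrected IC50 therefore sits at or below the GR50 — the
relative-viability readout overstates potency for fast growers, which
is precisely the bias the GR correction removes. The property suite
asserts this direction on noise-free synthetic curves.

## Biomarker discovery

Preprocessing follows the published order: duplicated gene rows are
resolved by keeping the row with the highest SD across samples;
quantile normalization forces every sample onto the per-rank means of
the sorted columns, with ties receiving the mean of the reference
quantiles they span; then log10 after a 1e-5 pseudocount. The
expression filter drops genes below 10 FPKM in *every* cell line and
is decided on the FPKM scale. Single-gene analysis uses the filtered
universe; the GSEA ranking by default uses all genes (the published
pathway analysis ranks "all genes"), with a flag to apply the filter
there too.

Associations are Spearman rank correlations of processed expression
against untransformed GR50 (rank statistics make the transform
immaterial), with average ranks for ties and the asymptotic
t-approximation for two-sided p (exact enumeration is infeasible at
n = 13; tests cross-check the approximation against the exact
permutation null at n = 6 and against scipy per gene). A gene passes
singly at |ρ| ≥ 0.65 with p < 0.05; ρ < 0 marks sensitizing genes
(high expression, better response) because high GR50 means resistance.
Robust biomarkers must hold |ρ| > 0.8 — strict, as printed — with a
consistent sign in every leave-one-out fold over cell lines; the sign
requirement is an addition, since mixed-sign "consistency" is not
meaningful. Any fold with undefined ρ disqualifies the gene.

Pre-ranked GSEA uses the classic weighted Kolmogorov–Smirnov running
sum with weight exponent 1 on |score|, a gene-label permutation null
(default 1000 permutations, fixed seed, shared per set size), NES =
ES / mean(|null ES| of matching sign), and the standard signed-pool
FDR on NES. Sets are restricted to ranking genes and to a 15–500 size
window; skipped sets carry an explicit reason. Significance requires
FDR < 0.001 and |ES| > 0.5. The ES equals a brute-force running-sum
enumeration on every tested input; gseapy serves as an independent
cross-check of ES values in one test, never as the implementation.

## Synthetic data

The generators define the study conditions; they are not tuning knobs.

* **Plates** — latent 4PL viability truths drive expected signal
  between a BzCl floor (200 a.u.) and a DMSO level (10 000 a.u.), with
  multiplicative lognormal noise (default CV 0.05) because plate reads
  are positive and right-skewed. Default geometry: 384 wells, 16 DMSO
  + 16 BzCl controls, one well per concentration (replicates
  supported), five 10-fold doses from 1 nM.
* **Confluence** — logistic growth (default 1/24 doublings·h⁻¹,
  carrying capacity 95 %, start 5 %) whose rate is multiplied by a
  non-increasing per-dose factor; additive Gaussian observation noise
  (default SD 1 percentage point) truncated to [0, 100]. Reversible
  truths revert to the baseline rate after withdrawal.
* **GR assay** — control cells double every 24 h for 72 h; treated
  endpoint counts are constructed so the GR transform reproduces the
  truth curve exactly, making round-trip recovery a sharp test. Seven
  10-fold doses spanning 0.1 nM – 100 µM.
* **Expression** — lognormal FPKM background; a planted
  (gene, compound, direction, effect) draws log expression
  effect·s·z + √(1−effect²)·ε with z the standardized rank of the
  compound's GR50 across lines, so effect 1 gives full-panel |ρ| = 1.
  A configurable fraction of genes (default 10 %) sits below the FPKM
  filter floor in every line. Default desk scale: 200–2000 genes, 13
  lines.
* **Gene sets** — uniform random draws within a size range, plus an
  optional set concentrated in planted genes; duplicates are
  deduplicated with a warning.

A single global seed fans out through fixed `SeedSequence` spawn keys,
one stream per generator, so adding one generator never shifts
another's draws and identical inputs are byte-identical across runs.

The default end-to-end scenario plants 13 cell lines and 10 compounds,
6 of them hits: potent truths (EC50 3–50 nM, viability floor ≤ 0.08,
per-line EC50 jitter lognormal σ = 0.3) whose true AUC sits well below
half scale, versus inactive truths with EC50 ≥ 300 µM. GR truths share
each line's EC50, so screen AUC and GR50 order the lines identically
and cross-stage concordance is ρ = 1 in the noise-free limit.

What the generators do **not** emulate: plate spatial/edge effects,
batch effects between plates, heteroscedastic confluence noise,
correlated gene-gene expression structure, and any sequencing-level
artifact. Passing tests therefore demonstrate correctness of the
analysis chain under its stated model, not robustness to those
real-data pathologies.

## Problem sizes and numerical choices

The test suite runs the recovery experiments at desk scale, chosen as
the package's own defaults: 100-seed simulations for the kinetic and
biomarker criteria, 50 seeds for noisy GR50 stability, 1000 GSEA
permutations for the planted-set check, and a 400-gene pipeline
scenario. Degenerate inputs have defined behaviour throughout: equal
control medians, zero-variance controls, constant expression or
response rows, empty AUC tables, sets without ranking overlap, and
perfect (zero-residual) model fits all either raise a named error or
return a recorded skip reason rather than NaNs.

## Known limitations

* The reducing-call contrast family assumes a one-way layout per cell
  line × compound; plate- or batch-level random effects are out of
  scope.
* The L1 antitonic fit returns one optimum of a possibly non-unique
  set (block medians); tests compare achieved cost, not pointwise
  values, against the oracle.
* GR50 values whose crossing lies outside the tested dose range are
  sentinels; downstream concordance simply omits non-finite entries.
* The Spearman p-value is asymptotic; at n ≤ 7 it can deviate from the
  exact permutation null by up to ~0.1 in absolute terms, which is
  immaterial at the |ρ| ≥ 0.65 working threshold but worth remembering
  near p ≈ 0.05.
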