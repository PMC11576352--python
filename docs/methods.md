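# Methods

This note documents the statistical procedures implemented in `nmrprofile`,
the choices made where the design was genuinely open, what the synthetic
cohort generator does and does not emulate, and the numerical conventions
that make results reproducible. All quantitative statements here are
properties the test suite or `scripts/acceptance.py` verifies at run time;
none are external claims.

## Data model and axis conventions

A cohort is an n × p matrix of intensities on a single, strictly
descending chemical-shift grid (ppm), the orientation in which NMR spectra
are displayed. Ascending inputs are reversed on read. Spectra from
heterogeneous sources (JCAMP-DX files, Bruker processed directories, TSV
exports) are brought onto a common grid by linear interpolation; grid
points outside a spectrum's observed range are zero-filled with a logged
warning rather than extrapolated. Linear interpolation is exact for
locally linear signal and cannot overshoot, which matters for noise-free
oracle tests; higher-order schemes would buy nothing at typical digital
resolutions (≥ 1000 points over 10 ppm).

File-format specifics worth knowing:

* **JCAMP-DX** — the `(X++(Y..Y))` tabular form with AFFN or
  SQZ/DIF/DUP-compressed ordinates is supported; PAC packing and NTUPLES
  records are rejected with explicit messages (the supported dialect is the
  one vendor exporters emit for 1D processed spectra). The abscissa is
  reconstructed as `NPOINTS` evenly spaced values from `FIRSTX` to
  `LASTX`; ordinates are scaled by `YFACTOR`. In DIF mode each
  continuation line's first ordinate is a check value that is validated
  and dropped; a count mismatch against `NPOINTS` is an integrity error,
  not a warning.
* **Bruker processed data** — `1r` holds int32 values scaled by
  `2**NC_proc`, byte order per `BYTORDP`. The ppm axis descends from
  `OFFSET` across `SW_p / SF` ppm over `SI` points, realized here as
  `linspace(OFFSET, OFFSET − SW_p/SF, SI)` — i.e. the stated window is
  spanned inclusively by the SI points.
* **TSV matrix** — header `sample_id` followed by the ppm values, one row
  per sample, all floats printed with `repr` so doubles survive the round
  trip bit-exactly. `#` lines before the header are comments. UTF-8,
  `.` decimal separator.

## Preprocessing

Order is fixed: **region exclusion → normalization → scaling**.
Exclusion first means removed signal (typically residual water,
4.55–4.90 ppm, shipped as an overridable constant and applied only on
request) never contaminates dilution-factor estimates. Every applied
factor is recorded (`PreprocessResult`), and re-applying the recorded
divisors/centers/scales to the raw matrix reproduces the processed matrix
to 1e−12 — the provenance contract the pipeline's determinism rests on.

* **Total-area normalization** divides each spectrum by its intensity sum,
  rescaled to `area_target` (default 100, an arbitrary display-friendly
  constant; only ratios matter). Idempotent by construction.
* **PQN (probabilistic quotient normalization)** always pre-applies
  total-area normalization so quotients are scale-free, then divides each
  sample by the median of its variable-wise quotients against the
  element-wise median spectrum. The median quotient is robust to the
  minority of variables that genuinely differ between samples, which is
  why PQN rather than total area is the standard for urine, where
  osmolality varies several-fold. Two factor series are reported:
  `dilution_factors` (the combined divisor actually applied to the raw
  rows — this is what recovers constructed dilution series) and
  `quotient_factors` (the median-quotient step alone — invariant to
  multiplying the whole cohort by a constant). Conflating the two gives a
  quantity with neither property.
* **Scaling** is variable-wise with denominator n−1 throughout: `center`,
  `uv` (unit variance), `pareto` (divide centered values by √sd, damping
  intense peaks without promoting baseline noise to equal footing the way
  uv does). Zero-variance columns are dropped with a logged list under
  uv/pareto rather than imputed — a constant column carries no
  information and would otherwise produce infinities.

## PCA by NIPALS, outliers, and the exclude–refit–reproject loop

NIPALS extracts components sequentially: starting from the
largest-sum-of-squares column, iterate `p = Xᵀt/(tᵀt)` (normalized),
`t = Xp` until the relative score change falls below `tol` (default
1e−10, `max_iter` 500), then deflate `X ← X − tpᵀ`. Sequential
extraction is what makes the interactive workflow cheap: the model is
refit on retained samples only, and excluded samples are projected back
(`T = (x − x̄)P`) to show where they would have fallen. Power iteration
converges at the square of the ratio of adjacent singular values, so for
matrices with closely spaced spectra callers wanting oracle-grade
agreement (1e−8 against SVD) should pass a tighter `tol` and larger
`max_iter`; the equivalence tests do exactly that. Component signs follow
the largest-|loading|-positive convention so plots and regression tests
are stable.

Explained variance is per-component score sum-of-squares over the total
sum of squares of the (centered) input; with full rank the ratios sum
to 1 (deflation is norm-conserving, which is asserted as a test).

Outlier flagging uses Hotelling's T²: `T²ᵢ = Σₐ t²ᵢₐ/λₐ` with λₐ the
per-component score variance (n−1), against the F-based limit
`A(n−1)(n+1)/(n(n−A)) · F₁₋α(A, n−A)` (α default 0.05). This is the
standard chemometrics ellipse; at α→1 the limit collapses to 0 and
everything is flagged, a limiting case kept as a test.

## OPLS-DA

Class membership is coded −1/+1 (lexicographically first label → −1);
X is centered internally and y is centered with its mean stored, so the
model carries everything needed to score new samples. Each orthogonal
component removes the part of the dominant X-structure that is
uncorrelated with y: `w ∝ Xᵀy`, `t = Xw`, `p = Xᵀt/(tᵀt)`,
`w_o ∝ p − (wᵀp)w`, `t_o = Xw_o`, `p_o = Xᵀt_o/(t_oᵀt_o)`,
`X ← X − t_o p_oᵀ`. The final predictive component is PLS1 on the
filtered X; `ŷ = q·t_pred + ȳ`, classified by sign, with an exact tie
(ŷ = 0) logged and assigned to the first label. With `n_orth = 0` the
model **is** PLS1's first component — asserted to 1e−10.

Diagnostics: R²Y (fraction of y-variance fitted), R²X split into
predictive and orthogonal parts (the three fractions plus the residual
sum to 1 exactly, by the orthogonality of each deflation step), and
Q² = 1 − PRESS/SSy from stratified k-fold cross-validation (default 7
folds, chemometrics convention; the fold assignment is seeded and
deterministic). Q² ≤ R²Y always; a Q² near zero under label permutation
is the builtin sanity check against overfitting. `n_orth` is never
auto-selected — it changes the interpretation of the loadings, so it is
the user's call (default 1); the CLI can be scripted to sweep it.

Multiclass cohorts are handled one-vs-rest with argmax-ŷ assignment — a
deliberate simplification; a joint multi-response OPLS is out of scope.

The per-variable loading table ranks |p_pred| descending (rank 1 = most
class-discriminating variable), alongside the orthogonal loadings so
class-related and confounder-related spectral structure can be read
side by side.

## STOCSY and intensity ranking

STOCSY correlates one driver variable (chosen in ppm, snapped to the
nearest grid point) against all variables: Pearson correlation plus
covariance (n−1). Across samples, all resonances of the driver's molecule
are proportional to one concentration, so they correlate at r → 1; the
covariance trace retains intensity units and is the conventional
pseudo-spectrum display (colored by r²). STOCSY runs by default on
normalized-but-unscaled data so covariance keeps lineshape meaning;
nothing prevents running it on scaled data. Zero-variance columns get
correlation 0 by convention (logged); a constant driver is an error that
names the nearest usable variable. Variable ranking (median/mean/max per
column, ties broken by descending ppm) gives the relative-abundance
ordering used to orient in an unfamiliar cohort.

## Consensus (multiblock) PCA

Blocks are named, non-overlapping ppm windows, each scaled independently
and weighted by `1/√p_b` by default so a wide, intense region does not
swamp a narrow one — the dynamic-range motivation for multiblock
modelling of spectra. The CPCA-W iteration (block loadings regressed on
the super score; block scores combined through unit-norm super weights;
super-score deflation of every block) has the property that the
fixed-point super scores equal the PCA scores of the column-concatenated
weighted blocks. That equivalence is exact at convergence (the effective
concatenated loading `[w_1p_1; …; w_Bp_B]` is the PCA power-iteration
fixed point) and is used as the independent oracle in tests rather than
trusted. Reported per block: scores, loadings, explained block variance;
the super weights read directly as "which block drives this component".
Regions not assigned to any block are simply unused.

## COMPASS-style pattern matching

A template is a mean-subtracted window (≥ 5 points, non-constant) cut
from one clean spectrum. For each sample the template is compared at
every integer lag within ±`max_shift_points` using Pearson correlation —
amplitude- and offset-invariant, so the threshold (default 0.8) reads as
pattern similarity, not abundance. Unnormalized cross-correlation would
conflate the two. Lag ties resolve to the smallest |lag|, negative
first, making results deterministic. Samples at or above threshold count
as containing the metabolite; they are ranked by matched-window maximum
intensity (correlation saturates near 1 for clean matches, so it cannot
rank). The COMPASS→STOCSY iteration restricts the cohort to matched
samples, drives STOCSY at the template apex to reveal the compound's
other resonances, and re-estimates the template as the lag-aligned mean
of matched windows; on noise-free data this is a fixed point after one
step. Sub-grid alignment is deliberately not attempted; the practical
consequence is that the grid must sample the lineshape adequately (see
the simulator section).

## Box statistics and sample placement

Five-number summaries (min, Q1, median, Q3, max) per variable, by class
or whole cohort, with quantiles by linear interpolation of order
statistics (the "type 7" convention, numpy's default) — fixed so numbers
are comparable across implementations. A single-member group reports all
five numbers equal to its value. An individual sample's placement within
its group is its midrank (average rank among ties) divided by the group
size — the group maximum sits at percentile 1.0, the median of a large
group near 0.5, and ties are handled deterministically — plus an
inside-IQR flag.

## The synthetic cohort generator

The generator exists so the entire pipeline is testable with known ground
truth. Each compound is a peak list (center ppm, relative intensity) with
one Lorentzian linewidth; the Lorentzian
`L(ν; μ, w) = (w/2)² / ((ν−μ)² + (w/2)²)` has unit apex, so an on-grid
apex reads concentration × relative intensity directly. Per sample:
base concentrations are log-uniform per compound (biological
concentrations span decades; default range 0.5–2.0, overridable per
compound), designated biomarkers are multiplied by per-class factors
(multiplicative effects match the "concentration range" semantics of
class differences), one global shift offset per sample emulates
coherent pH/ionic-strength shifts (default sd 0, i.e. off), and white
Gaussian noise is added per grid point. The default grid is 10–0 ppm with
1000 points. One `numpy` generator seeded from the config drives all
randomness in a fixed draw order, so a dataset is bit-reproducible; the
seed is recorded in the output annotations.

The builtin compound library ships ten urine-plausible peak-list specs
(doublets near 1.33 and 1.47 ppm, singlets near 3.05/3.56/8.44 ppm, a
quartet near 4.11 ppm, aromatic multiplets, etc.). They are illustrative
simulation fixtures — the multiplet shapes and shifts are chosen to look
right, not literature assignments — and per-compound J-coupling physics,
baseline and phase artifacts are intentionally absent.

Two study-condition choices deserve explanation:

* **Separable cohorts.** With the default 4-fold base-concentration
  spread, a 2–3× biomarker effect is *not* linearly separable: the
  within-class spread overlaps the class shift, and no classifier could
  reach 100% held-out accuracy. The separable-cohort experiments
  (held-out accuracy, biomarker localization) therefore give the
  biomarker a tight concentration range (0.8–1.25), making the 2× class
  effect ≈ 5 within-class log-standard-deviations — the "strong, clean
  biomarker" regime those experiments are about. Other compounds keep the
  wide default, so they still contribute realistic y-orthogonal
  variation for the orthogonal component to absorb.
* **Grid resolution for pattern matching.** The default linewidth
  (0.004 ppm) is narrower than the 0.01 ppm step of the default grid;
  that is fine for PCA/OPLS-DA, which operate on whole-spectrum
  covariance, but integer-lag template matching needs several points per
  linewidth, or sub-grid jitter distorts the sampled lineshape and
  correlations drop unpredictably. The pattern-matching experiments
  therefore use an 8192-point grid (step ≈ 0.0012 ppm, three-plus points
  per half-width) with jitter sd 0.001 ppm, safely within the ±5-point
  shift tolerance. This is a sampling-adequacy requirement, not a tuning
  choice.

What passing these tests shows — and does not. Recovery results
demonstrate that the algorithms are implemented correctly and behave as
their theory predicts on data satisfying their assumptions
(Lorentzian additivity, global shift coherence, white noise). Real
spectra add peak-specific shift drift, baseline distortion, overlapping
unknown metabolites and correlated noise; performance there is an
empirical question the simulator cannot answer.

## Pipeline, configuration, reproducibility

Stages hand off through plain TSV/JSON files; each stage is also a CLI
subcommand usable alone, and CLI results are the library's results (the
subcommands call the same stage functions). Configs are TOML validated by
a strict schema — unknown keys are errors naming the key — and the
resolved configuration is written next to the outputs. Every run emits a
manifest mapping each written file to its SHA-256 hash; because all
randomness flows from the recorded seed and all writers are
deterministic, rerunning a config reproduces identical hashes, which is
asserted as a test.

## Problem sizes

The test suite and the acceptance script run on deliberately modest
sizes — cohorts of 24–120 spectra on grids of 400–8192 points, oracle
batches of 20–100 random matrices or groups — chosen so the full suite
completes in seconds while every check retains its discriminating power
(the algebraic oracles are size-independent; the recovery experiments
use the smallest cohorts at which the effects they probe are
well-resolved).

## Known limitations

* No raw FID processing (apodization, Fourier transform, phasing) — input
  is processed spectra.
* No peak alignment (icoshift-style), binning, baseline correction, or
  absolute quantification by peak integration.
* NIPALS does not handle missing values in this version.
* JEOL and JCAMP NTUPLES/PAC dialects unsupported; 2D NMR out of scope.
* One-vs-rest multiclass only; no permutation p-values, S-plots or VIP
  scores; no multiblock PLS.
* Plotting is limited to static score scatters and STOCSY
  pseudo-spectra.
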