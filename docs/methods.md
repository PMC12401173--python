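# Methods

## Membrane-potential calibration

DiSC₃(5) is a slow-response potentiometric dye: in the slow-dye regime the
population fluorescence of a stained suspension is, to good approximation,
an affine function of the membrane potential Em. Adding the K⁺ ionophore
valinomycin clamps Em to the K⁺ equilibrium potential, so each stepped
external K⁺ concentration [K⁺]ₒ pins the population at a known potential

E(K) = (RT/F) · ln([K⁺]ₒ / [K⁺]ᵢ),

with R = 8.314 J·K⁻¹·mol⁻¹, F = 96485.33 C·mol⁻¹, T defaulting to 310.15 K
(37 °C recordings) and [K⁺]ᵢ defaulting to 120 mM — the standard value
measured in bovine sperm, used here as the assumption for human sperm; both
are configuration parameters, not claims. The default protocol steps the
bath to 7.5, 12.5, 22.5 and 42.5 mM final K⁺ on top of a 5 mM-K⁺ recording
medium (step payloads are final concentrations, so no dilution arithmetic is
performed anywhere).

Estimation: the plateau fluorescence of each step is the median over the
trailing window (default 5 s) of that step's segment — robust to the
settling transient. Fluorescence is then fitted against the theoretical
potentials by ordinary least squares, F = a + b·E. "Interpolation" admits
either regression direction; fluorescence-on-potential is chosen (and is the
convention documented here) because potential is the error-free design
variable. The resting potential is the inverse map at the pre-valinomycin
median fluorescence (excluding 2 s before the addition, where mixing
artefacts live). The estimate is exactly invariant to affine rescaling of
the fluorescence axis, so instrument gain and offset are irrelevant.
Degenerate calibrations are rejected: |slope| below tolerance or r² < 0.95
(a 4-point linear calibration below that floor is visually nonlinear and
untrustworthy). A resting Em outside the calibrated range — a hyperpolarized
population can sit below the −74.1 mV most-dilute point — is permitted but
flagged `extrapolated`.

## Ca²⁺ transient descriptors

Fluo-3 population traces are anchored by three additions: progesterone (P4)
elicits the transient, ionomycin saturates the dye, and Mn²⁺ quenches it to
the Ca²⁺-independent minimum. The Mn²⁺ level (median of the trailing 1 s)
defines zero. On the zeroed trace:

* basal F_b = median of the pre-P4 segment (≥ 5 s required);
* peak F_max = maximum of the smoothed trace between P4 and ionomycin;
* **ΔP4 = (F_max − F_b)/F_b**, a dimensionless fold increment. The raw
  definition of the response magnitude is "maximal minus basal
  fluorescence", but the ~1–2.5 unitless scale the analysis works at only
  exists in normalized units; expressing the amplitude relative to the
  Mn-zeroed basal level reproduces that scale and makes the descriptor
  invariant to gain and offset. This is the module's one interpretive
  choice, stated here deliberately.
* **τ-up / τ-down** are half-amplitude crossing times (P4 addition → upward
  crossing of F_b + (F_max−F_b)/2; peak → downward crossing of the same
  level), with linear interpolation between samples. They are crossing
  times, not fitted rate constants, because the quantities are defined as
  half-times and no functional model of the transient is assumed.
  If the trace has not recovered to half-amplitude before ionomycin,
  recovery is censored: `recovered = False` and τ-down is reported missing,
  never imputed.

Smoothing before extremum/crossing detection is a centered moving median,
window 5 samples: robust to single-sample spikes and level-preserving on
plateaus. A flat response (zero amplitude) yields ΔP4 = 0 with both
half-times missing. A basal level that is not positive after zeroing makes
the fold increment undefined and is a named error.

## CASA kinematics and motility classes

Per track (≥ 5 frames): VCL = point-to-point path length / duration;
VSL = net displacement / duration; VAP = path length of the 5-point
moving-average trajectory / duration; STR = 100·VSL/VAP capped to [0, 100].
The 5-point window is the common CASA default; before averaging, the
trajectory is padded by linear extrapolation at both ends so that a uniform
straight swim has VAP = VCL exactly, and VSL ≤ VAP ≤ VCL holds for every
track up to a ≤ 1% smoothing-boundary tolerance. Kinematics are invariant
under translation and rotation, and equivariant under time rescaling.

Velocity classes use the VCL cut-offs < 10 (slow), 10–35 (medium),
> 35 µm·s⁻¹ (fast); the conventional ranges touch at the endpoints, so the
partition is made exact with half-open intervals ([10, 35) medium, ≥ 35
fast). Motility classes: progressive iff STR > 80 (strict inequality — STR
exactly 80 is non-progressive); immotile; non-progressive otherwise. Two
immotile criteria are provided because the literal rule "immotile = STR
exactly 0" would classify a jittering dead cell as motile (positional noise
gives STR > 0): the default `floor` mode also calls a track immotile when
VCL < 10 µm·s⁻¹ (the slow cut-off), while `strict` mode applies the literal
rule. Tracks shorter than the smoothing window are counted as unanalyzed in
the profile metadata, never silently dropped.

## Paired statistics

Every variable is a within-subject pair (the same semen sample split across
both separation methods), so arms are compared with the two-sided Wilcoxon
signed-rank test and described as median ± MAD, the MAD unscaled (no 1.4826
consistency factor — it is a descriptive spread, not a σ-estimate). Zero
differences are discarded before ranking (the textbook procedure; the
Pratt variant is not used), ties receive midranks. The exact p-value is
computed by a generating-function dynamic program over the distribution of
the positive-rank sum under sign exchangeability — identical to full 2ⁿ
enumeration (the test suite checks this against a literal 2ⁿ enumerator) —
and is used up to 20 non-zero differences; beyond that, a normal
approximation with tie-corrected variance Σrᵢ²/4 and 0.5 continuity
correction. The two-sided p is min(1, 2·smaller one-sided tail); with all
differences zero the test is degenerate and reported as p = 1 with a flag.
No multiple-testing adjustment is applied — p-values are per-variable, as is
conventional for this kind of descriptive comparison — and the report says
so in a footnote. Reported n varies by variable (the underlying study pools
differ per assay), so every row carries its own pair count.

Fertilization rate is 100 × (2PN+2PB zygotes) / (MII oocytes inseminated).
Triploid (3PN+2PB) and post-ICSI degenerated oocytes were inseminated and
therefore stay in the denominator; "discarded" applies to culture, not to
the accounting. Per-cycle rates are paired across methods by cycle id.

## Synthetic-data generator

The generator's defaults are the study conditions; they are not tuning
knobs.

* **Calibration traces** — fluorescence is an increasing affine function of
  Em (depolarization → higher signal, matching the upward KCl steps); the
  slope is a truth field and the estimator never assumes its sign. Plateau
  transitions settle as a single exponential with time constant 3 sampling
  intervals (the settling shape is visible in real traces but not
  parameterized anywhere; 3 samples is a deliberate, configurable choice).
  Schedules leaving < 5 samples in any plateau are rejected as
  unanalyzable. Default sampling rate 5 Hz: fluorometer acquisition rates
  are instrument-configured and not dictated by the protocol, so this is an
  explicit assumption, configurable in `TraceSpec`.
* **P4 transients** — raised-cosine rise whose half-amplitude crossing is
  exactly τ-up after the P4 addition (peak at 2·τ-up), then exponential
  recovery toward baseline with half-life exactly τ-down, then ionomycin
  and Mn²⁺ steps with the same settling model. Parameterized directly by
  half-times rather than rate constants so the crossing-time estimators
  recover truth exactly on noiseless traces (the round-trip tests rely on
  this). The normalized peak amplitude equals ΔP4 by construction. Default
  sampling 10 Hz, same caveat as above.
* **Tracks** — persistent random walks at 50 Hz for 3 s: per-class speed
  ranges (progressive 40–80, non-progressive 15–35 µm·s⁻¹) and per-step
  heading noise (0.05 rad progressive, 1.5 rad non-progressive); immotile
  tracks move only by the positional noise floor, 0.1 µm per frame —
  sub-pixel jitter typical of 10–20× imaging, which makes "immotile" a
  non-trivial classification case (jitter alone produces VCL ≈ 9 µm·s⁻¹,
  just under the floor).
* **Cohorts** — arms are log-normal shifted to the target median with the
  log-sd solved numerically so the *population* unscaled MAD matches the
  target (this respects positivity of counts and amplitudes;
  negative-median variables such as Em are the negated positive family).
  Arms are coupled by a Gaussian copula with latent correlation 0.6 — a
  moderate within-subject correlation chosen once as typical for repeated
  semen measurements; only medians and MADs are specified by the study, so
  the correlation is an explicit generator assumption. With
  `calibrate_median` the arms are rescaled multiplicatively so the
  finite-sample medians equal the targets exactly (a multiplicative
  rescaling preserves positivity and sign; the MAD scales by the same
  near-unity factor). The sperm-count
  MADs are only ever displayed graphically, never as numbers;
  25% of the median is used as their default.

What the generator does *not* emulate: optics and photobleaching,
flow-cytometry event streams, cell-to-cell heterogeneity within a
population trace, spontaneous Ca²⁺ oscillations, within-subject coupling
*across* variables (each variable's cohort is drawn independently, so e.g.
a subject's motility percentages do not sum to 100 across the three
independently generated percentage variables), and any true biology of the
DGC-vs-CA0 contrast. Passing round-trip tests therefore demonstrates that
the estimators are correct and well-conditioned at realistic noise — not
that the biological findings would replicate on new samples.

## Pipeline and problem sizes

`run_study` draws all 18 cohorts at their reported pair counts (9–72), then
*re-measures* every membrane potential (66 calibration traces at 2%-of-span
noise) and every Ca²⁺ transient (110 traces at 3%-of-amplitude noise)
through the full generate → estimate path, runs a 300-track CASA stage per
sample/method, and builds the paired report. These sizes are the study's
own; the whole run takes a few seconds and is byte-identical under a fixed
seed — the provenance manifest records the seed, a configuration hash and
per-file checksums, and deliberately excludes the output path and any
timestamps. Tables written from generated cohorts are synthetic stand-ins
for the study's per-subject supplementary data and carry `synthetic` in
their filenames.

## Known limitations

* Em is a population estimate; no per-cell potentials, no correction for
  dye partitioning kinetics.
* ΔP4's fold-increment definition is one of two defensible readings of
  "maximal minus basal" (the other being an absolute difference in
  normalized units); it is applied consistently to generation and
  estimation, so round-trips are meaningful either way.
* An exponential-fit alternative for the half-times is not provided; the
  crossing-time estimator is the definition here, and its noise bias
  (first-crossing times shift slightly early under noise, visible as a few
  percent downward bias in τ-down at 3% noise) is characterized by the
  recovery diagnostics rather than corrected.
* Whether the original statistics software computed exact or asymptotic
  signed-rank p-values is unknowable from the outside; both modes are
  implemented, labelled in every report row, and validated against
  enumeration and the large-sample formula respectively.
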