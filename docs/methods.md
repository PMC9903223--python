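# Methods

This note records the models, defaults and numerical choices behind
`duokin`, and what the synthetic validation does and does not establish.

## Data model and conventions

Time is stored in seconds post injection; rate constants are per minute and
K1 in mL·cm⁻³·min⁻¹ (conversion is centralised in the forward model).
Activities are kBq/mL and are decay-corrected to the injection time before
any modelling (carbon-11 half-life 20.364 min). Frames are half-open
intervals and frame values are time-averages of the underlying
concentration, not midpoint samples; blood and HPLC samples are
instantaneous. The reference dynamic protocol is 21 frames over 90 min
(3×5 s, 3×10 s, 4×60 s, 2×150 s, 2×300 s, 7×600 s).

## Metabolite fractions and input functions

Radio-HPLC chromatograms are integrated trapezoidally inside fixed
retention-time windows (met1 1.5–3.5 min, met2 3.5–7 min, met3 7–8 min,
parent > 8 min — the parent elutes last, after all three metabolite
groups); each fraction is the window area over the total area of all
windows, so fractions sum to one by construction. Baseline subtraction,
when needed, is a straight line through the trace endpoints.

The parent fraction over time follows a Hill function
pf(t) = 1 − (1 − b)·tʰ/(tʰ + cʰ) with pf(0) = 1, monotone decay and late
plateau b. Species presets are solved in closed form with h = 2:

* human — b = 0.30, c solved so that pf(90 min) = 0.473 exactly
  (c ≈ 51.57 min): slow metabolism, fractions still drifting at scan end;
* mouse — b and c solved through pf(10 min) = 0.479 and
  pf(45 min) = 0.237 (b ≈ 0.218, c ≈ 7.08 min): fast metabolism with a
  plateau from ~30 min.

The metabolised fraction 1 − pf is split in constant proportions
0.45/0.25/0.30 over met1/met2/met3 (simulation defaults, configurable).
The two brain-penetrant metabolites, met1 and met3, are pooled into one
metabolite input curve: pooled fraction = share·(1 − pf(t)) with the share
estimated from the measured fractions. Pooling two chemically distinct
species into one compartment is a deliberate approximation (separate
compartments would cost two more parameters); a flag routes all three
metabolites into the metabolite input instead, and metabolite 2 always
remains part of total plasma.

Input functions are built on a uniform 1-s grid to the end of the scan:
continuous (automated) blood data are used up to the first manual sample
after cross-calibration against overlapping manual samples; interpolation
is linear up to the blood peak and log-linear afterwards (the standard
choice for monotone multi-exponential washout, also used to extrapolate
the terminal slope). Parent input = total plasma · pf; metabolite input =
total plasma · pooled metabolite fraction; the blood-volume term uses the
whole-blood curve (flag available for plasma).

## Forward models

Parent kinetics are one- or two-tissue; the metabolite compartment is
always one-tissue (K1m, k2m) driven by the metabolite input; the measured
signal mixes tissue and blood as
C = (1 − V_B)(C_parent + C_met) + V_B·C_wb. Two-tissue impulse responses
use the eigenvalues of the k2+k3+k4 system; all convolutions are exact for
piecewise-linear inputs (one-pole recursive filter with the closed-form
segment integral, `expm1`-stable for small rate·step), so solution error is
set by the 1-s input grid, not by quadrature. Agreement with an
adaptive-step ODE integrator is better than 1e-6 of the curve peak for all
four model kinds (tested). Degenerate cases: k3 = 0 falls back to the
one-tissue response; a negative eigenvalue discriminant raises.

Distribution volumes: V_T or V_Tp = (K1/k2)(1 + k3/k4) for two-tissue
(k3/k4 term omitted when k3 = 0; undefined when k4 = 0 with k3 > 0),
K1p/k2p for one-tissue. Metabolite parameters never enter V_Tp.

## Estimation

Weighted nonlinear least squares on the frame-averaged prediction.
Weights are frame_duration / max(measured activity, floor) with
floor = 5% of the TAC maximum, normalised to mean one — an approximation
to count statistics in which long low-activity frames are the most precise
after decay correction. The measured TAC, not the model prediction, sits
in the denominator so the weights are fixed during optimisation and the
Gauss–Newton covariance and nested-F theory apply unchanged; uniform
weighting is available.

Bounds: V_B ∈ [0, 0.2], all K1/k ∈ [1e-4, 2] (min⁻¹) — generous
physiological ranges around the reported medians. The 5–7 parameter
surface is multimodal, so fitting restarts from one heuristic start plus
Latin-hypercube draws (rates log-uniform; default 10 starts, seeded and
bit-reproducible); best weighted RSS wins, ties broken by the smaller
parameter norm. Callers can append extra starts; the dual-run and nested
comparisons use this to seed the full model with the reduced-model
solution, which enforces RSS_full ≤ RSS_reduced in practice.

%SE of a parameter is 100·SE/|estimate| with the covariance
RSS_w/(n − p) · (JᵀJ)⁻¹ at the optimum; %SE of V_T/V_Tp follows by
first-order (delta-method) propagation through its formula. Both are
invariant under a common rescaling of TAC and inputs. The dual-run
procedure fits the full model on the whole-brain grey-matter TAC, then
fixes k4 at that estimate for every region (a bound-hugging step-1 k4 is
warned about and propagated). QC: a region is excluded when the fit did
not converge (flagged distinctly) or %SE of its distribution volume
exceeds 50%; exclusion percentages are reported half-up to one decimal.

## Model comparison

AIC = n·ln(RSS/n) + 2p on the unweighted RSS (a weighted variant is
exposed); n is the number of frames (21). Nested models are compared with
the extra-sum-of-squares F-test on the weighted RSS the fits minimise:
df (1, 14) for 2TDI vs 2TDI[k4] (critical value 4.60 at p = 0.05) and
(2, 14) for 2TDI vs 1TDI (3.74). "Percent better fit" counts strictly
lower AIC; ties are not better. COV = sample SD / mean · 100 is pooled
over all regions and subjects after QC exclusion; agreement between
dual-input V_Tp vectors is least-squares regression plus Spearman rank
correlation, pooled and per region.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with ground truth recorded per subject and region:

* plasma: Feng bolus (linear rise after a 0.4-min arrival, three decaying
  exponentials; amplitudes 300/10/5 kBq/mL with rates 4/0.25/0.008 min⁻¹),
  constant plasma-to-whole-blood ratio 1.25, per-subject log-normal
  amplitude jitter (sd 0.15); sampled at 1 Hz for the first 10 min
  (continuous) and manually at ~2/5/10/20/40/60/75/90 min;
* fractions: species Hill preset with the constant metabolite split;
* tissue: every region is generated by the full 2TDI model, so each
  fitted kind is exactly correct (2TDI), correctly nested (2TDI[k4] —
  k4 is perturbed per subject but shared across regions), or deliberately
  misspecified (single-input kinds, 1TDI). Regional bases put V_Tp at
  the reported medians (0.10–0.16) via K1p with k2p = 0.5, k4 = 0.15,
  k3/k4 = 0.3, V_B = 0.07; between-subject variability is log-normal with
  sd 0.20 (an assumption — the real between-subject structure is
  unknown). The metabolite compartment uses K1m = 0.02, k2m = 0.06 min⁻¹;
  half of the subjects carry K1m tripled, which turns late washout into
  the slight steady late rise seen in the second TAC phenotype;
* noise: zero-mean Gaussian per frame with sd = noise_scale·√(C/Δt)
  (count-statistics approximation; default scale 0.3, giving ~10% early-
  and ~2-3% late-frame noise), negatives clamped to zero and counted;
* the whole-brain curve is the volume-weighted mean of the regional
  curves with nominal VOI volumes.

Everything is reproducible from one master seed (per-subject seed
sequences; regenerated bundles are byte-identical).

What passing tests show — and what they do not: recovery, COV-direction
and calibration results demonstrate the estimator and statistics behave
correctly when the generating model family is the fitted family and the
input functions are known exactly. They do not establish performance
under real-data violations: non-compartmental tissue heterogeneity,
input-function measurement error, dispersion/delay, scanner resolution
effects, or metabolite kinetics that differ between the two pooled
species.

## Numerical and statistical caveats

* The F-test type-I calibration is run under the error model the
  statistic assumes (homoscedastic Gaussian frame noise, uniform weights,
  unclipped); the observed rate at the 5% level is ~8% — the residual
  inflation comes from the nonlinearity of the model in k4, a known
  property of extra-sum-of-squares tests in nonlinear regression.
* Under the literal count-statistics noise model the ~3 pre-bolus frames
  carry zero variance and zero residual for any parameter vector, so the
  nominal denominator df (n − p = 14) over-counts informative frames and
  the empirical F rate rises to ~10–12%. This is a property of simulated
  bolus studies scored with fixed df, documented rather than patched.
* Parameters at a bound are reported (`at_bounds`) and a bound-hugging
  whole-brain k4 propagates a warning to all regional fits.
* A zero RSS makes the least-squares AIC degenerate (−inf, warned).
* Spearman correlation is undefined for constant vectors and flagged.
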