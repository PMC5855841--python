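# Methods

## The gating model

Whole-cell Ca²⁺ current density through a population of CaV2.1 channels is
modelled as an ohmic driving force gated by a single Boltzmann activation
term,

    I(V) = G_max (V − V_rev) / (1 + exp(−(V − V_½)/k)),

a standard description of high-voltage-activated Ca²⁺ channel steady-state
I–V relationships. The model assumes a voltage-independent single-channel
conductance (ohmic pore), first-order activation with exponent 1 (a simple
Hodgkin–Huxley m¹ gate), and no Markov-state structure, mode switching,
Q10/temperature corrections or Goldman–Hodgkin–Katz rectification. Sweep
kinetics are

    I(t) = I_ss(V) · (1 − e^(−t/τ_act)) · h(t),
    h(t) = r + (1 − r) e^(−t/τ_inact),

with the pedestal `r` solved so that `h` at the 3 s reference time equals
`1 − degree/100`; the degree of inactivation is thereby defined at the end
of the 3 s test pulse, the operational definition used in the analysis,
rather than at t → ∞.

## Condition presets and where their numbers come from

Nine presets describe the experimental groups (DMSO vehicle; tunicamycin at
0.2, 0.6 and 2 µg/mL; α2δ1-free; and a second WT series with N283Q under
vehicle and tunicamycin). Group mean peak current densities and group sizes
are the experimentally reported values (e.g. vehicle −149.8 pA/pF at
n = 27, N283Q −19.5 pA/pF at n = 19). Only *shifts* of V½ and *differences*
of inactivation degree are reported experimentally, so the absolute
activation parameters are anchored as follows:

- `k = 4.5 mV` and `V_rev = +60 mV` are typical CaV2.1 values in
  2–3 mM external Ca²⁺.
- The vehicle `V_½` is solved numerically so that the maximal inward
  current falls at +15 mV, the one absolute activation observable reported
  (the stationarity relation `(V_rev − V*)(1 − m(V*)) = k` gives
  `V_½ ≈ +5.11 mV`). The tunicamycin presets shift `V_½` by −3.5 / −5.0 mV
  (0.2 / 0.6 µg/mL) and the N283Q + tunicamycin preset by −4.5 mV; N283Q
  itself leaves activation unchanged.
- Inactivation-degree differences (percentage points at +20 / 0 mV):
  tunicamycin 0.6 −14/−16; N283Q −22/−35. The control absolute degrees are
  model assumptions set to 80 % (+20 mV) and 75 % (0 mV); the differences,
  which all recovery checks target, do not depend on these anchors.
- Absolute τ_inactivation values are not reported; the presets assume
  vehicle 300 ms (+20 mV) and 400 ms (0 mV), ×1.5 under tunicamycin 0.6 and
  ×2 for N283Q, encoding the qualitative "slower inactivation" direction.
  Only the ordering of group τ means is asserted, never absolute values.
- Between-cell SD of peak density is reconstructed from the printed
  SEM·√n (vehicle 14.9·√27 ≈ 77.4 pA/pF). Remaining variability defaults:
  V½ SD 2 mV, degree SD 5 points, τ CV 0.3, chosen as plausible
  between-cell spreads for heterologous expression; distributions are
  lognormal on magnitudes (peak density, τ, capacitance — positivity) and
  normal for V½ and degree.

Presets serialize to a flat `key = value` config (units in key names) whose
float fields are written with `repr` precision, so dump → load → dump is
byte-identical.

## The synthetic recording generator

Each simulated cell draws a peak-density target (unit-mean lognormal times
the group mean), V½, degrees and τ around the preset values, and a membrane
capacitance (lognormal, mean 12 pF, CV 0.3, typical of HEK293 cells). The
cell's maximal conductance is then *calibrated* so that the noiseless
analyzed peak density over the actual 20 ms I–V protocol equals the sampled
target; the analysis pipeline therefore recovers group mean densities
without bias from the kinetic gate.

Protocols: 20 ms steps, −50…+60 mV in 5 mV increments (covering both
current maxima and the reversal potential), 20 kHz; 3 s pulses to +20 and
0 mV at 1 kHz. τ_act = 1 ms so the 20 ms peak is effectively the
steady-state current. Leak and capacitive transients are not simulated, but
the first 1 ms of every sweep is treated as a blanking window by the
analysis so imported data containing them are handled identically.

Recording noise is additive white Gaussian, defined as 5 pA per sample *at
the 20 kHz acquisition bandwidth*. Traces produced at a lower sample rate
are modelled as anti-alias filtered before decimation, as on a real rig, so
their per-sample SD scales with √(rate/20 kHz) (1.12 pA at 1 kHz). Without
this scaling, the minimum-sample peak detector applied to 3000 samples of
5 pA noise would systematically inflate the measured degree of inactivation
of small-current groups by up to ~10 percentage points — a bandwidth
artifact, not channel biophysics.

Seeding: per-cell seeds spawn deterministically from the group master seed
(`numpy.random.SeedSequence`), so identical master seeds give byte-identical
sweep tables.

What the generator does *not* emulate: series-resistance and space-clamp
errors, leak subtraction residuals, rundown over the recording session,
liquid-junction potentials, and any correlation between cell size and
expression level. Passing recovery tests therefore demonstrates that the
analysis is correct and unbiased for the modelled data-generating process,
not that it is robust to every artifact of real recordings.

## Analysis choices

- **Peak detection** returns the most negative sample after the blanking
  window (inward convention), earliest sample on ties. Densities are
  peak/capacitance (pA/pF).
- **Boltzmann-ohmic fit**: unweighted least squares on the unnormalized
  density curve (V½, k, V_rev are scale-invariant, so fits of normalized
  curves agree exactly; this is verified by test). Initialization: V_rev
  from the zero crossing beyond the peak (fallback +60), V½ from the
  half-peak voltage on the rising limb, k = 5 mV. Bounds
  k ∈ [0.5, 20] mV, V_rev ∈ [20, 90] mV, V½ ∈ [−40, 30] mV. A fit whose
  solution lands on a box bound is flagged non-converged — a bound-pinned
  estimate carries no information about the parameter — and group V½
  summaries exclude non-converged fits (with the exclusion count reported).
- **Degree of inactivation**: 100·(1 − I_end/I_peak), I_end averaged over
  the final 50 ms for noise suppression, clipped to [0, 100]. Peaks within
  3× the estimated noise SD (robust estimator from successive differences)
  raise an unreliable-measurement error rather than returning a number.
- **τ fit**: single exponential *with* a constant pedestal,
  A·e^(−(t−t_peak)/τ) + C, fitted from the sample of peak current to pulse
  end. The pedestal is required for consistency with degrees < 100 %; a
  pure exponential without offset would systematically overestimate τ for
  strongly non-inactivating conditions.
- **Statistics**: all statistics are computed from their defining formulas
  (midranks with tie corrections, exact Mann-Whitney enumeration for
  n ≤ 12 without ties, hypergeometric enumeration for Fisher's test);
  distribution functions come from `scipy.special`. Dunn's post hoc
  defaults to Bonferroni adjustment (unadjusted available); Student's t is
  the classic pooled-variance form. Cross-checks against `scipy.stats`
  live in the test suite only.

## Clinical tables

The episode table packages the nine stroke-like episodes with their
published per-episode fields plus two clearly flagged *synthetic* candidate
rows representing the two excluded events (a true ischemic stroke on MRI; a
seizure at the onset of a CNS infection), so the classification rule can be
exercised end-to-end (9 SLE + 2 exclusions from 11 candidates). Episode
ages are summarized at the episode level. The group-comparison table
contains only group means/SDs and counts; per-patient laboratory values
were never published, so patient-level comparisons run on a synthetic
43-patient roster reproducing the group structure exactly (7 SLE-positive,
32 SLE-negative, 4 early-death exclusions; categorical counts exact) with
numeric labs drawn from the published means/SDs. Consequently the
published between-group p-values are *not* reproducible and are checked
only for validity (∈ [0, 1], correct test per variable kind). The MVRD
spread (0.10) is a synthetic placeholder; no SD was published.

## Problem sizes and numerical tolerances

Recovery checks simulate at the experimental group sizes (27/16/13/13/19
cells) with default noise; Monte-Carlo summaries in the test suite average
three replicate simulations per condition to reduce the error of the check
itself. Exact-recovery tests on noiseless model curves require agreement to
10⁻⁴ (mV); optimizer-vs-grid-oracle comparisons allow 1 % RSS slack; the
null-calibration simulation uses 2000 replicates at n = 10 per group and
requires rejection rates in [0.03, 0.07] at α = 0.05.

## Known limitations

- The residual minimum-sample peak bias leaves the recovered N283Q
  inactivation-degree difference ~2 points below its encoded 35-point
  value at the study group size; this is inherent to picking a peak as the
  minimum noisy sample and is well inside the ±4-point acceptance band.
- The vehicle group-mean peak density at n = 27 has a standard error of
  ≈ 14.9 pA/pF (the reconstruction of the published SEM), i.e. a single
  simulated cohort can legitimately land anywhere within ~±10 % of
  −149.8 pA/pF.
- Sequon scanning is motif-only (N-X-S/T, X ≠ P): no NetNGlyc-style
  scoring and no structural accessibility filtering. Verifying that the
  human α1A sequence yields N283 requires the external UniProt O00555
  record and is an optional check, not part of the test suite.
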