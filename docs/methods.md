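# Model and methods

`nichesim` simulates mammalian sleep/wake and rest/activity patterns from a
physiologically based circuit: a mutually inhibitory sleep/wake switch, a
first-order sleep homeostat, a van der Pol-type circadian pacemaker (SCN), a
retinal photoreceptor pool, and the relay pathways that carry SCN output —
via the subparaventricular zone (SPZ) and dorsomedial hypothalamus (DMH) —
to the switch. The same circuit, re-parameterized per species, produces
nocturnal, diurnal, cathemeral, bimodal, and switching phenotypes.

## Equations

**Sleep/wake switch.** The sleep-promoting VLPO and wake-promoting
monoaminergic (MA) populations carry mean voltages `V_v`, `V_m` (mV) with
sigmoidal firing rates

    Q(V) = Q_max / (1 + exp(-(V - theta)/sigma)),

and first-order dynamics

    tau_v dV_v/dt = -V_v + nu_vm Q_m + D_v + xi_v(t)
    tau_m dV_m/dt = -V_m + nu_mv Q_v + D_m + xi_m(t),

with `nu_vm, nu_mv < 0` (mutual inhibition) and additive Gaussian white
noise `xi` of intensity `noise_sd` (mV s^-1/2) on the two voltage equations
only. The model is awake when `Q_m` strictly exceeds the wake threshold
(1 s^-1; ties score as sleep for determinism).

**Drives.** `D_v = nu_vh H - g_dmh_vlpo S + m_mask f(I_eff)` and
`D_m = A_m + g_dmh_lha S`, where `H` is the homeostat, `S` the relayed
circadian signal, and the last term of `D_v` is light masking. `A_m` lumps
cholinergic and other constant arousal input.

**Homeostat.** `chi dH/dt = mu Q_m - H`: H saturates toward `mu Q_m` during
wake and decays toward zero during sleep. `chi` is stored in hours and
converted centrally to seconds.

**Circadian relay.** The pacemaker output `C0(x, x_c) = (1 + x)/2` is scaled
by `scn_gain` (1 intact, 0 lesioned) and modulated at the SPZ:

    S = c_offset + nu_spz * scn_gain * C0(x, x_c),

with `nu_spz` in [-1, 1]: +1 means SPZ fires in phase with the SCN
(diurnal), -1 out of phase (nocturnal), 0 cathemeral. The DMH forwards S
both to the VLPO (inhibition when S is high, hence `-g_dmh_vlpo S` with
`g_dmh_vlpo > 0` wake-promoting) and, via orexinergic LHA neurons, to the
MA; `g_dmh_lha > 0` makes the two relays cooperative, `< 0` competitive.

**Pacemaker.** With time in hours,

    dx/dt   = (pi/12) [x_c + gamma (x/3 + 4x^3/3 - 256 x^7/105) + B + N]
    dx_c/dt = (pi/12) [q B x_c - x ((24/(f tau_c))^2 + k B)],

gamma = 0.13, q = 1/3, k = 0.55, f = 0.99669 (so the unforced limit-cycle
period equals `tau_c` to well under 1%; verified numerically for
tau_c in {23.0, 24.2, 25.2} h).

**Photoreception and drives.** Ready retinal photoreceptors are activated at

    alpha(I) = alpha_0 (I/I_0)^p * I/(I + I_1),

(alpha_0 = 0.1 min^-1, I_0 = 9500 lux, p = 0.5, I_1 = 100 lux) and recover
at beta = 0.007 min^-1; the activated fraction obeys
`dn/dt = alpha (1-n) - beta n`. The photic drive is
`B = G alpha(I_eff) (1-n) (1 - b x)(1 - b x_c)` with b = 0.4; the
`(1 - b x)(1 - b x_c)` factor expresses the phase-dependent sensitivity of
the SCN to light. `I_eff = I` when awake and `eye_closure_factor * I` when
asleep (default 0: full gating by eye closure). The non-photic drive is
`N = rho_np s (1 - tanh 10x)` with `s = 1/3` awake and `-2/3` asleep; at
the default rho_np = 0.032 it shifts the DD free-run by well under 0.5 h.

**Masking.** `m_mask f(I_eff)` acts directly on the VLPO: `m_mask > 0` is
excitatory (sleep-promoting, negative masking), `m_mask < 0` inhibitory
(wake-promoting, positive masking). Two transductions of `f` are
implemented: the default reuses the retinal pathway,
`f = alpha(I_eff)(1-n)/alpha_0`, giving masking the photoreceptor's
adaptation kinetics; a `linear` mode uses `f = I_eff / I_mask_ref`. The
degu preset uses the linear mode together with `eye_closure_factor = 0.5`
(closed lids still transmitting substantial light): with full gating, a
sleep-promoting masking drive switches itself off the moment sleep begins
and cannot stabilize light-phase sleep — the partially gated linear pathway
lets inverted (negative) masking actually suppress light-phase activity.

## Integration

Euler–Maruyama with fixed step `dt` (default 1 s, resolving the 10-s
voltage time constants with ten steps; a dt-halving test bounds the induced
change in total sleep fraction below 0.5 percentage points). Noise enters
as `noise_sd * sqrt(dt) * z` on the two voltages, with `z` drawn from a
per-run seeded NumPy PCG64 stream, so identical inputs give bit-identical
trajectories. The arousal flag is recomputed from the current state at the
start of each step and gates light and the non-photic drive within that
step. `n` is clamped to [0, 1] after each step (Euler can overshoot by
O(dt·beta)). Non-finite state aborts with the step and variable named.

Protocols compile to piecewise-constant segments (lux, nu_spz, m_mask,
scn_gain); epoch overrides therefore switch instantaneously at day
boundaries and the base configuration is restored exactly afterwards. A
burn-in (default 14 days, discarded) precedes recording and uses the
configuration of protocol day 1. Experiment drivers initialize the
pacemaker near its expected entrained phase (x peaking mid-light) so the
burn-in completes entrainment rather than spending weeks phase-shifting;
under constant conditions the initial phase is immaterial.

## Outputs and analysis

`Q_m` is the arousal/activity proxy. Activity traces are 10-min windowed
means (sliding or non-overlapping). Rasters fold the record at 24 h and are
double-plotted. Spectra are Hann-windowed DFT amplitudes of the
mean-removed series mapped to a period axis and area-normalized to 1 over
the analysis band (default 2–30 h). The free-running period is the
least-squares slope of main-sleep-onset times against cycle index (main
onset = onset of the longest sleep bout per fold-period window, windows
advanced 0.8 periods past each onset); records without clean monophasic
structure fall back to the spectral fundamental with a warning.
Circadian-binned wake profiles fold at a stated period (25 h for the
squirrel-monkey comparison) with phase zero at the first bin exceeding 50%
wake. The modality classifier counts strict local maxima of the 60-day
averaged, 30-min smoothed daily waveform, merging peaks closer than 2 h and
requiring 5% of the waveform range in prominence. The diurnality index
(wake fraction in light minus wake fraction in dark; under DD, subjective
day defined by `x > 0`) is an artifact construct used to make phenotypes
testable — the underlying experiments describe phenotypes verbally.

## Species presets and calibration

Universal constants (sigmoid, mutual-inhibition couplings, voltage time
constants, `mu`, retinal constants, pacemaker coefficients) take the
standard values of this model family and are shared across presets.
Species-specific values — `chi`, `tau_c`, `c_offset`, the relay gains, the
masking gain, photic gain `G`, and the noise intensity — were calibrated so
each preset reproduces its target phenotype, and each carries a provenance
tag (`stated` vs `fitted`) in its YAML file:

- **rodent_generic** (chi = 2 h): polyphasic sleep (~20–50 wake bouts/day);
  the relayed circadian signal modulates the wake duty cycle across the
  day, yielding a monotone nocturnal-to-diurnal spectrum as `nu_spz` runs
  from -1 to +1 (these phenotypes persist with noise off).
- **degu** (tau_c = 23.0 h, stated): photic gain raised so a 30-lux LD
  cycle entrains the 23-h pacemaker; positive masking baseline; diurnal
  `nu_spz = +1`. Running-wheel epochs invert `nu_spz` and/or `m_mask` about
  zero, preserving magnitude (the switching experiments describe
  inversions, not refits).
- **squirrel_monkey** (tau_c = 25.2 h, stated): `chi = 14.25 h` and the
  drive offsets fitted jointly so the intact animal in 500-lux LL sleeps
  ~36% of the day in one consolidated bout free-running at ~25.0 h, while
  the lesioned configuration (scn_gain = 0, nothing else changed) sleeps
  ~59–60% in ~5.2-h ultradian cycles. The ultradian period is an emergent
  property of the homeostat: it scales with `chi`, sublinearly because
  noise-induced switching near the flip-flop knees and the photoreceptor
  adaptation of the masking drive contribute chi-independent timescales.
  The photic gain is reduced so wake-gated light exposure in LL leaves the
  observed period near the intrinsic one.
- **primate_generic** (chi = 45 h): consolidated nightly sleep;
  `|g_dmh_lha| = 1.2` with the sign selecting cooperative (unimodal
  activity, midday peak) vs competitive (bimodal, morning/evening peaks
  with a midday dip that persists in the deterministic model).
- **human_nominal**: consolidated ~8-h nightly sleep; reference preset.

Problem sizes follow the underlying experiments: 60 recorded days for the
spectrum/relay/lesion analyses, 108 days for the degu protocol, 14-day
burn-in everywhere.

## What the simulations do and do not show

All results here are properties of the model under its fitted presets, not
of animal recordings; the analysis layer can ingest external activity CSVs,
but no empirical data ship with the package. Known limitations, inherited
from the model class or the implementation: no REM/NREM distinction, no
food entrainment or thermoregulation, a single lumped SCN oscillator (no
multi-oscillator substructure, so splitting phenomena are out of reach),
no crepuscular activity peaks at the light/dark transitions (a known
model–data discrepancy in the switching experiments), and first-order
Euler–Maruyama stepping (adequate at dt = 1 s per the convergence test, but
no adaptive error control). The chi-sensitivity of the lesioned ultradian
period depends partly on the fitted noise intensity; its exponent is a
reconstruction-dependent quantity rather than a sharp model prediction.
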