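# nichesim

Physiologically based simulation of mammalian rest/activity patterns:
why the same hypothalamic circuitry makes one species nocturnal, another
diurnal, a third crepuscular — and what changes when a degu gets a running
wheel or a squirrel monkey loses its SCN.

The package is for chronobiologists and computational neuroscientists who
want a runnable, testable implementation of the sleep/wake flip-flop +
circadian pacemaker model with downstream relay modulation and light
masking, plus the protocol and analysis tooling (actograms, amplitude
spectra, bout statistics) used to compare such models with activity
recordings.

## The model in brief

A mutually inhibitory pair of neural populations — sleep-promoting VLPO
and wake-promoting monoaminergic (MA) nuclei — forms a flip-flop switch:

    tau dV_i/dt = -V_i + nu_ij Q_j + D_i,      Q(V) = Q_max / (1 + e^-(V-theta)/sigma)

The VLPO drive `D_v = nu_vh H - g_dmh_vlpo S + m_mask f(I)` combines a
sleep homeostat `chi dH/dt = mu Q_m - H`, the relayed circadian signal
`S = c + nu C` (SCN output `C = (1+x)/2` from a modified van der Pol
oscillator entrained by light through a retinal photoreceptor pool,
modulated at the SPZ by `nu in [-1, 1]`), and direct light masking. The
DMH also relays `S` to the MA through orexinergic LHA neurons with gain
`g_dmh_lha`, whose sign makes the two relay branches cooperative or
competitive. MA firing rate `Q_m` is the arousal proxy: awake when
`Q_m > 1 s^-1`, and 10-min averages of `Q_m` stand in for activity counts.

Four classic experiments ship as drivers:

| experiment | mechanism probed | outcome |
|---|---|---|
| `sweep-nu` | SPZ modulation of SCN output | continuous nocturnal-to-diurnal spectrum |
| `relay-modes` | cooperative vs. competitive DMH relays | unimodal vs. bimodal daily activity |
| `degu-switch` | wheel-induced inversions of circadian signal and/or masking | temporal-niche switching under LD and DD |
| `scn-lesion` | SCN output set to zero | polyphasic ~5-h sleep/wake cycles, more total sleep |

See `docs/methods.md` for the full equations, parameter meanings, species
presets, and calibration rationale.

## Worked example

Simulate an SCN-lesioned squirrel monkey kept in 500-lux constant light
(the lesion sets SCN output to zero; nothing else changes):

```bash
$ nichesim scn-lesion --lesioned --seed 1 --out results/scn_lesioned
[scn_lesion_lesioned] wrote 4 artifacts to results/scn_lesioned
  chi_h: 14.25
  scn_gain: 0
  total_sleep_percent: 60.18
  ultradian_peak_h: 5.18
  wake_profile_range_pp: 15.79
```

Reading the numbers: with the circadian drive removed, the model sleeps
60% of the day (the intact run reports ~36%) in short alternating bouts;
the amplitude spectrum of MA firing peaks at an ultradian period of 5.2 h —
set by the sleep homeostat's time constant (`chi_h`), not by any remaining
clock — and the wake profile folded at the circadian period is nearly flat
(range ~16 percentage points, versus 100 for the intact animal). The
output directory contains `metrics.json`, the spectrum and binned-profile
CSVs, a double-plotted actogram PNG, and a checksummed manifest.

The same from Python:

```python
from nichesim.experiments import run_scn_lesion
report = run_scn_lesion(lesioned=True, seed=1)
print(report.metrics["ultradian_peak_h"])   # 5.18
```

Other entry points: `nichesim sweep-nu`, `nichesim relay-modes`,
`nichesim degu-switch --hypothesis both|circadian_only|masking_only`,
`nichesim presets`, and `nichesim simulate --config cfg.yaml` for plain
trajectory export (CSV + JSON provenance sidecar).

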