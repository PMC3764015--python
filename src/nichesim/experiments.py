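"""Experiment drivers: one per headline simulation.

Each driver assembles a species preset and protocol, runs the
simulation, applies the analysis layer, and returns an
:class:`ExperimentReport` whose metrics mirror the quantities the
corresponding experiment reports (diurnality indices, waveform modality,
sleep totals, spectral peaks, free-running periods).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import (activity_trace, amplitude_spectrum, fold_average,
                       free_running_period, peak_period,
                       percent_wake_by_circadian_bin, raster, score_sleep_wake,
                       total_sleep_fraction)
from .integrate import IntegratorConfig, SimulationResult, run_protocol
from .params import ModelState
from .protocols import (LightSchedule, Protocol, build_degu_protocol,
                        build_lesion_protocol, load_preset)

__all__ = [
    "ExperimentReport", "entrained_pacemaker_state", "diurnality_index",
    "count_activity_peaks", "run_nu_sweep", "run_relay_modes",
    "run_degu_switch", "run_scn_lesion",
]


@dataclass
class ExperimentReport:
    """Named scalar metrics plus tables and full provenance for one run."""

    experiment: str
    metrics: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  #: name -> DataFrame
    provenance: dict = field(default_factory=dict)


def entrained_pacemaker_state(peak_hour: float = 16.0) -> ModelState:
    """Initial state with the pacemaker phased so x peaks at ``peak_hour``.

    Starting near the entrained phase lets the burn-in finish entrainment
    instead of spending weeks shifting the oscillator by hours.
    """
    th = -2.0 * math.pi * peak_hour / 24.0
    return ModelState(x=math.cos(th), x_c=-math.sin(th))


def diurnality_index(wake: np.ndarray, in_day: np.ndarray) -> float:
    """(wake fraction during 'day' - wake fraction during 'night').

    ``in_day`` marks the light phase under LD, or the subjective day
    (pacemaker output above its midpoint) under DD.  Ranges -1 (fully
    nocturnal) to +1 (fully diurnal).
    """
    return float(wake[in_day].mean() - wake[~in_day].mean())


def count_activity_peaks(profile: np.ndarray, fold_period: float = 24.0,
                         smooth_h: float = 0.5, merge_h: float = 2.0,
                         prominence_frac: float = 0.05
                         ) -> tuple[int, np.ndarray]:
    """Count daily activity peaks in a folded waveform (modality classifier).

    The waveform is circularly smoothed with a ``smooth_h``-hour moving
    average; strict local maxima closer than ``merge_h`` hours are merged
    and peaks must rise at least ``prominence_frac`` of the waveform range.
    Returns (number of peaks, peak phases in hours).
    """
    from scipy.signal import find_peaks
    prof = np.asarray(profile, dtype=float)
    n = prof.size
    bin_h = fold_period / n
    w = max(1, int(round(smooth_h / bin_h)))
    kern = np.full(w, 1.0 / w)
    sm = np.convolve(np.concatenate([prof, prof, prof]), kern, mode="same")[n:2 * n]
    rng = sm.max() - sm.min()
    if rng <= 0:
        return 0, np.array([])
    ext = np.concatenate([sm, sm, sm])
    pk, _ = find_peaks(ext, distance=max(1, int(round(merge_h / bin_h))),
                       prominence=prominence_frac * rng)
    pk = pk[(pk >= n) & (pk < 2 * n)] - n
    return len(pk), (pk + 0.5) * bin_h


def _cfg(seed: int, dt: float, burn_in: int = 14) -> IntegratorConfig:
    return IntegratorConfig(dt=dt, seed=seed, burn_in=burn_in,
                            record_stride=30.0)


# ---------------------------------------------------------------------------
# nocturnal-diurnal spectrum
# ---------------------------------------------------------------------------

def run_nu_sweep(values=(-1.0, -0.5, 0.0, 0.5, 1.0),
                 preset: str = "rodent_generic", days: int = 60,
                 seed: int = 0, dt: float = 1.0) -> ExperimentReport:
    """SPZ-modulation sweep: phenotype vs. nu_spz for an entrained rodent.

    LD 12:12 at 100 lux; masking and the DMH/LHA relay are switched off so
    circadian modulation acts in isolation.  Reports, per nu, the
    diurnality index, total wake percentage, and the averaged 10-min
    activity profile.
    """
    if any(abs(v) > 1.0 for v in values):
        raise ValueError("nu_spz values must lie in [-1, 1]")
    sp = load_preset(preset)
    schedule = LightSchedule.ld(8.0, 20.0, 100.0)
    rows, profiles = [], {}
    for nu in values:
        params = copy.deepcopy(sp.params)
        params.relay = replace(params.relay, nu_spz=float(nu), m_mask=0.0,
                               g_dmh_lha=0.0)
        proto = Protocol(f"nu_{nu:+.2f}", params, schedule, n_days=days)
        res = run_protocol(proto, _cfg(seed, dt),
                           init=entrained_pacemaker_state(16.0))
        in_light = res.lux > 0
        di = diurnality_index(res.awake, in_light)
        trace = activity_trace(res.Q_m, res.record_stride, 600.0,
                               mode="non-overlapping")
        centers, prof = fold_average(trace.values, trace.width, 24.0, 144)
        rows.append({"nu_spz": nu, "diurnality_index": di,
                     "wake_percent": 100.0 * res.awake.mean()})
        profiles[nu] = prof
    table = pd.DataFrame(rows)
    prof_table = pd.DataFrame(
        {"clock_h": centers, **{f"nu_{nu:+.2f}": profiles[nu] for nu in values}})
    metrics = {f"diurnality_nu_{nu:+.2f}": r["diurnality_index"]
               for nu, r in zip(values, rows)}
    metrics["monotone_in_nu"] = float(
        np.all(np.diff(table["diurnality_index"]) >= 0))
    return ExperimentReport(
        "nu_sweep", metrics=metrics,
        tables={"sweep": table, "activity_profiles": prof_table},
        provenance={"preset": preset, "seed": seed, "dt": dt, "days": days,
                    "schedule": schedule.label, "nu_values": list(values)})


# ---------------------------------------------------------------------------
# relay interactions
# ---------------------------------------------------------------------------

def run_relay_modes(preset: str = "primate_generic", days: int = 60,
                    seed: int = 0, dt: float = 1.0,
                    g_lha_magnitude: float | None = None) -> ExperimentReport:
    """Cooperative vs. competitive DMH/VLPO & DMH/LHA relays in a primate.

    LD 12:12 at 500 lux (lights 6-18 h), masking omitted.  The DMH/LHA
    gain is run at +|g| (cooperative: DMH inhibits VLPO and excites LHA)
    and -|g| (competitive: DMH inhibits both), and the averaged daily
    activity waveform is classified as unimodal or bimodal.  Also tabulates
    the averaged circadian drive components and homeostatic drive.
    """
    sp = load_preset(preset)
    g_mag = abs(sp.params.relay.g_dmh_lha if g_lha_magnitude is None
                else g_lha_magnitude)
    schedule = LightSchedule.ld(6.0, 18.0, 500.0)
    metrics, tables = {}, {}
    for label, sign in (("cooperative", +1.0), ("competitive", -1.0)):
        params = copy.deepcopy(sp.params)
        params.relay = replace(params.relay, g_dmh_lha=sign * g_mag, m_mask=0.0)
        proto = Protocol(f"relay_{label}", params, schedule, n_days=days)
        res = run_protocol(proto, _cfg(seed, dt),
                           init=entrained_pacemaker_state(14.0))
        centers, prof = fold_average(res.Q_m, res.record_stride, 24.0, 144)
        n_peaks, peak_hours = count_activity_peaks(prof)
        rl = params.relay
        C = rl.scn_gain * 0.5 * (1.0 + res.x)
        S = rl.c_offset + rl.nu_spz * C
        drives = pd.DataFrame({
            "clock_h": centers,
            "dmh_vlpo_wake_drive": fold_average(rl.g_dmh_vlpo * S,
                                                res.record_stride, 24.0, 144)[1],
            "dmh_lha_wake_drive": fold_average(rl.g_dmh_lha * S,
                                               res.record_stride, 24.0, 144)[1],
            "homeostatic_drive": fold_average(params.switch.nu_vh * res.H,
                                              res.record_stride, 24.0, 144)[1],
            "mean_Q_m": prof,
        })
        metrics[f"{label}_n_peaks"] = float(n_peaks)
        metrics[f"{label}_wake_percent"] = 100.0 * res.awake.mean()
        tables[f"{label}_waveforms"] = drives
    metrics["cooperative_unimodal"] = float(metrics["cooperative_n_peaks"] == 1)
    metrics["competitive_bimodal"] = float(metrics["competitive_n_peaks"] >= 2)
    return ExperimentReport(
        "relay_modes", metrics=metrics, tables=tables,
        provenance={"preset": preset, "seed": seed, "dt": dt, "days": days,
                    "g_lha_magnitude": g_mag, "schedule": schedule.label})


# ---------------------------------------------------------------------------
# temporal niche switching
# ---------------------------------------------------------------------------

DEGU_EPOCH_SPANS = ((1, 22, "wheel_ld"), (23, 67, "no_wheel_ld"),
                    (68, 88, "wheel_ld_2"), (89, 108, "wheel_dd"))


def run_degu_switch(hypothesis: str = "both", seed: int = 0,
                    dt: float = 1.0) -> ExperimentReport:
    """Degu running-wheel switching protocol (108 days) for one hypothesis.

    Reports per-epoch diurnality indices (light-based under LD; based on
    the subjective day, pacemaker output above midpoint, under DD) and the
    double-plotted activity raster.
    """
    proto = build_degu_protocol(hypothesis)
    res = run_protocol(proto, _cfg(seed, dt),
                       init=entrained_pacemaker_state(16.0))
    day = res.times / 86400.0 + 1.0
    metrics = {}
    rows = []
    for d0, d1, label in DEGU_EPOCH_SPANS:
        sel = (day >= d0) & (day < d1 + 1)
        in_day = (res.lux[sel] > 0) if d1 <= 88 else (res.x[sel] > 0)
        di = diurnality_index(res.awake[sel], in_day)
        metrics[f"diurnality_{label}"] = di
        rows.append({"epoch": label, "start_day": d0, "end_day": d1,
                     "diurnality_index": di,
                     "wake_percent": 100.0 * res.awake[sel].mean()})
    trace = activity_trace(res.Q_m, res.record_stride, 600.0, mode="sliding")
    mat = raster(trace, fold_period=24.0, double_plot=True, high_threshold=1.0)
    tables = {
        "epochs": pd.DataFrame(rows),
        "raster": pd.DataFrame(mat.astype(int)),
    }
    return ExperimentReport(
        f"degu_switch_{hypothesis}", metrics=metrics, tables=tables,
        provenance={"preset": "degu", "hypothesis": hypothesis, "seed": seed,
                    "dt": dt, "days": proto.n_days})


# ---------------------------------------------------------------------------
# SCN lesions
# ---------------------------------------------------------------------------

def run_scn_lesion(lesioned: bool, chi_scale: float = 1.0, days: int = 60,
                   seed: int = 0, dt: float = 1.0) -> ExperimentReport:
    """Squirrel monkey in constant light, intact or SCN-lesioned.

    Metrics: total sleep percentage, amplitude spectrum of Q_m over
    2-30 h, the ultradian spectral peak (2-12 h band, lesioned) or the
    circadian fundamental (20-30 h band) and onset-drift free-running
    period (intact), and the circadian-binned wake profile folded at 25 h.
    """
    proto = build_lesion_protocol(lesioned, chi_scale=chi_scale, n_days=days)
    res = run_protocol(proto, _cfg(seed, dt))
    bouts = score_sleep_wake(res.Q_m, proto.params.wake_threshold,
                             res.record_stride)
    metrics = {
        "total_sleep_percent": total_sleep_fraction(bouts),
        "scn_gain": proto.params.relay.scn_gain,
        "chi_h": proto.params.homeostat.chi,
    }
    spec = amplitude_spectrum(res.Q_m, res.record_stride, band=(2.0, 30.0))
    if lesioned:
        metrics["ultradian_peak_h"] = peak_period(spec, band=(2.0, 12.0))
    else:
        metrics["fundamental_period_h"] = peak_period(spec, band=(20.0, 30.0))
        try:
            metrics["free_running_period_h"] = free_running_period(bouts)
        except ValueError:
            pass  # record too short for onset-drift estimation
    profile = percent_wake_by_circadian_bin(bouts, period=25.0, n_bins=24)
    metrics["wake_profile_range_pp"] = float(profile.max() - profile.min())
    tables = {
        "spectrum": pd.DataFrame({"period_h": spec.periods,
                                  "amplitude": spec.amplitudes}),
        "wake_by_circadian_bin": pd.DataFrame(
            {"bin": np.arange(profile.size), "wake_percent": profile}),
        "raster": pd.DataFrame(
            raster(bouts, fold_period=24.0, double_plot=True).astype(int)),
    }
    return ExperimentReport(
        "scn_lesion" + ("_lesioned" if lesioned else "_intact"),
        metrics=metrics, tables=tables,
        provenance={"preset": "squirrel_monkey", "lesioned": lesioned,
                    "chi_scale": chi_scale, "seed": seed, "dt": dt,
                    "days": days})
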