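"""Light schedules, protocol epochs, and species parameter presets.

A :class:`LightSchedule` is a daily-repeating piecewise-constant lux
pattern; a :class:`Protocol` couples a parameter set and base schedule
with timed override epochs (running-wheel access, SCN lesion, switches
to DD).  Species presets are shipped as structured-text (YAML) files
with per-value provenance tags.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .params import ModelParams

__all__ = [
    "LightSchedule", "ProtocolEpoch", "Protocol", "SpeciesPreset",
    "load_preset", "preset_names", "build_degu_protocol",
    "build_lesion_protocol", "compile_segments",
]

SECONDS_PER_DAY = 86400.0

#: parameters that protocol epochs may override mid-run
OVERRIDABLE = ("nu_spz", "m_mask", "scn_gain", "schedule")

DEGU_HYPOTHESES = ("both", "circadian_only", "masking_only")


@dataclass(frozen=True)
class LightSchedule:
    """Daily-repeating light pattern: ordered (start_h, end_h, lux) segments.

    Clock time is hours since midnight; segments must tile [0, 24) without
    overlap.  ``I(t)`` is periodic with 24 h within an epoch.
    """

    segments: tuple[tuple[float, float, float], ...]
    label: str = ""

    def __post_init__(self):
        segs = tuple(sorted(self.segments))
        object.__setattr__(self, "segments", segs)
        edge = 0.0
        for start, end, lux in segs:
            if abs(start - edge) > 1e-9 or end <= start:
                raise ValueError(f"segments must tile [0, 24) contiguously: {segs}")
            if lux < 0:
                raise ValueError("lux must be nonnegative")
            edge = end
        if abs(edge - 24.0) > 1e-9:
            raise ValueError("segments must cover the full 24 h day")

    @classmethod
    def ld(cls, lights_on: float, lights_off: float, lux: float) -> "LightSchedule":
        """LD cycle with light between ``lights_on`` and ``lights_off`` h."""
        if not 0 <= lights_on < lights_off <= 24:
            raise ValueError("need 0 <= lights_on < lights_off <= 24")
        segs = []
        if lights_on > 0:
            segs.append((0.0, lights_on, 0.0))
        segs.append((lights_on, lights_off, lux))
        if lights_off < 24:
            segs.append((lights_off, 24.0, 0.0))
        return cls(tuple(segs), label=f"LD {lux:g} lux {lights_on:g}-{lights_off:g} h")

    @classmethod
    def dd(cls) -> "LightSchedule":
        return cls(((0.0, 24.0, 0.0),), label="DD")

    @classmethod
    def ll(cls, lux: float) -> "LightSchedule":
        return cls(((0.0, 24.0, lux),), label=f"LL {lux:g} lux")

    def lux_at(self, t_seconds: float) -> float:
        """Lux at simulation time t (seconds), repeating daily."""
        clock = (t_seconds / 3600.0) % 24.0
        for start, end, lux in self.segments:
            if start <= clock < end:
                return lux
        return self.segments[-1][2]  # clock == 24.0 edge case

    def to_dict(self) -> dict:
        return {"segments": [list(s) for s in self.segments], "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "LightSchedule":
        return cls(tuple(tuple(s) for s in d["segments"]), d.get("label", ""))


@dataclass
class ProtocolEpoch:
    """Half-open day range [start_day, end_day] (1-based, inclusive) with
    parameter overrides applied instantaneously at the boundaries."""

    start_day: int
    end_day: int
    overrides: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        if self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")
        unknown = set(self.overrides) - set(OVERRIDABLE)
        if unknown:
            raise ValueError(f"non-overridable parameters in epoch: {sorted(unknown)}")

    def contains(self, day: int) -> bool:
        return self.start_day <= day <= self.end_day


@dataclass
class Protocol:
    """A complete runnable configuration: parameters, base light schedule,
    protocol length, and ordered non-overlapping override epochs."""

    name: str
    params: ModelParams
    schedule: LightSchedule
    n_days: int
    epochs: list[ProtocolEpoch] = field(default_factory=list)

    def __post_init__(self):
        self.params.validate()
        eps = sorted(self.epochs, key=lambda e: e.start_day)
        for a, b in zip(eps, eps[1:]):
            if b.start_day <= a.end_day:
                raise ValueError(f"overlapping epochs: {a} / {b}")
        self.epochs = eps

    def config_at_day(self, day: int) -> tuple[float, float, float, LightSchedule]:
        """(nu_spz, m_mask, scn_gain, schedule) active on a protocol day.

        Base values are exactly restored on days outside every epoch.
        """
        rl = self.params.relay
        nu, mask, scn, sched = rl.nu_spz, rl.m_mask, rl.scn_gain, self.schedule
        for ep in self.epochs:
            if ep.contains(day):
                nu = ep.overrides.get("nu_spz", nu)
                mask = ep.overrides.get("m_mask", mask)
                scn = ep.overrides.get("scn_gain", scn)
                sched = ep.overrides.get("schedule", sched)
                break
        return nu, mask, scn, sched


# ---------------------------------------------------------------------------
# species presets
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPreset:
    """Named full parameter set with per-value provenance notes."""

    name: str
    params: ModelParams
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "params": self.params.to_dict(),
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesPreset":
        extra = set(d) - {"name", "params", "provenance"}
        if extra:
            raise ValueError(f"unknown preset keys: {sorted(extra)}")
        return cls(name=d["name"], params=ModelParams.from_dict(d["params"]),
                   provenance=d.get("provenance", {}))


def preset_names() -> list[str]:
    root = importlib.resources.files("nichesim") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> SpeciesPreset:
    """Load and validate a shipped species preset by name."""
    root = importlib.resources.files("nichesim") / "presets"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {preset_names()}") from None
    preset = SpeciesPreset.from_dict(yaml.safe_load(text))
    if preset.name != name:
        raise ValueError(f"preset file {name}.yaml declares name {preset.name!r}")
    return preset


# ---------------------------------------------------------------------------
# experiment protocols
# ---------------------------------------------------------------------------

def build_degu_protocol(hypothesis: str = "both") -> Protocol:
    """Degu running-wheel temporal-niche-switching protocol (108 days).

    Wheel access on days 1-22 and 68-108; LD (30 lux, clock 8-20 h) on
    days 1-88 and DD from day 89.  The wheel's hypothesized effect is a
    sign inversion, about zero, of the SPZ modulation ``nu_spz`` (circadian
    signal inversion) and/or the masking gain ``m_mask``:

    * ``"both"``          - invert nu_spz and m_mask in wheel epochs;
    * ``"circadian_only"`` - invert nu_spz only;
    * ``"masking_only"``   - invert m_mask only.
    """
    if hypothesis not in DEGU_HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; "
                         f"choose from {DEGU_HYPOTHESES}")
    preset = load_preset("degu")
    params = preset.params
    rl = params.relay
    inv: dict = {}
    if hypothesis in ("both", "circadian_only"):
        inv["nu_spz"] = -rl.nu_spz
    if hypothesis in ("both", "masking_only"):
        inv["m_mask"] = -rl.m_mask
    ld = LightSchedule.ld(8.0, 20.0, 30.0)
    dd = LightSchedule.dd()
    epochs = [
        ProtocolEpoch(1, 22, dict(inv), label="wheel, LD"),
        # days 23-67: no wheel, base (diurnal) configuration under LD
        ProtocolEpoch(68, 88, dict(inv), label="wheel, LD"),
        ProtocolEpoch(89, 108, dict(inv, schedule=dd), label="wheel, DD"),
    ]
    return Protocol(name=f"degu_switch_{hypothesis}", params=params,
                    schedule=ld, n_days=108, epochs=epochs)


def build_lesion_protocol(lesioned: bool, chi_scale: float = 1.0,
                          n_days: int = 60) -> Protocol:
    """Squirrel-monkey constant-light (LL, 500 lux) protocol.

    The lesioned condition sets SCN output to zero (``scn_gain = 0``);
    positive masking by light is retained in both conditions and no other
    parameter differs between them.  ``chi_scale`` multiplies the
    homeostatic time constant (sensitivity analyses).
    """
    if chi_scale <= 0:
        raise ValueError("chi_scale must be positive")
    preset = load_preset("squirrel_monkey")
    params = copy.deepcopy(preset.params)
    params.homeostat.chi *= chi_scale
    params.relay = replace(params.relay, scn_gain=0.0 if lesioned else 1.0)
    tag = "lesioned" if lesioned else "intact"
    return Protocol(name=f"scn_{tag}", params=params,
                    schedule=LightSchedule.ll(500.0), n_days=n_days)


# ---------------------------------------------------------------------------
# compilation to integrator segments
# ---------------------------------------------------------------------------

def compile_segments(protocol: Protocol, burn_days: int, dt: float
                     ) -> dict[str, np.ndarray]:
    """Flatten a protocol into piecewise-constant integrator segments.

    The burn-in interval [0, burn_days) replicates the configuration of
    protocol day 1; protocol day d then occupies
    [burn_days + d - 1, burn_days + d) days of simulation time.  Returns
    arrays ``end_step`` (exclusive step index of each segment's end) and
    per-segment ``lux``, ``nu_spz``, ``m_mask``, ``scn_gain``.
    """
    if burn_days != int(burn_days) or burn_days < 0:
        raise ValueError("burn_days must be a nonnegative whole number of days")
    burn_days = int(burn_days)
    total_days = burn_days + protocol.n_days
    n_steps = int(round(total_days * SECONDS_PER_DAY / dt))
    ends, lux, nu, mask, scn = [], [], [], [], []

    def emit(day_start_s: float, day_end_s: float, cfg) -> None:
        nu_d, mask_d, scn_d, sched = cfg
        for s_h, e_h, s_lux in sched.segments:
            t0 = day_start_s + s_h * 3600.0
            t1 = min(day_start_s + e_h * 3600.0, day_end_s)
            if t1 <= t0:
                continue
            end_step = min(int(round(t1 / dt)), n_steps)
            if ends and end_step <= ends[-1]:
                continue
            ends.append(end_step)
            lux.append(s_lux)
            nu.append(nu_d)
            mask.append(mask_d)
            scn.append(scn_d)

    burn_s = burn_days * SECONDS_PER_DAY
    cfg_day1 = protocol.config_at_day(1)
    for d in range(burn_days):
        t0 = d * SECONDS_PER_DAY
        emit(t0, t0 + SECONDS_PER_DAY, cfg_day1)
    for day in range(1, protocol.n_days + 1):
        t0 = burn_s + (day - 1) * SECONDS_PER_DAY
        emit(t0, t0 + SECONDS_PER_DAY, protocol.config_at_day(day))

    ends[-1] = n_steps  # guard rounding at the terminal boundary
    return {
        "end_step": np.asarray(ends, dtype=np.int64),
        "lux": np.asarray(lux, dtype=np.float64),
        "nu_spz": np.asarray(nu, dtype=np.float64),
        "m_mask": np.asarray(mask, dtype=np.float64),
        "scn_gain": np.asarray(scn, dtype=np.float64),
        "n_steps": n_steps,
    }
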