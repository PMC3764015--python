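"""Parameter and state containers for the sleep/wake--circadian model.

The model couples four subsystems:

* a mutually inhibitory sleep/wake switch (sleep-promoting VLPO vs.
  wake-promoting monoaminergic (MA) populations), described by mean
  cell-body voltages with sigmoidal voltage-to-rate conversion;
* a first-order sleep homeostat H driven by MA firing;
* a modified van der Pol circadian pacemaker (SCN) with photic and
  non-photic drives;
* a retinal photoreceptor pool converting environmental lux into the
  pacemaker light drive, gated by behavioural state (eye closure).

SCN output is relayed through the SPZ (modulation factor ``nu_spz``) and
DMH to the VLPO and, via the orexinergic LHA, to the MA.  Light also acts
directly on the VLPO (masking).

All parameters are stored in the units stated in each field's docstring
(mixed hours/seconds, as conventional for this model family) and are
converted to SI seconds once, when packed for the integrator; see
:func:`pack_params`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Callable

import numpy as np

__all__ = [
    "SleepSwitchParams",
    "HomeostatParams",
    "PacemakerParams",
    "PhoticParams",
    "RelayMaskingParams",
    "ModelParams",
    "ModelState",
    "pack_params",
    "PV_SIZE",
]

HOURS_TO_SECONDS = 3600.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SleepSwitchParams:
    """Constants of the VLPO/MA flip-flop voltage equations.

    The two populations obey first-order voltage dynamics
    ``tau_i dV_i/dt = -V_i + nu_ij Q_j + D_i`` with sigmoidal firing
    rates ``Q(V)``.  Mutual inhibition requires both cross-couplings to
    be negative.
    """

    Q_max: float = 100.0  #: maximum firing rate (s^-1)
    theta: float = 10.0  #: sigmoid midpoint voltage (mV)
    sigma: float = 3.0  #: sigmoid width (mV)
    nu_vm: float = -2.1  #: VLPO <- MA coupling (mV s)
    nu_mv: float = -1.8  #: MA <- VLPO coupling (mV s)
    nu_vh: float = 1.0  #: VLPO <- homeostat gain (mV per H-unit)
    A_m: float = 1.3  #: constant cholinergic/other drive to MA (mV)
    tau_v: float = 10.0  #: VLPO voltage decay time constant (s)
    tau_m: float = 10.0  #: MA voltage decay time constant (s)
    noise_sd: float = 0.0  #: additive white-noise intensity on each voltage (mV s^-1/2)

    def validate(self) -> None:
        _require(self.Q_max > 0, "Q_max must be positive")
        _require(self.sigma > 0, "sigma must be positive")
        _require(self.tau_v > 0 and self.tau_m > 0, "voltage time constants must be positive")
        _require(self.nu_vm < 0 and self.nu_mv < 0,
                 "nu_vm and nu_mv must be negative (mutual inhibition)")
        _require(self.noise_sd >= 0, "noise_sd must be nonnegative")


@dataclass
class HomeostatParams:
    """Sleep homeostat: ``chi dH/dt = mu * Q_m - H``.

    H saturates toward ``mu * Q_m`` during wake (high MA firing) and
    decays approximately exponentially toward zero during sleep.
    """

    chi: float = 45.0  #: homeostatic time constant (h)
    mu: float = 4.4  #: production gain (H-units per (s^-1 * s))

    def validate(self) -> None:
        _require(self.chi > 0, "chi must be positive")
        _require(self.mu > 0, "mu must be positive")


@dataclass
class VdpCoeffs:
    """Stiffness/nonlinearity constants of the modified van der Pol pacemaker."""

    gamma: float = 0.13  #: stiffness of the cubic/7th-order nonlinearity
    f: float = 0.99669  #: period correction factor in (24/(f*tau_c))^2
    q: float = 1.0 / 3.0  #: light-drive coefficient on x_c
    k: float = 0.55  #: light-drive coefficient on x


@dataclass
class PacemakerParams:
    """Modified van der Pol circadian pacemaker with non-photic drive.

    With time measured in hours the pacemaker reads::

        dx/dt   = (pi/12) [ x_c + gamma (x/3 + 4x^3/3 - 256 x^7/105) + B + N ]
        dx_c/dt = (pi/12) [ q B x_c - x ((24/(f tau_c))^2 + k B) ]

    where B is the photic drive and N the (small) non-photic drive,
    ``N = rho_np * s * (1 - tanh(10 x))`` with ``s = np_wake`` during wake
    and ``s = np_sleep`` during sleep.
    """

    tau_c: float = 24.2  #: intrinsic circadian period (h)
    vdp_coeffs: VdpCoeffs = field(default_factory=VdpCoeffs)
    rho_np: float = 0.032  #: non-photic drive strength
    np_wake: float = 1.0 / 3.0  #: state coefficient during wake
    np_sleep: float = -2.0 / 3.0  #: state coefficient during sleep

    def validate(self) -> None:
        _require(self.tau_c > 0, "tau_c must be positive")
        _require(self.vdp_coeffs.f > 0, "period correction factor must be positive")


@dataclass
class PhoticParams:
    """Retinal photoreceptor transduction and photic drive to the SCN.

    Ready receptors are activated at rate
    ``alpha(I) = alpha_0 (I/I_0)^p * I/(I + I_1)`` and recover at rate
    ``beta``; the activated fraction n obeys
    ``dn/dt = alpha (1-n) - beta n``.  The drive to the pacemaker is
    ``B = G alpha(I_eff) (1-n) (1 - b x)(1 - b x_c)``, where ``I_eff`` is
    environmental lux gated by eye closure during scored sleep.
    """

    alpha_0: float = 0.1 / 60.0  #: activation-rate scale (s^-1)
    p: float = 0.5  #: power-law exponent (dimensionless)
    I_0: float = 9500.0  #: reference irradiance (lux)
    I_1: float = 100.0  #: half-saturation irradiance of the linear roll-off (lux)
    beta: float = 0.007 / 60.0  #: ready-state recovery rate (s^-1)
    G: float = 37.0 * 60.0  #: photic drive gain (converts alpha in s^-1 to drive units)
    b: float = 0.4  #: circadian phase-modulation coefficient
    eye_closure_factor: float = 0.0  #: lux multiplier during scored sleep

    def validate(self) -> None:
        _require(self.beta > 0, "beta must be positive")
        _require(self.alpha_0 >= 0, "alpha_0 must be nonnegative")
        _require(0.0 <= self.eye_closure_factor <= 1.0,
                 "eye_closure_factor must lie in [0, 1]")


@dataclass
class RelayMaskingParams:
    """SPZ/DMH relay of SCN output and direct light masking of the VLPO.

    The relayed circadian signal is ``S = c_offset + nu_spz * C`` with
    ``C = scn_gain * C0(x, x_c)`` the (modulated) pacemaker output.
    ``nu_spz`` runs from -1 (nocturnal; SPZ fires out of phase with the
    SCN) to +1 (diurnal).  The DMH forwards S to the VLPO (inhibitory
    when S is high -> wake-promoting) and to the MA via the orexinergic
    LHA; ``g_dmh_lha > 0`` makes the two relays cooperative, ``< 0``
    competitive.  ``m_mask`` scales the direct retinal input to the
    VLPO: positive = excitatory/sleep-promoting (negative masking),
    negative = inhibitory/wake-promoting (positive masking).
    """

    nu_spz: float = 1.0  #: SPZ modulation factor, in [-1, 1]
    c_offset: float = 0.5  #: mean offset of the relayed circadian signal
    g_dmh_vlpo: float = 2.9  #: DMH/VLPO relay gain onto VLPO (mV per S-unit)
    g_dmh_lha: float = 0.0  #: DMH/LHA relay gain onto MA (mV per S-unit)
    m_mask: float = 0.0  #: masking gain of light input onto VLPO (mV)
    scn_gain: float = 1.0  #: multiplier on pacemaker output C (1 intact, 0 lesioned)
    masking_mode: str = "photoreceptor"  #: "photoreceptor" or "linear" lux transduction
    I_mask_ref: float = 100.0  #: reference lux for the linear masking mode

    def validate(self) -> None:
        _require(-1.0 <= self.nu_spz <= 1.0, "nu_spz must lie in [-1, 1]")
        _require(0.0 <= self.scn_gain <= 1.0, "scn_gain must lie in [0, 1]")
        _require(self.masking_mode in ("photoreceptor", "linear"),
                 f"unknown masking_mode {self.masking_mode!r}")
        _require(self.I_mask_ref > 0, "I_mask_ref must be positive")


def default_pacemaker_output(x: float, x_c: float) -> float:
    """Default SCN output function C0 = (1 + x)/2, nonnegative and ~[0, 1.1]."""
    return 0.5 * (1.0 + x)


@dataclass
class ModelParams:
    """Complete parameter set, grouped by subsystem."""

    switch: SleepSwitchParams = field(default_factory=SleepSwitchParams)
    homeostat: HomeostatParams = field(default_factory=HomeostatParams)
    pacemaker: PacemakerParams = field(default_factory=PacemakerParams)
    photic: PhoticParams = field(default_factory=PhoticParams)
    relay: RelayMaskingParams = field(default_factory=RelayMaskingParams)
    wake_threshold: float = 1.0  #: Q_m level separating wake from sleep (s^-1)
    #: pacemaker output hook C0(x, x_c); only the default is supported by the
    #: compiled integrator fast path
    pacemaker_output: Callable[[float, float], float] = default_pacemaker_output

    def validate(self) -> "ModelParams":
        self.switch.validate()
        self.homeostat.validate()
        self.pacemaker.validate()
        self.photic.validate()
        self.relay.validate()
        _require(self.wake_threshold > 0, "wake_threshold must be positive")
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "switch": asdict(self.switch),
            "homeostat": asdict(self.homeostat),
            "pacemaker": asdict(self.pacemaker),
            "photic": asdict(self.photic),
            "relay": asdict(self.relay),
            "wake_threshold": self.wake_threshold,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        def build(klass, payload):
            allowed = {f.name for f in fields(klass)}
            unknown = set(payload) - allowed
            if unknown:
                raise ValueError(f"unknown keys for {klass.__name__}: {sorted(unknown)}")
            return klass(**payload)

        pk = dict(d.get("pacemaker", {}))
        if "vdp_coeffs" in pk:
            pk["vdp_coeffs"] = build(VdpCoeffs, pk["vdp_coeffs"])
        mp = cls(
            switch=build(SleepSwitchParams, d.get("switch", {})),
            homeostat=build(HomeostatParams, d.get("homeostat", {})),
            pacemaker=build(PacemakerParams, pk),
            photic=build(PhoticParams, d.get("photic", {})),
            relay=build(RelayMaskingParams, d.get("relay", {})),
            wake_threshold=d.get("wake_threshold", 1.0),
        )
        extra = set(d) - {"switch", "homeostat", "pacemaker", "photic", "relay",
                          "wake_threshold"}
        if extra:
            raise ValueError(f"unknown parameter sections: {sorted(extra)}")
        return mp.validate()


@dataclass
class ModelState:
    """Instantaneous dynamical state of the full model."""

    V_v: float = -10.0  #: VLPO mean voltage (mV)
    V_m: float = 0.0  #: MA mean voltage (mV)
    H: float = 10.0  #: homeostatic sleep drive (H-units)
    x: float = 1.0  #: pacemaker state (dimensionless)
    x_c: float = 0.0  #: complementary pacemaker variable (no physiological meaning)
    n: float = 0.0  #: activated photoreceptor fraction, in [0, 1]
    t: float = 0.0  #: simulation time (s)

    def as_array(self) -> np.ndarray:
        return np.array([self.V_v, self.V_m, self.H, self.x, self.x_c, self.n],
                        dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "ModelState":
        return cls(V_v=float(y[0]), V_m=float(y[1]), H=float(y[2]),
                   x=float(y[3]), x_c=float(y[4]), n=float(y[5]), t=t)


# ---------------------------------------------------------------------------
# Packed parameter vector for the compiled integrator kernel.  Index layout is
# shared with nichesim.model._derivs; times are converted to seconds here.
# ---------------------------------------------------------------------------

(IV_QMAX, IV_THETA, IV_SIGMA, IV_NU_VM, IV_NU_MV, IV_NU_VH, IV_A_M, IV_TAU_V,
 IV_TAU_M, IV_NOISE_SD, IV_CHI_S, IV_MU, IV_OMEGA_C, IV_GAMMA, IV_KX, IV_Q,
 IV_K, IV_RHO_NP, IV_NP_WAKE, IV_NP_SLEEP, IV_ALPHA0, IV_P, IV_I0, IV_I1,
 IV_BETA, IV_G, IV_B_PHASE, IV_EYE, IV_NU_SPZ, IV_C_OFFSET, IV_G_V, IV_G_L,
 IV_M_MASK, IV_SCN_GAIN, IV_WAKE_THR, IV_MASK_MODE, IV_I_MASK_REF) = range(37)

PV_SIZE = 37


def pack_params(params: ModelParams) -> np.ndarray:
    """Flatten a validated :class:`ModelParams` into the kernel vector.

    All rates end up in s^-1 and all time constants in seconds; the
    pacemaker's hourly form is absorbed into ``omega_c = pi/(12*3600)``
    and ``kx = (24/(f*tau_c))^2``.
    """
    params.validate()
    sw, ho, pc, ph, rl = (params.switch, params.homeostat, params.pacemaker,
                          params.photic, params.relay)
    pv = np.zeros(PV_SIZE, dtype=np.float64)
    pv[IV_QMAX] = sw.Q_max
    pv[IV_THETA] = sw.theta
    pv[IV_SIGMA] = sw.sigma
    pv[IV_NU_VM] = sw.nu_vm
    pv[IV_NU_MV] = sw.nu_mv
    pv[IV_NU_VH] = sw.nu_vh
    pv[IV_A_M] = sw.A_m
    pv[IV_TAU_V] = sw.tau_v
    pv[IV_TAU_M] = sw.tau_m
    pv[IV_NOISE_SD] = sw.noise_sd
    pv[IV_CHI_S] = ho.chi * HOURS_TO_SECONDS
    pv[IV_MU] = ho.mu
    pv[IV_OMEGA_C] = math.pi / (12.0 * HOURS_TO_SECONDS)
    pv[IV_GAMMA] = pc.vdp_coeffs.gamma
    pv[IV_KX] = (24.0 / (pc.vdp_coeffs.f * pc.tau_c)) ** 2
    pv[IV_Q] = pc.vdp_coeffs.q
    pv[IV_K] = pc.vdp_coeffs.k
    pv[IV_RHO_NP] = pc.rho_np
    pv[IV_NP_WAKE] = pc.np_wake
    pv[IV_NP_SLEEP] = pc.np_sleep
    pv[IV_ALPHA0] = ph.alpha_0
    pv[IV_P] = ph.p
    pv[IV_I0] = ph.I_0
    pv[IV_I1] = ph.I_1
    pv[IV_BETA] = ph.beta
    pv[IV_G] = ph.G
    pv[IV_B_PHASE] = ph.b
    pv[IV_EYE] = ph.eye_closure_factor
    pv[IV_NU_SPZ] = rl.nu_spz
    pv[IV_C_OFFSET] = rl.c_offset
    pv[IV_G_V] = rl.g_dmh_vlpo
    pv[IV_G_L] = rl.g_dmh_lha
    pv[IV_M_MASK] = rl.m_mask
    pv[IV_SCN_GAIN] = rl.scn_gain
    pv[IV_WAKE_THR] = params.wake_threshold
    pv[IV_MASK_MODE] = 0.0 if rl.masking_mode == "photoreceptor" else 1.0
    pv[IV_I_MASK_REF] = rl.I_mask_ref
    return pv
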