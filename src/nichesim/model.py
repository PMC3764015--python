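"""Right-hand sides of the coupled sleep/wake--circadian equations.

This module is pure model mathematics: no integration, no I/O.  Each
subsystem exposes a small function operating on the dataclasses from
:mod:`nichesim.params`; :func:`full_rhs` composes them into the complete
state derivative.  The scalar numerics are ``numba``-jitted so the same
compiled kernels back both these functions and the fixed-step integrator.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import (
    ModelParams, ModelState, PacemakerParams, PhoticParams, HomeostatParams,
    RelayMaskingParams, SleepSwitchParams, HOURS_TO_SECONDS,
)

__all__ = [
    "firing_rate", "homeostat_rhs", "relay_drive", "masking_signal",
    "masking_drive", "photic_alpha", "photoreceptor_rhs",
    "circadian_light_drive", "nonphotic_drive", "pacemaker_rhs", "full_rhs",
]


# ---------------------------------------------------------------------------
# jitted scalar kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sigmoid_rate(V: float, Q_max: float, theta: float, sigma: float) -> float:
    # guard the exponential against overflow for very negative V
    z = (theta - V) / sigma
    if z > 500.0:
        return Q_max * math.exp(-z)
    return Q_max / (1.0 + math.exp(z))


@njit(cache=True)
def _alpha_rate(I: float, alpha_0: float, p: float, I_0: float, I_1: float) -> float:
    if I <= 0.0:
        return 0.0
    return alpha_0 * (I / I_0) ** p * (I / (I + I_1))


@njit(cache=True)
def _vdp_nonlin(x: float) -> float:
    return x / 3.0 + (4.0 / 3.0) * x ** 3 - (256.0 / 105.0) * x ** 7


# ---------------------------------------------------------------------------
# sleep/wake switch
# ---------------------------------------------------------------------------

def firing_rate(V: float, p: SleepSwitchParams) -> float:
    """Sigmoidal voltage-to-rate conversion Q(V), in s^-1.

    Saturates at ``Q_max``, crosses ``Q_max/2`` at ``V = theta`` and has
    slope width ``sigma``; strictly increasing for all finite V.
    """
    if not math.isfinite(V):
        raise ValueError(f"non-finite voltage: {V}")
    return _sigmoid_rate(V, p.Q_max, p.theta, p.sigma)


def homeostat_rhs(H: float, Q_m: float, p: HomeostatParams) -> float:
    """dH/dt for the sleep homeostat, in H-units per second.

    ``chi dH/dt = mu Q_m - H`` with chi converted from hours; the fixed
    point is ``H* = mu Q_m``.
    """
    if p.chi <= 0:
        raise ValueError("chi must be positive")
    return (p.mu * Q_m - H) / (p.chi * HOURS_TO_SECONDS)


# ---------------------------------------------------------------------------
# relay and masking drives
# ---------------------------------------------------------------------------

def relay_drive(state: ModelState, p: RelayMaskingParams,
                params: ModelParams | None = None) -> tuple[float, float]:
    """Circadian drives relayed through SPZ/DMH, as (to_VLPO, to_MA) in mV.

    The relayed signal is ``S = c_offset + nu_spz * scn_gain * C0(x, x_c)``.
    The DMH/VLPO branch inhibits the VLPO when S is high (wake-promoting),
    so the VLPO drive is ``-g_dmh_vlpo * S``; the DMH/LHA branch delivers
    ``g_dmh_lha * S`` to the MA (positive gain = cooperative/excitatory,
    negative = competitive/inhibitory).
    """
    c0 = (params.pacemaker_output if params is not None
          else lambda x, xc: 0.5 * (1.0 + x))
    C = p.scn_gain * c0(state.x, state.x_c)
    S = p.c_offset + p.nu_spz * C
    return -p.g_dmh_vlpo * S, p.g_dmh_lha * S


def masking_signal(I_eff: float, n: float, relay: RelayMaskingParams,
                   photic: PhoticParams | None = None) -> float:
    """Monotone light-transduction signal f(I_eff) >= 0 with f(0) = 0.

    In ``photoreceptor`` mode the signal reuses the retinal activation
    pathway, ``alpha(I_eff) * (1 - n) / alpha_0`` (dimensionless, unit
    reference ``alpha_0``); in ``linear`` mode it is plain
    ``I_eff / I_mask_ref``.
    """
    if I_eff < 0:
        raise ValueError("effective irradiance must be nonnegative")
    if relay.masking_mode == "linear":
        return I_eff / relay.I_mask_ref
    if photic is None:
        raise ValueError("photoreceptor masking mode requires PhoticParams")
    a = _alpha_rate(I_eff, photic.alpha_0, photic.p, photic.I_0, photic.I_1)
    return a * (1.0 - n) / photic.alpha_0


def masking_drive(I_eff: float, p: RelayMaskingParams,
                  photic: PhoticParams | None = None, n: float = 0.0) -> float:
    """Direct (masking) light drive onto the VLPO, ``m_mask * f(I_eff)`` in mV.

    ``m_mask > 0`` is excitatory/sleep-promoting (negative masking);
    ``m_mask < 0`` is inhibitory/wake-promoting (positive masking).
    """
    return p.m_mask * masking_signal(I_eff, n, p, photic)


# ---------------------------------------------------------------------------
# photoreception and pacemaker drives
# ---------------------------------------------------------------------------

def photic_alpha(I: float, p: PhoticParams) -> float:
    """Photoreceptor activation rate alpha(I) in s^-1.

    ``alpha = alpha_0 (I/I_0)^p * I/(I + I_1)``; zero in darkness and
    monotone increasing in lux.
    """
    if I < 0:
        raise ValueError("irradiance must be nonnegative")
    return _alpha_rate(I, p.alpha_0, p.p, p.I_0, p.I_1)


def photoreceptor_rhs(n: float, alpha: float, p: PhoticParams) -> float:
    """dn/dt for the activated photoreceptor fraction.

    ``dn/dt = alpha (1 - n) - beta n``; equilibrium at
    ``n* = alpha/(alpha + beta)`` with relaxation rate ``alpha + beta``.
    """
    if not 0.0 <= n <= 1.0:
        raise ValueError(f"photoreceptor fraction out of [0, 1]: {n}")
    return alpha * (1.0 - n) - p.beta * n


def circadian_light_drive(state: ModelState, awake: bool, I: float,
                          p: PhoticParams) -> float:
    """Photic drive B to the pacemaker (dimensionless drive units).

    Lux is gated by eye closure during scored sleep
    (``I_eff = I`` awake, ``eye_closure_factor * I`` asleep), transduced by
    the photoreceptor pool, and modulated by circadian phase through
    ``(1 - b x)(1 - b x_c)``.
    """
    I_eff = I if awake else p.eye_closure_factor * I
    a = photic_alpha(I_eff, p)
    return p.G * a * (1.0 - state.n) * (1.0 - p.b * state.x) * (1.0 - p.b * state.x_c)


def nonphotic_drive(awake: bool, state: ModelState, p: PacemakerParams) -> float:
    """Non-photic (behavioural-state) drive N to the pacemaker.

    Two-level in arousal state: ``N = rho_np * s * (1 - tanh(10 x))`` with
    ``s = np_wake`` during wake and ``s = np_sleep`` during sleep; small
    compared with the photic drive under lit protocols.
    """
    s = p.np_wake if awake else p.np_sleep
    return p.rho_np * s * (1.0 - math.tanh(10.0 * state.x))


def pacemaker_rhs(state: ModelState, B: float, N: float,
                  p: PacemakerParams) -> tuple[float, float]:
    """(dx/dt, dx_c/dt) of the modified van der Pol pacemaker, per second.

    With B = N = 0 the oscillator settles onto a stable limit cycle whose
    period matches ``tau_c`` to well under 1%.
    """
    c = p.vdp_coeffs
    omega = math.pi / (12.0 * HOURS_TO_SECONDS)
    kx = (24.0 / (c.f * p.tau_c)) ** 2
    dx = omega * (state.x_c + c.gamma * _vdp_nonlin(state.x) + B + N)
    dxc = omega * (c.q * B * state.x_c - state.x * (kx + c.k * B))
    return dx, dxc


# ---------------------------------------------------------------------------
# full composition
# ---------------------------------------------------------------------------

def full_rhs(state: ModelState, t: float, params: ModelParams,
             schedule) -> np.ndarray:
    """Complete state derivative [dV_v, dV_m, dH, dx, dx_c, dn] at time t.

    ``schedule`` must provide ``lux_at(t_seconds)``.  The VLPO drive is
    ``D_v = nu_vh H + relay + masking`` and the MA drive
    ``D_m = A_m + relay``; the wake flag is the instantaneous
    ``Q_m > wake_threshold`` and gates both light input and the
    non-photic drive.
    """
    sw, ph = params.switch, params.photic
    I = schedule.lux_at(t)
    if I is None or not math.isfinite(I):
        raise ValueError(f"light schedule undefined at t = {t} s")

    Q_v = firing_rate(state.V_v, sw)
    Q_m = firing_rate(state.V_m, sw)
    awake = Q_m > params.wake_threshold

    I_eff = I if awake else ph.eye_closure_factor * I
    alpha = photic_alpha(I_eff, ph)
    dn = photoreceptor_rhs(state.n, alpha, ph)

    B = circadian_light_drive(state, awake, I, ph)
    N = nonphotic_drive(awake, state, params.pacemaker)
    dx, dxc = pacemaker_rhs(state, B, N, params.pacemaker)

    d_relay_v, d_relay_m = relay_drive(state, params.relay, params)
    d_mask = masking_drive(I_eff, params.relay, ph, state.n)

    D_v = sw.nu_vh * state.H + d_relay_v + d_mask
    D_m = sw.A_m + d_relay_m
    dVv = (sw.nu_vm * Q_m + D_v - state.V_v) / sw.tau_v
    dVm = (sw.nu_mv * Q_v + D_m - state.V_m) / sw.tau_m
    dH = homeostat_rhs(state.H, Q_m, params.homeostat)
    return np.array([dVv, dVm, dH, dx, dxc, dn], dtype=np.float64)
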