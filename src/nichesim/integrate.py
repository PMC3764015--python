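"""Fixed-step Euler--Maruyama integration of the full model.

The deterministic right-hand side is advanced with step ``dt`` and
additive voltage noise ``noise_sd * sqrt(dt) * z`` with z drawn from a
seeded generator, so identical (params, protocol, config) reproduce
bit-identical trajectories.  The arousal flag (``Q_m > wake_threshold``)
is recomputed at the start of every step from the current state and
gates light input and the non-photic drive within that step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import params as P
from .model import _sigmoid_rate, _alpha_rate, _vdp_nonlin
from .params import ModelParams, ModelState, pack_params
from .protocols import LightSchedule, Protocol, compile_segments, SECONDS_PER_DAY

__all__ = ["IntegratorConfig", "SimulationResult", "IntegrationError",
           "integrate", "run_protocol", "step"]

STATE_NAMES = ("V_v", "V_m", "H", "x", "x_c", "n")


class IntegrationError(RuntimeError):
    pass


@dataclass
class IntegratorConfig:
    """Stepper configuration; ``record_stride`` must be a multiple of ``dt``."""

    dt: float = 1.0  #: step size (s)
    seed: int = 0  #: seed of the per-run random stream
    burn_in: int = 14  #: discarded initial duration (days)
    record_stride: float = 30.0  #: output sampling interval (s)

    def validate(self) -> "IntegratorConfig":
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ratio = self.record_stride / self.dt
        if self.record_stride < self.dt or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("record_stride must be an integer multiple of dt")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        return self


@dataclass
class SimulationResult:
    """Uniformly sampled trajectories plus full provenance.

    ``times`` is in seconds with t = 0 at the end of burn-in (protocol
    day 1 starts at 0).  ``awake[i]`` is exactly ``Q_m[i] > wake_threshold``.
    """

    times: np.ndarray
    V_v: np.ndarray
    V_m: np.ndarray
    H: np.ndarray
    x: np.ndarray
    x_c: np.ndarray
    n: np.ndarray
    Q_m: np.ndarray
    Q_v: np.ndarray
    awake: np.ndarray
    lux: np.ndarray
    params_snapshot: dict
    seed: int
    dt: float
    record_stride: float
    burn_in: int
    protocol_name: str = ""
    wake_threshold: float = 1.0
    final_state: ModelState | None = None

    @property
    def sampling_interval(self) -> float:
        return self.record_stride

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "time_s": self.times, "V_v": self.V_v, "V_m": self.V_m, "H": self.H,
            "x": self.x, "x_c": self.x_c, "n": self.n, "Q_m": self.Q_m,
            "Q_v": self.Q_v, "awake": self.awake.astype(int), "lux": self.lux,
        })

    def to_csv(self, path) -> None:
        """Write the trajectory as CSV with a JSON provenance sidecar."""
        self.to_dataframe().to_csv(path, index=False)
        sidecar = str(path) + ".provenance.json"
        with open(sidecar, "w") as fh:
            json.dump({"params": self.params_snapshot, "seed": self.seed,
                       "dt": self.dt, "record_stride": self.record_stride,
                       "burn_in_days": self.burn_in,
                       "protocol": self.protocol_name,
                       "wake_threshold": self.wake_threshold}, fh, indent=2)


@njit(cache=True)
def _kernel(y, pv, dt, n_steps, burn_steps, stride,
            seg_end, seg_lux, seg_nu, seg_mask, seg_scn,
            noise_v, noise_m, has_noise,
            rec_state, rec_qm, rec_qv, rec_lux):
    """Euler--Maruyama loop; records every `stride` steps after burn-in.

    Returns (status, step, var_index); status 0 = success, 1 = non-finite
    state component var_index produced at step."""
    sqrt_dt = math.sqrt(dt)
    sd = pv[P.IV_NOISE_SD]
    seg = 0
    k = 0
    for istep in range(n_steps):
        while istep >= seg_end[seg]:
            seg += 1
        lux = seg_lux[seg]
        nu_spz = seg_nu[seg]
        m_mask = seg_mask[seg]
        scn_gain = seg_scn[seg]

        V_v, V_m, H, x, x_c, n = y[0], y[1], y[2], y[3], y[4], y[5]
        Q_v = _sigmoid_rate(V_v, pv[P.IV_QMAX], pv[P.IV_THETA], pv[P.IV_SIGMA])
        Q_m = _sigmoid_rate(V_m, pv[P.IV_QMAX], pv[P.IV_THETA], pv[P.IV_SIGMA])
        awake = Q_m > pv[P.IV_WAKE_THR]

        if istep >= burn_steps and (istep - burn_steps) % stride == 0:
            rec_state[0, k] = V_v
            rec_state[1, k] = V_m
            rec_state[2, k] = H
            rec_state[3, k] = x
            rec_state[4, k] = x_c
            rec_state[5, k] = n
            rec_qm[k] = Q_m
            rec_qv[k] = Q_v
            rec_lux[k] = lux
            k += 1

        # photoreception, gated by eye closure during sleep
        I_eff = lux if awake else pv[P.IV_EYE] * lux
        alpha = _alpha_rate(I_eff, pv[P.IV_ALPHA0], pv[P.IV_P],
                            pv[P.IV_I0], pv[P.IV_I1])
        dn = alpha * (1.0 - n) - pv[P.IV_BETA] * n

        # pacemaker drives
        B = (pv[P.IV_G] * alpha * (1.0 - n)
             * (1.0 - pv[P.IV_B_PHASE] * x) * (1.0 - pv[P.IV_B_PHASE] * x_c))
        s_np = pv[P.IV_NP_WAKE] if awake else pv[P.IV_NP_SLEEP]
        N = pv[P.IV_RHO_NP] * s_np * (1.0 - math.tanh(10.0 * x))
        dx = pv[P.IV_OMEGA_C] * (x_c + pv[P.IV_GAMMA] * _vdp_nonlin(x) + B + N)
        dxc = pv[P.IV_OMEGA_C] * (pv[P.IV_Q] * B * x_c
                                  - x * (pv[P.IV_KX] + pv[P.IV_K] * B))

        # relayed circadian signal and masking
        C = scn_gain * 0.5 * (1.0 + x)
        S = pv[P.IV_C_OFFSET] + nu_spz * C
        if pv[P.IV_MASK_MODE] < 0.5:
            f_mask = alpha * (1.0 - n) / pv[P.IV_ALPHA0]
        else:
            f_mask = I_eff / pv[P.IV_I_MASK_REF]

        D_v = pv[P.IV_NU_VH] * H - pv[P.IV_G_V] * S + m_mask * f_mask
        D_m = pv[P.IV_A_M] + pv[P.IV_G_L] * S
        dVv = (pv[P.IV_NU_VM] * Q_m + D_v - V_v) / pv[P.IV_TAU_V]
        dVm = (pv[P.IV_NU_MV] * Q_v + D_m - V_m) / pv[P.IV_TAU_M]
        dH = (pv[P.IV_MU] * Q_m - H) / pv[P.IV_CHI_S]

        V_v += dVv * dt
        V_m += dVm * dt
        if has_noise:
            V_v += sd * sqrt_dt * noise_v[istep]
            V_m += sd * sqrt_dt * noise_m[istep]
        H += dH * dt
        x += dx * dt
        x_c += dxc * dt
        n += dn * dt
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0

        y[0], y[1], y[2], y[3], y[4], y[5] = V_v, V_m, H, x, x_c, n
        for j in range(6):
            if not math.isfinite(y[j]):
                return 1, istep, j
    return 0, n_steps, -1


def run_protocol(protocol: Protocol, cfg: IntegratorConfig,
                 init: ModelState | None = None) -> SimulationResult:
    """Simulate a full protocol (burn-in + all protocol days)."""
    cfg.validate()
    params = protocol.params.validate()
    if params.pacemaker_output is not P.default_pacemaker_output:
        raise NotImplementedError(
            "the compiled integrator supports only the default pacemaker "
            "output C0 = (1 + x)/2")
    pv = pack_params(params)
    segs = compile_segments(protocol, cfg.burn_in, cfg.dt)
    n_steps = segs["n_steps"]
    burn_steps = int(round(cfg.burn_in * SECONDS_PER_DAY / cfg.dt))
    stride = int(round(cfg.record_stride / cfg.dt))
    n_rec = int(math.ceil((n_steps - burn_steps) / stride))

    state0 = init if init is not None else ModelState()
    y = state0.as_array()

    has_noise = params.switch.noise_sd > 0
    if has_noise:
        rng = np.random.default_rng(cfg.seed)
        noise_v = rng.standard_normal(n_steps)
        noise_m = rng.standard_normal(n_steps)
    else:
        noise_v = np.zeros(1)
        noise_m = np.zeros(1)

    rec_state = np.empty((6, n_rec))
    rec_qm = np.empty(n_rec)
    rec_qv = np.empty(n_rec)
    rec_lux = np.empty(n_rec)

    status, istep, var = _kernel(
        y, pv, cfg.dt, n_steps, burn_steps, stride,
        segs["end_step"], segs["lux"], segs["nu_spz"], segs["m_mask"],
        segs["scn_gain"], noise_v, noise_m, has_noise,
        rec_state, rec_qm, rec_qv, rec_lux)
    if status != 0:
        raise IntegrationError(
            f"non-finite value in state variable {STATE_NAMES[var]!r} at "
            f"step {istep} (t = {istep * cfg.dt:.1f} s)")

    times = (np.arange(n_rec) * stride * cfg.dt)
    return SimulationResult(
        times=times, V_v=rec_state[0], V_m=rec_state[1], H=rec_state[2],
        x=rec_state[3], x_c=rec_state[4], n=rec_state[5],
        Q_m=rec_qm, Q_v=rec_qv, awake=rec_qm > params.wake_threshold,
        lux=rec_lux, params_snapshot=params.to_dict(), seed=cfg.seed,
        dt=cfg.dt, record_stride=cfg.record_stride, burn_in=cfg.burn_in,
        protocol_name=protocol.name, wake_threshold=params.wake_threshold,
        final_state=ModelState.from_array(y, t=n_steps * cfg.dt))


def integrate(params: ModelParams, schedule: LightSchedule, duration: float,
              cfg: IntegratorConfig, init: ModelState | None = None
              ) -> SimulationResult:
    """Simulate `duration` days under a fixed light schedule.

    The first ``cfg.burn_in`` days are discarded; ``duration`` must
    exceed the burn-in.
    """
    if duration <= cfg.burn_in:
        raise ValueError("duration must exceed the burn-in")
    n_days = int(round(duration - cfg.burn_in))
    proto = Protocol(name="adhoc", params=params, schedule=schedule,
                     n_days=n_days)
    return run_protocol(proto, cfg, init=init)


def step(state: ModelState, t: float, params: ModelParams,
         schedule: LightSchedule, dt: float,
         rng: np.random.Generator | None = None) -> ModelState:
    """One Euler--Maruyama update (reference implementation).

    The arousal flag is recomputed from the updated voltages so the next
    step's light gating sees the new state.
    """
    from .model import full_rhs
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = state.as_array()
    dy = full_rhs(state, t, params, schedule)
    y += dy * dt
    sd = params.switch.noise_sd
    if sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires a random generator")
        z = rng.standard_normal(2)
        y[0] += sd * math.sqrt(dt) * z[0]
        y[1] += sd * math.sqrt(dt) * z[1]
    y[5] = min(max(y[5], 0.0), 1.0)
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(y))[0])]
        raise IntegrationError(f"non-finite value in {bad!r} at t = {t:.1f} s")
    return ModelState.from_array(y, t=t + dt)
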