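"""Two-state mass/momentum-exchange model of light-driven condensate swimming.

A DNA condensate under localized, alternating UV/Vis irradiation is reduced
to a binary system of a 'Liquid' domain (mass ``m_L``) and a 'Dissociated'
domain (mass ``m_D``).  Photoswitching is treated as instantaneous; between
switches the system evolves over half-cycles ("intervals") of length ``T``:

* UV-to-Vis interval — the Liquid domain disassembles at a time-dependent
  rate ``A(t')`` (``t'`` is the lap time since the last switch); a fraction
  ``lambda(t')`` of the transferring motifs disengages from the cycle by
  free diffusion, the rest joins the Dissociated domain.
* Vis-to-UV interval — the Dissociated domain reassociates at a constant
  rate ``B``; a constant fraction ``kappa`` disengages, the rest rejoins
  the Liquid domain.

Both ``A`` and ``lambda`` grow nonlinearly with the lap time relative to a
characteristic diffusion time ``tau_star``; here they take the saturating
form ``max * (1 - exp(-(t'/tau_star)^2))`` (quadratic onset, bounded), and
the functional form is pluggable via ``ModelParams.ramp``.

Migration of the Liquid domain is one-dimensional (positive = away from the
irradiated region of interest).  Its velocity ``u`` receives a momentum
term and a viscous dissipation term in each interval:

* UV-to-Vis: rocket-type recoil ``du = A(t') * v_eject * dt`` from mass
  ejected backward at relative speed ``v_eject``; the ejected mass
  accumulates in a Dissociated-domain momentum pool with bulk velocity
  ``u_D`` which relaxes diffusively at rate ``beta``.
* Vis-to-UV: perfectly mixing momentum transfer of the returning mass,
  ``du = (1-kappa) * B * (m_D/m_L) * ((u_D - v_reverse) - u) * dt``,
  carrying both the Vis-generated reversing flow (speed ``v_reverse``
  toward the ROI) and the conserved negative momentum from the previous
  UV ejection.  This term is the "momentum exchange" and can be ablated.
* Both intervals: viscous drag ``du = -gamma * u * dt``.

Integration is forward (explicit) Euler with step ``dt``; mass transfers
are constructed to conserve the ledger ``m_L + m_D + m_lost`` exactly up
to floating-point rounding.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "SwitchingSchedule",
    "ModelParams",
    "CondensateState",
    "StateTimeSeries",
    "RegimeSummary",
    "disassembly_ratio",
    "disengagement_ratio",
    "euler_step",
    "simulate",
    "summarize_run",
    "frequency_sweep",
    "ablation_compare",
    "load_default_params",
    "DEFAULT_FREQUENCIES",
    "DEFAULT_HORIZON",
]

_MASS_FLOOR = 1e-12  # guard on m_L in the Vis-phase exchange denominator


class Phase(enum.Enum):
    """Half-cycle identity: the pulse that opened it and the one that ends it."""

    UV_TO_VIS = "UV_to_Vis"
    VIS_TO_UV = "Vis_to_UV"

    def other(self) -> "Phase":
        return Phase.VIS_TO_UV if self is Phase.UV_TO_VIS else Phase.UV_TO_VIS


def _gaussian_ramp(t_lap: float, tau_star: float) -> float:
    """Saturating onset 1 - exp(-(t'/tau*)^2): quadratic at small t', bounded by 1."""
    s = t_lap / tau_star
    return -math.expm1(-s * s)


@dataclass(frozen=True)
class SwitchingSchedule:
    """Alternation of instantaneous UV/Vis pulses every ``interval_length``.

    The switching frequency counts full UV+Vis cycles: ``f = 1/(2T)``.
    """

    interval_length: float
    n_intervals: int = 1
    start_phase: Phase = Phase.UV_TO_VIS

    def __post_init__(self) -> None:
        if not self.interval_length > 0:
            raise ValueError(f"interval_length must be > 0, got {self.interval_length}")
        if self.n_intervals < 1:
            raise ValueError(f"n_intervals must be >= 1, got {self.n_intervals}")

    @property
    def switching_frequency(self) -> float:
        return 1.0 / (2.0 * self.interval_length)

    @classmethod
    def from_frequency(cls, f: float, n_intervals: int = 1,
                       start_phase: Phase = Phase.UV_TO_VIS) -> "SwitchingSchedule":
        if not f > 0:
            raise ValueError(f"switching frequency must be > 0, got {f}")
        return cls(interval_length=1.0 / (2.0 * f), n_intervals=n_intervals,
                   start_phase=start_phase)

    @property
    def total_time(self) -> float:
        return self.interval_length * self.n_intervals


@dataclass(frozen=True)
class ModelParams:
    """Rate, momentum and integration parameters (dimensionless model units).

    Parameters
    ----------
    A_max : maximum disassembly ratio in UV-to-Vis intervals (1/time).
    lambda_max : maximum disengagement ratio in UV-to-Vis (fraction in [0, 1]).
    B : constant disassembly ratio in Vis-to-UV (1/time).
    kappa : constant disengagement ratio in Vis-to-UV (fraction in [0, 1]).
    tau_star : characteristic diffusion time t* governing the onset of
        A(t') and lambda(t').
    dt : explicit-Euler time step.
    v_eject : speed of the UV-discharged flow relative to the Liquid domain
        (ejected backward, i.e. toward the ROI).
    v_reverse : speed of the Vis-generated reversing flow toward the ROI.
    gamma : viscous drag rate on the Liquid-domain velocity (1/time).
    beta : diffusive momentum-decay rate of the Dissociated domain (1/time).
    exchange_enabled : if False, the Vis-to-UV momentum-exchange term is
        ablated (the UV recoil and the drag remain).
    ramp : onset profile g(t', tau*) in [0, 1] shared by A and lambda;
        defaults to 1 - exp(-(t'/tau*)^2).
    """

    A_max: float = 0.05
    lambda_max: float = 1.0
    B: float = 0.3
    kappa: float = 0.05
    tau_star: float = 8.0
    dt: float = 0.01
    v_eject: float = 1.0
    v_reverse: float = 5.0
    gamma: float = 0.2
    beta: float = 0.1
    exchange_enabled: bool = True
    ramp: Callable[[float, float], float] = field(default=_gaussian_ramp, repr=False)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not self.tau_star > 0:
            raise ValueError(f"tau_star must be > 0, got {self.tau_star}")
        if self.A_max < 0 or self.B < 0:
            raise ValueError("disassembly ratios must be nonnegative")
        if self.A_max * self.dt >= 1 or self.B * self.dt >= 1:
            raise ValueError(
                "explicit-Euler positivity requires A_max*dt < 1 and B*dt < 1 "
                f"(got A_max*dt={self.A_max * self.dt}, B*dt={self.B * self.dt})"
            )
        if not 0 <= self.lambda_max <= 1:
            raise ValueError(f"lambda_max must lie in [0, 1], got {self.lambda_max}")
        if not 0 <= self.kappa <= 1:
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        for name in ("v_eject", "v_reverse", "gamma", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class CondensateState:
    """Instantaneous model state.

    Velocities are 1D with positive pointing away from the ROI.  ``u_D`` is
    the bulk velocity of the Dissociated domain's momentum pool; ``m_lost``
    is the cumulative mass disengaged from the cycle.
    """

    t: float = 0.0
    t_lap: float = 0.0
    phase: Phase = Phase.UV_TO_VIS
    m_L: float = 100.0
    m_D: float = 0.0
    m_lost: float = 0.0
    u: float = 0.0
    u_D: float = 0.0
    x: float = 0.0

    def validate(self) -> None:
        if self.m_L < 0 or self.m_D < 0 or self.m_lost < 0:
            raise ValueError("masses must be nonnegative")
        if self.t_lap < 0:
            raise ValueError("lap time must be nonnegative")


def disassembly_ratio(t_lap: float, params: ModelParams) -> float:
    """Disassembly ratio A(t') of the Liquid domain in a UV-to-Vis interval.

    Grows from 0 at the switch instant and saturates at ``A_max`` on the
    scale of ``tau_star``.
    """
    if t_lap < 0:
        raise ValueError(f"lap time must be >= 0, got {t_lap}")
    return params.A_max * params.ramp(t_lap, params.tau_star)


def disengagement_ratio(t_lap: float, params: ModelParams) -> float:
    """Disengagement ratio lambda(t') in a UV-to-Vis interval, in [0, lambda_max]."""
    if t_lap < 0:
        raise ValueError(f"lap time must be >= 0, got {t_lap}")
    return params.lambda_max * params.ramp(t_lap, params.tau_star)


def _step(
    phase: Phase,
    t_lap: float,
    m_L: float,
    m_D: float,
    m_lost: float,
    u: float,
    u_D: float,
    x: float,
    p: ModelParams,
) -> tuple[float, float, float, float, float, float]:
    """One forward-Euler update of (m_L, m_D, m_lost, u, u_D, x).

    All derivatives are evaluated at the old state.  Mass transfers are
    split so the ledger m_L + m_D + m_lost is conserved to rounding.
    """
    dt = p.dt
    if phase is Phase.UV_TO_VIS:
        A = p.A_max * p.ramp(t_lap, p.tau_star)
        lam = p.lambda_max * p.ramp(t_lap, p.tau_star)
        dm = A * m_L * dt
        if dm > m_L:
            raise ArithmeticError(
                f"unstable step: UV transfer {dm} exceeds m_L={m_L}; reduce dt"
            )
        dm_lost = lam * dm
        dm_kept = dm - dm_lost
        new_m_L = m_L - dm
        new_m_D = m_D + dm_kept
        new_m_lost = m_lost + dm_lost
        # recoil: mass ejected backward at relative speed v_eject pushes the
        # Liquid domain forward
        du = A * p.v_eject * dt - p.gamma * u * dt
        # momentum pool of the Dissociated domain: the kept mass enters at
        # lab velocity (u - v_eject); the pool then randomizes at rate beta
        if new_m_D > _MASS_FLOOR:
            p_D = m_D * u_D + dm_kept * (u - p.v_eject)
            new_u_D = p_D / new_m_D
        else:
            new_u_D = 0.0
        new_u_D -= p.beta * new_u_D * dt
        new_u = u + du
    else:
        dm = p.B * m_D * dt
        if dm > m_D:
            raise ArithmeticError(
                f"unstable step: Vis transfer {dm} exceeds m_D={m_D}; reduce dt"
            )
        dm_lost = p.kappa * dm
        dm_kept = dm - dm_lost
        new_m_D = m_D - dm
        new_m_L = m_L + dm_kept
        new_m_lost = m_lost + dm_lost
        du = -p.gamma * u * dt
        if p.exchange_enabled:
            # returning mass mixes into the Liquid domain carrying the
            # reversing-flow bias and the pool's conserved momentum
            du += (1.0 - p.kappa) * p.B * (m_D / max(m_L, _MASS_FLOOR)) \
                * ((u_D - p.v_reverse) - u) * dt
        # mass leaving the pool carries velocity u_D, leaving u_D unchanged;
        # diffusive randomization continues
        new_u_D = u_D - p.beta * u_D * dt
        new_u = u + du
    new_x = x + u * dt
    return new_m_L, new_m_D, new_m_lost, new_u, new_u_D, new_x


def euler_step(state: CondensateState, params: ModelParams) -> CondensateState:
    """Advance the state by one explicit-Euler step of length ``params.dt``.

    Clocks advance by ``dt``; phase switching is the scheduler's job
    (see :func:`simulate`), not this function's.
    """
    state.validate()
    m_L, m_D, m_lost, u, u_D, x = _step(
        state.phase, state.t_lap, state.m_L, state.m_D, state.m_lost,
        state.u, state.u_D, state.x, params,
    )
    return replace(
        state,
        t=state.t + params.dt,
        t_lap=state.t_lap + params.dt,
        m_L=m_L, m_D=m_D, m_lost=m_lost, u=u, u_D=u_D, x=x,
    )


@dataclass
class StateTimeSeries:
    """Snapshot arrays at every Euler step, with the generating configuration."""

    params: ModelParams
    schedule: SwitchingSchedule
    t: np.ndarray
    t_lap: np.ndarray
    phase: np.ndarray  # 0 = UV_to_Vis, 1 = Vis_to_UV
    m_L: np.ndarray
    m_D: np.ndarray
    m_lost: np.ndarray
    u: np.ndarray
    u_D: np.ndarray
    x: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self, stride: int = 1) -> pd.DataFrame:
        """Long-format table, optionally decimated to every ``stride``-th step."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        sl = slice(None, None, stride)
        phase_labels = np.where(self.phase[sl] == 0,
                                Phase.UV_TO_VIS.value, Phase.VIS_TO_UV.value)
        return pd.DataFrame({
            "t": self.t[sl],
            "phase": phase_labels,
            "m_L": self.m_L[sl],
            "m_D": self.m_D[sl],
            "m_lost": self.m_lost[sl],
            "u": self.u[sl],
            "u_D": self.u_D[sl],
            "x": self.x[sl],
        })


def simulate(
    params: ModelParams,
    schedule: SwitchingSchedule,
    m_L0: float = 100.0,
    m_D0: float = 0.0,
) -> StateTimeSeries:
    """Integrate the two-state model over the full switching schedule.

    The first snapshot is the initial condition (m_L = ``m_L0``,
    m_D = ``m_D0``, everything else zero).  Photoswitching is instantaneous
    and occurs exactly at multiples of the interval length, at which point
    the lap time resets to zero; the interval length must therefore be an
    integer multiple of ``dt`` (checked to 1e-9 relative).
    """
    if not m_L0 > 0:
        raise ValueError(f"initial Liquid mass must be > 0, got {m_L0}")
    if m_D0 < 0:
        raise ValueError(f"initial Dissociated mass must be >= 0, got {m_D0}")
    steps_per_interval = schedule.interval_length / params.dt
    n_per = round(steps_per_interval)
    if n_per < 1 or abs(steps_per_interval - n_per) > 1e-9 * steps_per_interval:
        raise ValueError(
            f"interval_length={schedule.interval_length} is not an integer "
            f"multiple of dt={params.dt}; phase changes must fall on steps"
        )
    n_steps = n_per * schedule.n_intervals
    n = n_steps + 1

    t = np.empty(n)
    t_lap = np.empty(n)
    phase_arr = np.empty(n, dtype=np.int8)
    m_L_arr = np.empty(n)
    m_D_arr = np.empty(n)
    m_lost_arr = np.empty(n)
    u_arr = np.empty(n)
    u_D_arr = np.empty(n)
    x_arr = np.empty(n)

    phase = schedule.start_phase
    m_L, m_D, m_lost, u, u_D, x = float(m_L0), float(m_D0), 0.0, 0.0, 0.0, 0.0
    lap = 0.0
    dt = params.dt
    t[0], t_lap[0] = 0.0, 0.0
    phase_arr[0] = 0 if phase is Phase.UV_TO_VIS else 1
    m_L_arr[0], m_D_arr[0], m_lost_arr[0] = m_L, m_D, m_lost
    u_arr[0], u_D_arr[0], x_arr[0] = u, u_D, x

    for k in range(1, n):
        m_L, m_D, m_lost, u, u_D, x = _step(
            phase, lap, m_L, m_D, m_lost, u, u_D, x, params)
        lap += dt
        if (k % n_per) == 0:  # instantaneous pulse: toggle phase, reset lap
            phase = phase.other()
            lap = 0.0
        t[k] = k * dt
        t_lap[k] = lap
        phase_arr[k] = 0 if phase is Phase.UV_TO_VIS else 1
        m_L_arr[k], m_D_arr[k], m_lost_arr[k] = m_L, m_D, m_lost
        u_arr[k], u_D_arr[k], x_arr[k] = u, u_D, x

    return StateTimeSeries(
        params=params, schedule=schedule,
        t=t, t_lap=t_lap, phase=phase_arr,
        m_L=m_L_arr, m_D=m_D_arr, m_lost=m_lost_arr,
        u=u_arr, u_D=u_D_arr, x=x_arr,
    )


@dataclass(frozen=True)
class RegimeSummary:
    """Scalar diagnostics of one simulated run at switching frequency ``f``.

    ``lifetime`` is the first time m_L falls below a fraction of its initial
    value (math.inf if it never does within the horizon).
    """

    f: float
    lifetime: float
    net_displacement: float
    peak_speed: float
    positive_fraction: float


def summarize_run(series: StateTimeSeries,
                  lifetime_threshold: float = 0.10) -> RegimeSummary:
    """Reduce a run to lifetime / displacement / velocity-sign diagnostics."""
    if len(series) == 0:
        raise ValueError("cannot summarize an empty series")
    if not 0 < lifetime_threshold < 1:
        raise ValueError("lifetime_threshold must lie in (0, 1)")
    m_L0 = series.m_L[0]
    below = np.nonzero(series.m_L < lifetime_threshold * m_L0)[0]
    lifetime = float(series.t[below[0]]) if below.size else math.inf
    u_steps = series.u[1:] if len(series) > 1 else series.u
    return RegimeSummary(
        f=series.schedule.switching_frequency,
        lifetime=lifetime,
        net_displacement=float(series.x[-1]),
        peak_speed=float(np.max(np.abs(series.u))),
        positive_fraction=float(np.mean(u_steps > 0)) if u_steps.size else 0.0,
    )


def _schedule_for(f: float, horizon: float, params: ModelParams) -> SwitchingSchedule:
    if not f > 0:
        raise ValueError(f"switching frequency must be > 0, got {f}")
    T = 1.0 / (2.0 * f)
    n_intervals = max(1, round(horizon / T))
    return SwitchingSchedule(interval_length=T, n_intervals=n_intervals)


def frequency_sweep(
    params: ModelParams,
    frequencies: Sequence[float],
    horizon: float,
    m_L0: float = 100.0,
    lifetime_threshold: float = 0.10,
) -> list[RegimeSummary]:
    """Run the model at each switching frequency over a common horizon.

    Each run spans ``round(horizon / T)`` intervals so all runs cover the
    same elapsed time (up to one half-cycle of rounding).  The model is
    deterministic, so the sweep is too.
    """
    if len(set(frequencies)) < 2:
        raise ValueError("a sweep needs at least 2 distinct frequencies")
    out = []
    for f in frequencies:
        series = simulate(params, _schedule_for(f, horizon, params), m_L0=m_L0)
        out.append(summarize_run(series, lifetime_threshold=lifetime_threshold))
    return out


def ablation_compare(
    params: ModelParams,
    frequencies: Sequence[float],
    horizon: float,
    m_L0: float = 100.0,
) -> dict[str, list[RegimeSummary]]:
    """Paired sweeps with the Vis-interval momentum exchange on and off.

    Without the exchange the returning mass imparts no momentum, so only the
    positively signed UV recoil drives migration at every frequency.
    """
    on = replace(params, exchange_enabled=True)
    off = replace(params, exchange_enabled=False)
    return {
        "exchange_on": frequency_sweep(on, frequencies, horizon, m_L0=m_L0),
        "exchange_off": frequency_sweep(off, frequencies, horizon, m_L0=m_L0),
    }


#: default low / intermediate / high switching frequencies (cycles per unit
#: time, f = 1/(2T)); chosen so the half-cycle is long (5 tau*), comparable
#: (tau*), and short (tau*/8) relative to tau_star = 8 respectively.
DEFAULT_FREQUENCIES: tuple[float, float, float] = (0.0125, 0.0625, 0.5)

#: default sweep horizon (model time units): an odd multiple of the low-
#: frequency half-cycle, so every run ends exactly at a switching moment
#: after a completed UV-to-Vis interval (displacements are read off at
#: switching moments, as in the interface-tracking experiments).
DEFAULT_HORIZON: float = 200.0


def load_default_params(path=None) -> ModelParams:
    """Load the shipped (or a user) flat YAML parameter profile."""
    import yaml
    from importlib import resources

    if path is None:
        text = resources.files("azoswim.data").joinpath("defaults.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    known = {k: v for k, v in raw.items()
             if k in ModelParams.__dataclass_fields__ and k != "ramp"}
    return ModelParams(**known)
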