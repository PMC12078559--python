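"""Swimming-displacement bookkeeping and the threshold-frequency estimate.

A swimming condensate is tracked by the position of its interface at each
photoswitching moment t_i.  The step displacement is Delta_r_i = p_i -
p_{i-1}; the running vector sum gives (Delta_x, Delta_y); its norm is the
net displacement L(t) = |sum_i Delta_r_i|, with maximum L_max.

The push/pull threshold frequency follows from a diffusive traversal
argument: the UV-discharged microflow must spread across the condensate
(size ``a``) and the Vis-reversed flow must travel the same distance back.
With 2D mean-square-displacement scaling <r^2(tau)> ~ 4 D tau, the
characteristic cycle time is

    tau_c = tau_UV + tau_Vis = a^2 / (4 D_S) + a^2 / (4 D_R),

and f_c = 1 / tau_c.  Below f_c the motion is dissipation-dominant
(push-swimming away from the ROI); above it, energy-exchange-dominant
(pull-swimming toward the ROI).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DisplacementSeries",
    "CycleEstimate",
    "SwimmingRegime",
    "RegimeCall",
    "displacement_series",
    "cycle_estimate",
    "regime",
    "max_net_displacement",
]


@dataclass
class DisplacementSeries:
    """Per-switch interface displacements and their running net displacement."""

    switch_times: np.ndarray        # t_i (s), increasing, one per position
    step_displacements: np.ndarray  # Delta_r_i (um), shape (n-1, 2)
    cumulative: np.ndarray          # running (Delta_x, Delta_y), shape (n-1, 2)
    L: np.ndarray                   # |running sum| per step (um)
    L_max: float
    normalized_time: np.ndarray     # elapsed / total duration per step, in [0, 1]
    frequency: float | None = None  # optional switching-frequency tag (1/s)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.switch_times[1:],
            "dx_um": self.step_displacements[:, 0],
            "dy_um": self.step_displacements[:, 1],
            "cum_dx_um": self.cumulative[:, 0],
            "cum_dy_um": self.cumulative[:, 1],
            "L_um": self.L,
            "normalized_time": self.normalized_time,
        })


def displacement_series(
    interface_positions: Sequence[Sequence[float]],
    switch_times: Sequence[float],
    frequency: float | None = None,
) -> DisplacementSeries:
    """Displacement bookkeeping from interface positions at switching moments."""
    pos = np.asarray(interface_positions, dtype=float)
    times = np.asarray(switch_times, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("interface_positions must be an (n, 2) array")
    if len(pos) < 2:
        raise ValueError(f"need >= 2 interface positions, got {len(pos)}")
    if len(times) != len(pos):
        raise ValueError("one switch time per interface position required")
    if not np.all(np.diff(times) > 0):
        raise ValueError("switch times must be strictly increasing")
    steps = np.diff(pos, axis=0)
    cumulative = np.cumsum(steps, axis=0)
    L = np.linalg.norm(cumulative, axis=1)
    duration = times[-1] - times[0]
    normalized = (times[1:] - times[0]) / duration
    return DisplacementSeries(
        switch_times=times,
        step_displacements=steps,
        cumulative=cumulative,
        L=L,
        L_max=float(L.max()),
        normalized_time=normalized,
        frequency=frequency,
    )


@dataclass(frozen=True)
class CycleEstimate:
    """Characteristic cycle time and threshold switching frequency.

    ``tau_UV = a^2/(4 D_S)`` (UV spread across the condensate) and
    ``tau_Vis = a^2/(4 D_R)`` (Vis reversal over the same distance);
    ``tau_c`` is their sum and ``f_c = 1/tau_c``.
    """

    a: float      # condensate size (um)
    D_S: float    # spreading effective diffusion coefficient (um^2/s)
    D_R: float    # reversed-flow effective diffusion coefficient (um^2/s)
    tau_UV: float
    tau_Vis: float
    tau_c: float
    f_c: float


def cycle_estimate(a: float, D_S: float, D_R: float) -> CycleEstimate:
    """Threshold-frequency estimate from condensate size and flow mobilities."""
    for name, v in (("a", a), ("D_S", D_S), ("D_R", D_R)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    tau_UV = a * a / (4.0 * D_S)
    tau_Vis = a * a / (4.0 * D_R)
    tau_c = tau_UV + tau_Vis
    return CycleEstimate(a=a, D_S=D_S, D_R=D_R, tau_UV=tau_UV,
                         tau_Vis=tau_Vis, tau_c=tau_c, f_c=1.0 / tau_c)


class SwimmingRegime(enum.Enum):
    DISSIPATION_DOMINANT_PUSH = "dissipation_dominant_push"
    EXCHANGE_DOMINANT_PULL = "exchange_dominant_pull"


@dataclass(frozen=True)
class RegimeCall:
    regime: SwimmingRegime
    at_boundary: bool = False


def regime(f: float, estimate: CycleEstimate) -> RegimeCall:
    """Push/pull regime of a switching frequency relative to f_c.

    f < f_c: dissipation-dominant push-swimming; f > f_c: exchange-dominant
    pull-swimming.  The boundary f == f_c is assigned to pull with a flag.
    """
    if not f > 0:
        raise ValueError(f"switching frequency must be > 0, got {f}")
    if f < estimate.f_c:
        return RegimeCall(SwimmingRegime.DISSIPATION_DOMINANT_PUSH)
    return RegimeCall(SwimmingRegime.EXCHANGE_DOMINANT_PULL,
                      at_boundary=(f == estimate.f_c))


def max_net_displacement(series_set: Iterable[DisplacementSeries]) -> pd.DataFrame:
    """(f, L_max) scatter table across displacement series."""
    rows = []
    for i, series in enumerate(series_set):
        rows.append({"series": i, "f_per_s": series.frequency,
                     "L_max_um": series.L_max})
    if not rows:
        raise ValueError("need at least one displacement series")
    return pd.DataFrame(rows)
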