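"""Temperature-to-flow-mode classification of photoresponsive condensates.

A DNA condensate variant is characterized, for each azobenzene isomer state
(trans under Vis, cis under UV), by two temperatures: the gel-to-liquid
transition temperature T_GL and the dissolving temperature T_D (above which
the condensate is stably dissociated).  At temperature T the phase state is

    gel          if T <  T_GL
    liquid       if T_GL <= T < T_D
    dissociated  if T >= T_D

(half-open boundaries; cis destabilizes sticky-end binding, so T_D under
cis never exceeds T_D under trans).  The photoinduced flow mode follows
from the (Vis-state, UV-state) pair:

    (gel, dissociated)    -> spread             (fast outward dissolution)
    (gel, liquid)         -> collapse           (gel-to-liquid compaction)
    (liquid, dissociated) -> spread_and_collect (cyclic out-and-back flow)
    anything else         -> none

The shipped variant fixtures (Y_1x7, Y_3x5, Y_2x1x5 — named by azobenzene
insertion site in the 8-nt sticky end) carry measured dissolving
temperatures where printed; the gel--liquid transition temperatures are
back-solved from the observed mode/temperature ranges and are synthetic
derived values, not measurements.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Isomer",
    "PhaseState",
    "FlowMode",
    "VariantThermo",
    "ModeCall",
    "phase_state",
    "flow_mode",
    "mode_table",
    "shipped_variants",
    "read_variants",
]

#: temperatures within this band of a boundary are snapped onto it
TEMP_TOL = 0.1


class Isomer(enum.Enum):
    TRANS = "trans"  # Vis-stabilized
    CIS = "cis"      # UV-destabilized


class PhaseState(enum.Enum):
    GEL = "gel"
    LIQUID = "liquid"
    DISSOCIATED = "dissociated"


_LADDER = {PhaseState.GEL: 0, PhaseState.LIQUID: 1, PhaseState.DISSOCIATED: 2}


class FlowMode(enum.Enum):
    SPREAD = "spread"
    COLLAPSE = "collapse"
    SPREAD_AND_COLLECT = "spread_and_collect"
    NONE = "none"


@dataclass(frozen=True)
class VariantThermo:
    """Per-variant thermal parameters (degrees C).

    ``dH_trans`` / ``dH_cis`` are optional sticky-end binding enthalpy
    magnitudes (kcal/mol), carried as passthrough metadata only.
    """

    variant_name: str
    T_D_trans: float
    T_D_cis: float
    T_GL_trans: float
    T_GL_cis: float
    dH_trans: float | None = None
    dH_cis: float | None = None

    def __post_init__(self) -> None:
        if self.T_GL_trans > self.T_D_trans:
            raise ValueError(
                f"{self.variant_name}: T_GL_trans ({self.T_GL_trans}) must not "
                f"exceed T_D_trans ({self.T_D_trans})"
            )
        if self.T_GL_cis > self.T_D_cis:
            raise ValueError(
                f"{self.variant_name}: T_GL_cis ({self.T_GL_cis}) must not "
                f"exceed T_D_cis ({self.T_D_cis})"
            )
        if self.T_D_cis > self.T_D_trans:
            raise ValueError(
                f"{self.variant_name}: T_D_cis ({self.T_D_cis}) must not exceed "
                f"T_D_trans ({self.T_D_trans}); cis destabilizes binding"
            )

    def boundaries(self, isomer: Isomer) -> tuple[float, float]:
        if isomer is Isomer.TRANS:
            return self.T_GL_trans, self.T_D_trans
        return self.T_GL_cis, self.T_D_cis


def _snap(T: float, boundary: float) -> float:
    """Temperatures within TEMP_TOL of a boundary count as on the boundary."""
    return boundary if abs(T - boundary) <= TEMP_TOL else T


def phase_state(T: float, thermo: VariantThermo, isomer: Isomer) -> PhaseState:
    """Phase state on the gel -> liquid -> dissociated ladder at T (degC)."""
    t_gl, t_d = thermo.boundaries(isomer)
    if _snap(T, t_d) >= t_d:
        return PhaseState.DISSOCIATED
    if _snap(T, t_gl) >= t_gl:
        return PhaseState.LIQUID
    return PhaseState.GEL


@dataclass(frozen=True)
class ModeCall:
    """Classification of one (variant, temperature) pair."""

    variant_name: str
    temperature: float
    state_vis: PhaseState
    state_uv: PhaseState
    mode: FlowMode


_MODE_RULES = {
    (PhaseState.GEL, PhaseState.DISSOCIATED): FlowMode.SPREAD,
    (PhaseState.GEL, PhaseState.LIQUID): FlowMode.COLLAPSE,
    (PhaseState.LIQUID, PhaseState.DISSOCIATED): FlowMode.SPREAD_AND_COLLECT,
}


def flow_mode(thermo: VariantThermo, T: float) -> ModeCall:
    """Flow mode at temperature T, a pure function of (Vis-state, UV-state)."""
    state_vis = phase_state(T, thermo, Isomer.TRANS)
    state_uv = phase_state(T, thermo, Isomer.CIS)
    mode = _MODE_RULES.get((state_vis, state_uv), FlowMode.NONE)
    return ModeCall(thermo.variant_name, T, state_vis, state_uv, mode)


def mode_table(
    variants: Iterable[VariantThermo],
    temperatures: Sequence[float],
) -> pd.DataFrame:
    """Mode calls for every (variant, temperature) on a grid."""
    rows = []
    for thermo in variants:
        for T in temperatures:
            call = flow_mode(thermo, T)
            rows.append({
                "variant": call.variant_name,
                "temperature_C": call.temperature,
                "state_vis": call.state_vis.value,
                "state_uv": call.state_uv.value,
                "mode": call.mode.value,
            })
    return pd.DataFrame(rows)


def shipped_variants() -> dict[str, VariantThermo]:
    """Built-in fixtures for the three azobenzene insertion-site variants.

    T_D_trans of Y_2x1x5 (50 degC) and Y_3x5 (65 degC) are the printed
    dissolving temperatures; the remaining values are synthetic, back-solved
    so the classifier reproduces the observed mode/temperature ranges
    (spread < 40 degC for Y_2x1x5, 45-60 degC for Y_3x5, > 60 degC for
    Y_1x7; collapse 35-50 degC for Y_1x7; spread-and-collect 40-45 degC for
    Y_2x1x5 and 55-60 degC for Y_3x5).
    """
    return {
        "Y_1x7": VariantThermo("Y_1x7", T_D_trans=80.0, T_D_cis=61.0,
                               T_GL_trans=75.0, T_GL_cis=35.0),
        "Y_3x5": VariantThermo("Y_3x5", T_D_trans=65.0, T_D_cis=45.0,
                               T_GL_trans=55.0, T_GL_cis=45.0),
        "Y_2x1x5": VariantThermo("Y_2x1x5", T_D_trans=50.0, T_D_cis=3.0,
                                 T_GL_trans=40.0, T_GL_cis=3.0),
    }


_REQUIRED_COLUMNS = ["variant_name", "T_D_trans", "T_D_cis",
                     "T_GL_trans", "T_GL_cis"]


def read_variants(path) -> dict[str, VariantThermo]:
    """Load variant thermal parameters from a CSV fixture file."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant file {path} missing columns: {missing}")
    out = {}
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _REQUIRED_COLUMNS}
        kwargs["variant_name"] = str(kwargs["variant_name"])
        for opt in ("dH_trans", "dH_cis"):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = float(row[opt])
        thermo = VariantThermo(**kwargs)
        out[thermo.variant_name] = thermo
    return out
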