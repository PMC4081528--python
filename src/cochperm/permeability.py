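"""Closed-form water-permeability arithmetic with strict unit handling.

Diffusional coefficient:  P_D = P' * V_e / A
Osmotic volume flow:      J_v = V_e * (SI / 100) / duration
Osmotic coefficient:      P_f = J_v / (Vw_bar * A * dc)
Channel density:          n   = P_f / p_f_single

All public results are in cm/s (P_D, P_f), ul/min (J_v) or 1/um^2
(channel density).  Inputs arrive in the bench units used throughout
the package (1/min, ul, mm^2, mol/l) and are converted to CGS
internally; the conversions are exact powers of ten.

The estimated channel density from the printed inputs is
3.14e4 um^-2 whereas the source literature prints 3.45e4 um^-2; the
quotient does not reproduce the printed figure and the computed value
is reported (see ``ChannelDensityResult.note``).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "VBAR_W_CM3_MOL",
    "DiffusionalInputs",
    "OsmoticInputs",
    "PermeabilityResult",
    "ChannelDensityResult",
    "compute_Pd",
    "compute_Jv",
    "compute_Pf",
    "compute_ratio",
    "mean_reference_Pd",
    "estimate_channel_density",
    "load_reference_table",
]

#: Partial molar volume of water (cm^3/mol).
VBAR_W_CM3_MOL = 18.0

_SECONDS_PER_MIN = 60.0
_CM3_PER_UL = 1.0e-3
_CM2_PER_MM2 = 1.0e-2
_MOL_CM3_PER_MOL_L = 1.0e-3
_UM2_PER_CM2 = 1.0e8

CHANNEL_DENSITY_NOTE = (
    "direct quotient of the printed inputs gives 3.14e4 um^-2; "
    "the source text prints 3.45e4 um^-2 and the origin of the "
    "difference is not stated -- the computed quotient is reported"
)


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (v > 0) or not math.isfinite(v):
            raise ValidationError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class DiffusionalInputs:
    p_prime_per_min: float
    v_e_ul: float
    area_mm2: float

    def __post_init__(self):
        _require_positive(p_prime_per_min=self.p_prime_per_min,
                          v_e_ul=self.v_e_ul, area_mm2=self.area_mm2)


@dataclass(frozen=True)
class OsmoticInputs:
    """Inputs for P_f; J_v may be given directly or derived from SI."""

    area_mm2: float
    delta_c_mol_l: float
    jv_ul_min: float | None = None
    v_e_ul: float | None = None
    si_pct: float | None = None
    duration_min: float = 20.0
    vbar_w_cm3_mol: float = VBAR_W_CM3_MOL

    def __post_init__(self):
        _require_positive(area_mm2=self.area_mm2, delta_c_mol_l=self.delta_c_mol_l,
                          duration_min=self.duration_min,
                          vbar_w_cm3_mol=self.vbar_w_cm3_mol)
        if self.jv_ul_min is None:
            if self.v_e_ul is None or self.si_pct is None:
                raise ValidationError(
                    "either jv_ul_min or both v_e_ul and si_pct must be given")
            if self.si_pct < 0:
                raise ValidationError("solute increase must be >= 0")

    def resolved_jv_ul_min(self) -> float:
        if self.jv_ul_min is not None:
            return self.jv_ul_min
        return compute_Jv(self.v_e_ul, self.si_pct, self.duration_min)


@dataclass(frozen=True)
class PermeabilityResult:
    """A permeability coefficient in cm/s plus the inputs that produced it."""

    value_cm_s: float
    kind: str  # "P_D" or "P_f"
    inputs: dict = field(default_factory=dict)

    def scaled(self, scale: float) -> float:
        """Value on a display scale, e.g. ``scaled(1e-5)`` for 1e-5 cm/s units."""
        return self.value_cm_s / scale


@dataclass(frozen=True)
class ChannelDensityResult:
    channels_per_um2: float
    single_channel_pf_cm3_s: float
    note: str = CHANNEL_DENSITY_NOTE


def compute_Pd(inputs: DiffusionalInputs) -> PermeabilityResult:
    """Diffusional water permeability P_D = P' V_e / A, in cm/s."""
    p_prime_per_s = inputs.p_prime_per_min / _SECONDS_PER_MIN
    v_cm3 = inputs.v_e_ul * _CM3_PER_UL
    a_cm2 = inputs.area_mm2 * _CM2_PER_MM2
    value = p_prime_per_s * v_cm3 / a_cm2
    return PermeabilityResult(value_cm_s=value, kind="P_D", inputs={
        "p_prime_per_min": inputs.p_prime_per_min,
        "v_e_ul": inputs.v_e_ul, "area_mm2": inputs.area_mm2})


def compute_Jv(v_e_ul: float, si_pct: float, duration_min: float = 20.0) -> float:
    """Transepithelial volume flow J_v = V_e (SI/100) / duration, in ul/min."""
    _require_positive(v_e_ul=v_e_ul, duration_min=duration_min)
    if si_pct < 0:
        raise ValidationError("solute increase must be >= 0")
    return v_e_ul * (si_pct / 100.0) / duration_min


def compute_Pf(inputs: OsmoticInputs) -> PermeabilityResult:
    """Osmotic water permeability P_f = J_v / (Vw_bar A dc), in cm/s."""
    jv_ul_min = inputs.resolved_jv_ul_min()
    jv_cm3_s = jv_ul_min * _CM3_PER_UL / _SECONDS_PER_MIN
    a_cm2 = inputs.area_mm2 * _CM2_PER_MM2
    dc_mol_cm3 = inputs.delta_c_mol_l * _MOL_CM3_PER_MOL_L
    denom = inputs.vbar_w_cm3_mol * a_cm2 * dc_mol_cm3
    if denom == 0:
        raise ValidationError("P_f denominator is zero")
    value = jv_cm3_s / denom
    return PermeabilityResult(value_cm_s=value, kind="P_f", inputs={
        "jv_ul_min": jv_ul_min, "area_mm2": inputs.area_mm2,
        "delta_c_mol_l": inputs.delta_c_mol_l,
        "vbar_w_cm3_mol": inputs.vbar_w_cm3_mol})


def compute_ratio(pf: PermeabilityResult, pd_: PermeabilityResult) -> float:
    """Dimensionless P_f / P_D (report rounded to two decimals)."""
    if pf.kind != "P_f" or pd_.kind != "P_D":
        raise ValidationError("compute_ratio expects (P_f, P_D) in that order")
    return pf.value_cm_s / pd_.value_cm_s


def mean_reference_Pd(values_1e5_cm_s: Sequence[float]) -> float:
    """Arithmetic mean of reference P_D values, on the 1e-5 cm/s scale."""
    vals = [float(v) for v in values_1e5_cm_s]
    if not vals:
        raise ValidationError("reference P_D list is empty")
    return sum(vals) / len(vals)


def estimate_channel_density(pf_cm_s: float,
                             pf_single_cm3_s: float) -> ChannelDensityResult:
    """Channel density n = P_f / p_f_single, reported per um^2."""
    _require_positive(pf_cm_s=pf_cm_s, pf_single_cm3_s=pf_single_cm3_s)
    n_per_cm2 = pf_cm_s / pf_single_cm3_s
    return ChannelDensityResult(channels_per_um2=n_per_cm2 / _UM2_PER_CM2,
                                single_channel_pf_cm3_s=pf_single_cm3_s)


def load_reference_table() -> pd.DataFrame:
    """Bundled comparative table of epithelial P_D / P_f values.

    The ``aqp5_reference`` flag marks the five AQP5-expressing epithelia
    whose P_D values are averaged for the outer-sulcus-cell reference.
    """
    ref = importlib.resources.files("cochperm.data") / "reference_permeabilities.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
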