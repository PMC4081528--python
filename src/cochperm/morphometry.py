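"""Surface-area morphometry of the cochlear perilymph-endolymph barrier.

The barrier separating endolymph from perilymph is split into two
partitions: Reissner's membrane (RM, between scala vestibuli and scala
media) and the organ of Corti (OC, between scala tympani and scala
media).  Each partition's water-permeated area is obtained from per
half-turn radial widths and longitudinal segment lengths: every
half-turn contributes a trapezoid ``l_i * (w_i + w_{i+1}) / 2``, the
hook region a rectangle ``l_h * w_I`` and the apical-most half-turn a
rectangle ``l_VIII * w_VIII`` (it has no apical neighbour).

Areas are carried in cm**2 internally for the downstream permeability
arithmetic; micrometre/millimetre values appear only at I/O boundaries.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "SEGMENT_LABELS",
    "HalfTurnTable",
    "BarrierAreas",
    "ReplicateSet",
    "ShuntMembraneArea",
    "compute_partition_areas",
    "summarize_replicates",
    "compute_shunt_area",
    "load_half_turn_table",
    "default_half_turn_table",
]

#: Ordered base-to-apex segment labels: hook region plus eight half-turns.
SEGMENT_LABELS = ("hook", "I", "II", "III", "IV", "V", "VI", "VII", "VIII")

UM2_PER_MM2 = 1.0e6
MM2_PER_CM2 = 1.0e2


@dataclass(frozen=True)
class HalfTurnTable:
    """Radial widths and longitudinal lengths per cochlear segment.

    Widths are indexed by half-turn (I..VIII); the hook region has no
    width of its own (the rule is to reuse ``w_I``).  Lengths cover all
    nine segments including the hook.  All values in micrometres.
    """

    labels: tuple[str, ...]
    w_rm_um: tuple[float, ...]  # 8 widths, half-turns I..VIII
    w_oc_um: tuple[float, ...]  # 8 widths, half-turns I..VIII
    l_um: tuple[float, ...]     # 9 lengths, hook + I..VIII

    def __post_init__(self):
        if self.labels != SEGMENT_LABELS:
            missing = set(SEGMENT_LABELS) - set(self.labels)
            if missing:
                raise ValidationError(
                    f"half-turn table is missing segment(s): {sorted(missing)}")
            raise ValidationError(
                f"segment labels must be ordered base->apex {SEGMENT_LABELS}, "
                f"got {self.labels}")
        if len(self.l_um) != 9:
            raise ValidationError(
                f"expected 9 segment lengths (hook + I..VIII), got {len(self.l_um)}")
        for name, widths in (("w_RM_um", self.w_rm_um), ("w_OC_um", self.w_oc_um)):
            if len(widths) != 8:
                raise ValidationError(
                    f"expected 8 {name} widths (half-turns I..VIII), got {len(widths)}")
            for label, w in zip(SEGMENT_LABELS[1:], widths):
                if not (w > 0) or not math.isfinite(w):
                    raise ValidationError(
                        f"{name} for half-turn {label} must be strictly positive, got {w}")
        for label, l in zip(SEGMENT_LABELS, self.l_um):
            if not (l > 0) or not math.isfinite(l):
                raise ValidationError(
                    f"length for segment {label} must be strictly positive, got {l}")

    def widths(self, partition: Literal["RM", "OC"]) -> tuple[float, ...]:
        if partition == "RM":
            return self.w_rm_um
        if partition == "OC":
            return self.w_oc_um
        raise ValidationError(f"unknown partition {partition!r}; expected 'RM' or 'OC'")


@dataclass(frozen=True)
class BarrierAreas:
    """Per-segment and total areas of one barrier partition."""

    partition: str
    labels: tuple[str, ...]
    per_segment_mm2: tuple[float, ...]
    total_mm2: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "total_mm2", float(sum(self.per_segment_mm2)))

    @property
    def total_cm2(self) -> float:
        return self.total_mm2 / MM2_PER_CM2

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "per_segment": [
                {"segment": s, "area_mm2": a}
                for s, a in zip(self.labels, self.per_segment_mm2)
            ],
            "total_mm2": self.total_mm2,
        }


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate measurements with sample statistics (sd uses n-1)."""

    values: tuple[float, ...]
    n: int
    mean: float
    sd: float | None

    def to_dict(self) -> dict:
        return {"values": list(self.values), "n": self.n,
                "mean": self.mean, "sd": self.sd}


@dataclass(frozen=True)
class ShuntMembraneArea:
    """Rectangular membrane area of the apical outer-sulcus-cell shunt."""

    radial_width_um: float
    longitudinal_length_um: float
    area_um2: float
    area_mm2: float

    @property
    def area_cm2(self) -> float:
        return self.area_mm2 / MM2_PER_CM2


def compute_partition_areas(table: HalfTurnTable,
                            partition: Literal["RM", "OC"]) -> BarrierAreas:
    """Trapezoidal per-segment areas of one barrier partition.

    Half-turns I..VII use the trapezoid ``l_i * (w_i + w_{i+1}) / 2``;
    the hook region and half-turn VIII, which lack a basal/apical
    neighbour, use rectangles ``l_h * w_I`` and ``l_VIII * w_VIII``.
    Areas are reported in mm**2.
    """
    w = table.widths(partition)
    l = table.l_um
    areas_um2 = [l[0] * w[0]]                                   # hook rectangle
    for i in range(7):                                          # half-turns I..VII
        areas_um2.append(l[i + 1] * (w[i] + w[i + 1]) / 2.0)
    areas_um2.append(l[8] * w[7])                               # apical rectangle
    per_segment = tuple(a / UM2_PER_MM2 for a in areas_um2)
    return BarrierAreas(partition=partition, labels=SEGMENT_LABELS,
                        per_segment_mm2=per_segment)


def summarize_replicates(values: Iterable[float]) -> ReplicateSet:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    sd is ``None`` for a single replicate.
    """
    vals = tuple(float(v) for v in values)
    n = len(vals)
    if n == 0:
        raise ValidationError("replicate set is empty")
    mean = sum(vals) / n
    if n >= 2:
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    else:
        sd = None
    return ReplicateSet(values=vals, n=n, mean=mean, sd=sd)


def compute_shunt_area(radial_width_um: float,
                       longitudinal_length_um: float) -> ShuntMembraneArea:
    """Rectangular shunt membrane area: radial width x longitudinal length."""
    if not (radial_width_um > 0):
        raise ValidationError(
            f"radial width must be positive, got {radial_width_um}")
    if not (longitudinal_length_um > 0):
        raise ValidationError(
            f"longitudinal length must be positive, got {longitudinal_length_um}")
    area_um2 = radial_width_um * longitudinal_length_um
    return ShuntMembraneArea(
        radial_width_um=radial_width_um,
        longitudinal_length_um=longitudinal_length_um,
        area_um2=area_um2,
        area_mm2=area_um2 / UM2_PER_MM2,
    )


def _table_from_frame(df: pd.DataFrame) -> HalfTurnTable:
    required = {"label", "w_RM_um", "w_OC_um", "l_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"half-turn CSV is missing column(s): {sorted(missing)}")
    df = df.set_index("label")
    for label in SEGMENT_LABELS:
        if label not in df.index:
            raise ValidationError(f"half-turn table is missing segment: {label}")
    df = df.loc[list(SEGMENT_LABELS)]
    w_rm = tuple(float(x) for x in df["w_RM_um"].iloc[1:])
    w_oc = tuple(float(x) for x in df["w_OC_um"].iloc[1:])
    l_um = tuple(float(x) for x in df["l_um"])
    return HalfTurnTable(labels=SEGMENT_LABELS, w_rm_um=w_rm, w_oc_um=w_oc, l_um=l_um)


def load_half_turn_table(path) -> HalfTurnTable:
    """Read a half-turn width/length table from CSV.

    Expected columns: segment,label,w_RM_um,w_OC_um,l_um.  The hook row
    carries no width (empty cells allowed).
    """
    df = pd.read_csv(path)
    return _table_from_frame(df)


def default_half_turn_table() -> HalfTurnTable:
    """Packaged guinea-pig fixture table.

    The widths follow a smooth base-to-apex trend and are calibrated so
    the partition totals equal 11.46 mm**2 (RM) and 9.78 mm**2 (OC).
    This is a fixture approximating published figure-panel measurements,
    not digitised source data.
    """
    ref = importlib.resources.files("cochperm.data") / "guinea_pig_half_turns.csv"
    with importlib.resources.as_file(ref) as path:
        return load_half_turn_table(path)


def table_to_frame(table: HalfTurnTable) -> pd.DataFrame:
    """Serialize a table back to the CSV dialect of ``load_half_turn_table``."""
    rows = []
    for i, label in enumerate(SEGMENT_LABELS):
        rows.append({
            "segment": i,
            "label": label,
            "w_RM_um": "" if label == "hook" else table.w_rm_um[i - 1],
            "w_OC_um": "" if label == "hook" else table.w_oc_um[i - 1],
            "l_um": table.l_um[i],
        })
    return pd.DataFrame(rows)


def areas_report(table: HalfTurnTable) -> dict:
    """JSON-ready report with both partitions and the combined total."""
    rm = compute_partition_areas(table, "RM")
    oc = compute_partition_areas(table, "OC")
    return {
        "per_segment": [
            {"segment": s, "A_RM_mm2": a, "A_OC_mm2": b}
            for s, a, b in zip(SEGMENT_LABELS, rm.per_segment_mm2, oc.per_segment_mm2)
        ],
        "totals": {
            "A_SV_SM_mm2": rm.total_mm2,
            "A_ST_SM_mm2": oc.total_mm2,
            "A_total_mm2": rm.total_mm2 + oc.total_mm2,
        },
    }


def dump_areas_report(table: HalfTurnTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(areas_report(table), fh, indent=2)
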