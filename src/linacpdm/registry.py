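"""Schema of the monitored accelerator parameters.

A modern digital linac writes two log files for every delivery of the daily
QA treatment: a *text log* — one snapshot of 45 operating values (voltages,
currents, temperatures, pressures) taken at beam-on — and a *trajectory log*
— 131 axis positions sampled every 20 ms throughout the arc.  Monitoring
works on 525 derived parameters:

* 35 of the 45 text values (the remainder are recorded for context only);
* 490 trajectory-derived metrics over the 127 monitored axes (the four couch
  axes are recorded but excluded): each of the 120 MLC leaves contributes two
  segment speeds and two cross-correlation fidelity metrics (480 values), the
  two leaf carriages and four jaws contribute a position each, and the gantry
  contributes two segment speeds plus the two cross-correlation metrics.

Of the 490 trajectory parameters, 482 are MLC-related (480 leaf metrics plus
the 2 carriage positions).

Every parameter carries an :class:`SpRule`, the specification-derived
inflation applied on top of the classical 3-sigma Individuals/Moving-Range
limits (see :mod:`linacpdm.spc`): up to 10 % of the manufacturer operating
range, up to 1 % of a published QC value/range, or an empirically chosen
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

from . import _defaults as d
from .errors import ValidationError

SpBasis = Literal["operating_range", "qc_published", "empirical"]
Source = Literal["text", "trajectory"]
Metric = Literal[
    "raw_value",
    "position",
    "speed_segment_1",
    "speed_segment_2",
    "cc_max_value",
    "cc_max_location",
]

_FRACTION_CAP = {"operating_range": 0.10, "qc_published": 0.01, "empirical": 1.0}

TRAJECTORY_METRICS: tuple[Metric, ...] = (
    "speed_segment_1",
    "speed_segment_2",
    "cc_max_value",
    "cc_max_location",
)


@dataclass(frozen=True)
class SpRule:
    """Hybrid-limit inflation rule: S_p = reference_value * fraction.

    ``basis`` caps the admissible fraction: at most 10 % of an operating
    range, at most 1 % of a published QC value; an empirical rule uses the
    reference value directly (fraction 1).
    """

    basis: SpBasis
    reference_value: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        cap = _FRACTION_CAP.get(self.basis)
        if cap is None:
            raise ValidationError(f"unknown Sp basis {self.basis!r}")
        if not 0.0 <= self.fraction <= cap:
            raise ValidationError(
                f"Sp fraction {self.fraction} outside [0, {cap}] for basis {self.basis!r}"
            )
        if self.reference_value < 0:
            raise ValidationError("Sp reference_value must be >= 0")


def sp_value(rule: SpRule) -> float:
    """Resolve an :class:`SpRule` to its scalar S_p (parameter units, >= 0)."""
    return rule.reference_value * rule.fraction


@dataclass(frozen=True)
class ParameterDescriptor:
    """One monitored parameter: where it comes from and how it is limited."""

    id: str
    name: str
    source: Source
    group: str
    metric: Metric
    units: str
    sp_rule: SpRule
    axis: str | None = None
    mlc_related: bool = False

    def __post_init__(self) -> None:
        if self.source == "text":
            if self.metric != "raw_value":
                raise ValidationError(f"{self.id}: text parameters must be raw_value")
            if self.axis is not None:
                raise ValidationError(f"{self.id}: text parameters carry no axis")
        else:
            if self.metric == "raw_value":
                raise ValidationError(f"{self.id}: trajectory parameters need a metric")
            if self.axis is None:
                raise ValidationError(f"{self.id}: trajectory parameters need an axis")


@dataclass(frozen=True)
class ParameterRegistry:
    """Ordered collection of descriptors plus the nine operational groups."""

    descriptors: tuple[ParameterDescriptor, ...]
    groups: tuple[str, ...] = d.GROUPS

    def __post_init__(self) -> None:
        ids = [p.id for p in self.descriptors]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate parameter ids: {dup}")
        unknown = {p.group for p in self.descriptors} - set(self.groups)
        if unknown:
            raise ValidationError(f"descriptors reference unknown groups: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self) -> Iterator[ParameterDescriptor]:
        return iter(self.descriptors)

    def __getitem__(self, parameter_id: str) -> ParameterDescriptor:
        try:
            return self._by_id[parameter_id]
        except KeyError:
            raise KeyError(f"unknown parameter id {parameter_id!r}") from None

    def __contains__(self, parameter_id: str) -> bool:
        return parameter_id in self._by_id

    @property
    def _by_id(self) -> dict[str, ParameterDescriptor]:
        # cached lazily on the instance despite frozen dataclass
        cache = self.__dict__.get("_by_id_cache")
        if cache is None:
            cache = {p.id: p for p in self.descriptors}
            object.__setattr__(self, "_by_id_cache", cache)
        return cache

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.descriptors)

    def by_source(self, source: Source) -> tuple[ParameterDescriptor, ...]:
        return tuple(p for p in self.descriptors if p.source == source)

    def by_group(self, group: str) -> tuple[ParameterDescriptor, ...]:
        return tuple(p for p in self.descriptors if p.group == group)

    def by_axis(self, axis: str) -> tuple[ParameterDescriptor, ...]:
        return tuple(p for p in self.descriptors if p.axis == axis)

    @property
    def monitored_axes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.descriptors:
            if p.axis is not None:
                seen.setdefault(p.axis, None)
        return tuple(seen)

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in self.groups}
        for p in self.descriptors:
            counts[p.group] += 1
        return counts

    # -- serialization ----------------------------------------------------

    def to_config(self) -> list[dict]:
        """Registry as a plain structure (one mapping per descriptor)."""
        out = []
        for p in self.descriptors:
            out.append(
                {
                    "id": p.id,
                    "name": p.name,
                    "source": p.source,
                    "group": p.group,
                    "axis": p.axis,
                    "metric": p.metric,
                    "units": p.units,
                    "mlc_related": p.mlc_related,
                    "sp": {
                        "basis": p.sp_rule.basis,
                        "reference_value": p.sp_rule.reference_value,
                        "fraction": p.sp_rule.fraction,
                    },
                }
            )
        return out

    @classmethod
    def from_config(cls, entries: list[dict]) -> "ParameterRegistry":
        descriptors = []
        for e in entries:
            sp = e["sp"]
            descriptors.append(
                ParameterDescriptor(
                    id=e["id"],
                    name=e["name"],
                    source=e["source"],
                    group=e["group"],
                    axis=e.get("axis"),
                    metric=e["metric"],
                    units=e["units"],
                    mlc_related=bool(e.get("mlc_related", False)),
                    sp_rule=SpRule(sp["basis"], sp["reference_value"], sp["fraction"]),
                )
            )
        return cls(descriptors=tuple(descriptors))


def _trajectory_descriptor(axis: str, metric: Metric, units: str, group: str,
                           sp: tuple[str, float, float], mlc: bool,
                           label: str) -> ParameterDescriptor:
    basis, ref, frac = sp
    return ParameterDescriptor(
        id=f"{axis}/{metric}",
        name=label,
        source="trajectory",
        group=group,
        axis=axis,
        metric=metric,
        units=units,
        sp_rule=SpRule(basis, ref, frac),  # type: ignore[arg-type]
        mlc_related=mlc,
    )


def build_default_registry() -> ParameterRegistry:
    """The default 525-parameter registry (35 text + 490 trajectory).

    Construction is deterministic: two calls yield identical ordered
    descriptor tuples.
    """
    descriptors: list[ParameterDescriptor] = []

    for (pid, name, units, group, _nom, _sig,
         basis, ref, frac, _emode, _elevel, _edesc) in d.TEXT_PARAMETERS:
        descriptors.append(
            ParameterDescriptor(
                id=pid,
                name=name,
                source="text",
                group=group,
                metric="raw_value",
                units=units,
                sp_rule=SpRule(basis, ref, frac),  # type: ignore[arg-type]
            )
        )

    for axis in d.JAW_AXES:
        label = f"Jaw {axis.split('_')[1].upper()} Position"
        descriptors.append(_trajectory_descriptor(
            axis, "position", "cm", d.GROUP_COLL, d.SP_JAW_POSITION, False, label))
    for axis in d.CARRIAGE_AXES:
        label = f"Carriage {axis.split('_')[1].upper()} Position"
        descriptors.append(_trajectory_descriptor(
            axis, "position", "cm", d.GROUP_COLL, d.SP_CARRIAGE_POSITION, True, label))

    gantry_meta = {
        "speed_segment_1": ("deg/s", d.SP_GANTRY_SPEED, "Gantry Speed 1"),
        "speed_segment_2": ("deg/s", d.SP_GANTRY_SPEED, "Gantry Speed 2"),
        "cc_max_value": ("", d.SP_GANTRY_CC_VALUE, "Gantry CC Max Value"),
        "cc_max_location": ("snapshots", d.SP_GANTRY_CC_LOCATION, "Gantry CC Max Location"),
    }
    for metric, (units, sp, label) in gantry_meta.items():
        descriptors.append(_trajectory_descriptor(
            d.GANTRY_AXIS, metric, units, d.GROUP_GANTRY, sp, False, label))  # type: ignore[arg-type]

    leaf_meta = {
        "speed_segment_1": ("cm/s", d.SP_MLC_SPEED, "Speed 1"),
        "speed_segment_2": ("cm/s", d.SP_MLC_SPEED, "Speed 2"),
        "cc_max_value": ("", d.SP_MLC_CC_VALUE, "CC Max Value"),
        "cc_max_location": ("snapshots", d.SP_MLC_CC_LOCATION, "CC Max Location"),
    }
    for axis in d.MLC_AXES:
        bank = "A" if axis in d.MLC_AXES_A else "B"
        leaf = int(axis[-2:])
        for metric, (units, sp, label) in leaf_meta.items():
            descriptors.append(_trajectory_descriptor(
                axis, metric, units, d.GROUP_MLC, sp, True,  # type: ignore[arg-type]
                f"MLC Bank {bank} Leaf {leaf:02d} {label}"))

    return ParameterRegistry(descriptors=tuple(descriptors))
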