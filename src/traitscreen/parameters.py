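"""Screened factor space: parameter registry, variation ranges, virtual genotypes.

A crop-model parameter is either a single scalar or a "function" parameter —
a piecewise-linear curve stored as paired x/y vectors (x drives a state
variable such as development stage, y carries the trait value).  The screen
perturbs every parameter within a fixed 40%-wide band around its nominal
value for the reference cultivar (Hartog): symmetric +/-20% where possible,
one-sided when a hard bound (e.g. a fraction capped at 1) would be violated.

Some parameters cannot vary independently without producing aberrant
physiology (e.g. a minimum threshold overtaking a maximum); these are tied
into *meta-parameters* that move all members together, so the number of
independent Morris factors is

    n_factors = n_parameters - n_grouped_members + n_groups.

A normalized level in [0, 1] maps linearly onto each factor's variation
range; level 0.5 recovers the nominal value for symmetric ranges.  One
sampled level vector, materialized into concrete parameter values, is a
*virtual genotype*.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Curve",
    "ParameterDef",
    "VariationRange",
    "Registry",
    "VirtualGenotype",
    "apply_range_rule",
    "scale_curve",
    "materialize_genotype",
    "count_factors",
    "load_registry",
    "save_registry",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Curve:
    """Piecewise-linear function parameter: paired x/y vectors, x strictly increasing."""

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("curve x and y vectors must have equal length")
        if len(self.x) < 2:
            raise ValueError("curve needs at least two points")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("curve x vector must be strictly increasing")

    def __call__(self, xq: float) -> float:
        return float(np.interp(xq, self.x, self.y))


@dataclass(frozen=True)
class VariationRange:
    """Tested interval for one scalar quantity.

    ``one_sided`` records whether the 40% band was shifted to respect a hard
    bound: ``"below"`` places the whole band under the nominal, ``"above"``
    over it, ``"none"`` is the symmetric +/-20% case.  A ``fixed`` range has
    zero width (nominal value 0 cannot be scaled multiplicatively) and the
    parameter drops out of the factor set.
    """

    lower: float
    upper: float
    one_sided: str = "none"  # none | below | above
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper + _EPS:
            raise ValueError(f"range lower {self.lower} exceeds upper {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def value_at(self, level: float) -> float:
        """Concrete value at a normalized level in [0, 1]."""
        if not 0.0 - _EPS <= level <= 1.0 + _EPS:
            raise ValueError(f"level {level} outside [0, 1]")
        return self.lower + level * (self.upper - self.lower)

    def level_of(self, value: float) -> float:
        """Inverse of :meth:`value_at`; undefined for fixed ranges."""
        if self.fixed or self.width == 0.0:
            raise ValueError("cannot renormalize against a zero-width range")
        return (value - self.lower) / (self.upper - self.lower)


def apply_range_rule(
    nominal: float,
    hard_lower: float | None = None,
    hard_upper: float | None = None,
) -> VariationRange:
    """Map a nominal value to its tested variation range.

    The default band is multiplicative and symmetric, [0.8, 1.2] x nominal
    (total width 40% of the nominal magnitude).  If the symmetric band would
    cross a hard bound, the full 40% width is placed on the feasible side of
    the nominal instead, then clipped to the bounds.  A zero nominal yields a
    zero-width "fixed" range rather than a divide-by-zero.
    """
    if not np.isfinite(nominal):
        raise ValueError("nominal must be finite")
    if nominal == 0.0:
        return VariationRange(0.0, 0.0, fixed=True)

    mag = abs(nominal)
    lower = nominal - 0.2 * mag
    upper = nominal + 0.2 * mag
    one_sided = "none"

    if hard_upper is not None and upper > hard_upper + _EPS:
        lower, upper, one_sided = nominal - 0.4 * mag, nominal, "below"
    elif hard_lower is not None and lower < hard_lower - _EPS:
        lower, upper, one_sided = nominal, nominal + 0.4 * mag, "above"

    if hard_lower is not None:
        lower = max(lower, hard_lower)
    if hard_upper is not None:
        upper = min(upper, hard_upper)
    return VariationRange(lower, upper, one_sided=one_sided)


@dataclass(frozen=True)
class ParameterDef:
    """One named model input: scalar or curve, with its screening metadata.

    ``scaling_mode`` is ``"full"`` (scale the single value, or every y entry
    of a curve) or ``"point"`` (scale one designated x- or y-entry of a
    curve, used where perturbing a single threshold is the biologically
    meaningful variation).  ``group`` ties the parameter to a meta-parameter
    factor; ``active`` marks whether the surrogate simulator consumes it —
    inactive entries are screened like any other factor and serve as
    known-inert controls.
    """

    name: str
    kind: str  # scalar | curve
    nominal: float | Curve
    units: str = ""
    hard_lower: float | None = None
    hard_upper: float | None = None
    scaling_mode: str = "full"  # full | point
    point_axis: str | None = None  # x | y
    point_index: int | None = None
    group: str | None = None
    process: str = ""
    active: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("scalar", "curve"):
            raise ValueError(f"{self.name}: kind must be scalar or curve")
        if self.kind == "scalar" and not isinstance(self.nominal, (int, float)):
            raise ValueError(f"{self.name}: scalar parameter needs numeric nominal")
        if self.kind == "curve" and not isinstance(self.nominal, Curve):
            raise ValueError(f"{self.name}: curve parameter needs Curve nominal")
        if self.scaling_mode not in ("full", "point"):
            raise ValueError(f"{self.name}: scaling_mode must be full or point")
        if self.scaling_mode == "point":
            if self.kind != "curve":
                raise ValueError(f"{self.name}: point scaling only applies to curves")
            if self.point_axis not in ("x", "y"):
                raise ValueError(f"{self.name}: point scaling needs axis x or y")
            n = len(self.nominal.x)
            if self.point_index is None or not 0 <= self.point_index < n:
                raise ValueError(f"{self.name}: point_index out of range")
        if self.kind == "scalar":
            v = float(self.nominal)
            if self.hard_lower is not None and v < self.hard_lower - _EPS:
                raise ValueError(f"{self.name}: nominal below hard_lower")
            if self.hard_upper is not None and v > self.hard_upper + _EPS:
                raise ValueError(f"{self.name}: nominal above hard_upper")

    def scalar_range(self) -> VariationRange:
        if self.kind != "scalar":
            raise ValueError(f"{self.name} is not scalar")
        return apply_range_rule(float(self.nominal), self.hard_lower, self.hard_upper)

    def _scaled_entry_nominal(self) -> float:
        """Nominal value of the entry that point-scaling perturbs."""
        assert isinstance(self.nominal, Curve)
        vec = self.nominal.x if self.point_axis == "x" else self.nominal.y
        return vec[self.point_index]  # type: ignore[index]

    def factor_range(self) -> VariationRange:
        """Range of the scalar quantity that this parameter's factor moves.

        Full-curve scaling moves a dimensionless multiplier (nominal 1.0);
        point scaling moves the designated entry itself.
        """
        if self.kind == "scalar":
            return self.scalar_range()
        if self.scaling_mode == "full":
            hi = self.hard_upper
            lo = self.hard_lower
            ymax = max(self.nominal.y)  # type: ignore[union-attr]
            ymin = min(self.nominal.y)  # type: ignore[union-attr]
            # bounds apply to the scaled y values, translate to the multiplier
            if hi is not None and ymax * 1.2 > hi + _EPS and ymax > 0:
                return VariationRange(0.6, 1.0, one_sided="below")
            if lo is not None and ymin * 0.8 < lo - _EPS and ymin > 0:
                return VariationRange(1.0, 1.4, one_sided="above")
            return VariationRange(0.8, 1.2)
        return apply_range_rule(self._scaled_entry_nominal(), self.hard_lower, self.hard_upper)

    def is_fixed(self) -> bool:
        return self.factor_range().fixed


def scale_curve(param: ParameterDef, level: float) -> Curve:
    """Perturb a curve parameter to a normalized level in [0, 1].

    Full mode multiplies every y entry by the factor interpolated across the
    parameter's multiplier range (0.8 at level 0, 1.2 at level 1 in the
    symmetric case).  Point mode rescales only the designated x- or y-entry;
    an x perturbation that would break the strict ordering of the x vector
    is rejected rather than silently re-sorted.
    """
    if param.kind != "curve":
        raise ValueError(f"{param.name} is not a curve parameter")
    if not 0.0 - _EPS <= level <= 1.0 + _EPS:
        raise ValueError(f"{param.name}: level {level} outside [0, 1]")
    nominal: Curve = param.nominal  # type: ignore[assignment]
    rng = param.factor_range()
    value = rng.value_at(float(np.clip(level, 0.0, 1.0)))

    if param.scaling_mode == "full":
        return Curve(nominal.x, tuple(yi * value for yi in nominal.y))

    i = param.point_index
    if param.point_axis == "y":
        y = list(nominal.y)
        y[i] = value
        return Curve(nominal.x, tuple(y))
    x = list(nominal.x)
    x[i] = value
    if any(b <= a for a, b in zip(x, x[1:])):
        raise ValueError(
            f"{param.name}: scaling x[{i}] to {value:g} breaks strict x ordering"
        )
    return Curve(tuple(x), nominal.y)


@dataclass
class Registry:
    """Ordered parameter inventory with meta-parameter groups.

    Factor order is registry order, with each group appearing once at the
    position of its first member.  Parameters whose range collapses to zero
    width (zero nominal) are excluded from the factor set.
    """

    parameters: list[ParameterDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dup}")

    def __len__(self) -> int:
        return len(self.parameters)

    def __iter__(self):
        return iter(self.parameters)

    def __getitem__(self, name: str) -> ParameterDef:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p in self.parameters:
            if p.group is not None:
                out.setdefault(p.group, []).append(p.name)
        return out

    def factor_names(self) -> list[str]:
        """Independent factor ids: parameter names, groups collapsed to one id."""
        seen: set[str] = set()
        out: list[str] = []
        for p in self.parameters:
            if p.is_fixed():
                continue
            key = p.group if p.group is not None else p.name
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def subset(self, names: Iterable[str]) -> "Registry":
        """Registry restricted to the given parameter names (order preserved)."""
        wanted = set(names)
        missing = wanted - {p.name for p in self.parameters}
        if missing:
            raise KeyError(f"unknown parameters: {sorted(missing)}")
        return Registry([p for p in self.parameters if p.name in wanted])


def count_factors(registry: Registry) -> int:
    """Number of independent Morris factors: p - grouped members + groups."""
    return len(registry.factor_names())


@dataclass(frozen=True)
class VirtualGenotype:
    """One sampled point of the factor space, materialized to concrete values."""

    levels: Mapping[str, float]  # factor id -> normalized level
    values: Mapping[str, float | Curve]  # parameter name -> concrete value


def materialize_genotype(
    registry: Registry, levels: Sequence[float] | Mapping[str, float]
) -> VirtualGenotype:
    """Turn a normalized level vector into a concrete virtual genotype.

    ``levels`` is either a mapping factor-id -> level or a sequence in
    :meth:`Registry.factor_names` order.  Every member of a meta-parameter
    group receives the group's level, applied to its own variation range.
    """
    factor_ids = registry.factor_names()
    if isinstance(levels, Mapping):
        unknown = set(levels) - set(factor_ids)
        if unknown:
            raise KeyError(f"unknown factors: {sorted(unknown)}")
        missing = set(factor_ids) - set(levels)
        if missing:
            raise KeyError(f"missing factor levels: {sorted(missing)}")
        level_map = dict(levels)
    else:
        if len(levels) != len(factor_ids):
            raise ValueError(
                f"expected {len(factor_ids)} levels, got {len(levels)}"
            )
        level_map = dict(zip(factor_ids, levels))
    for fid, lv in level_map.items():
        if not 0.0 - _EPS <= lv <= 1.0 + _EPS:
            raise ValueError(f"factor {fid}: level {lv} outside [0, 1]")

    values: dict[str, float | Curve] = {}
    for p in registry:
        if p.is_fixed():
            values[p.name] = p.nominal
            continue
        lv = level_map[p.group if p.group is not None else p.name]
        if p.kind == "scalar":
            values[p.name] = p.scalar_range().value_at(lv)
        else:
            values[p.name] = scale_curve(p, lv)
    return VirtualGenotype(levels=level_map, values=values)


# ---------------------------------------------------------------------------
# registry file I/O (one flat table; curves serialized as "x1;x2|y1;y2")

_COLUMNS = [
    "name", "kind", "nominal", "units", "hard_lower", "hard_upper",
    "scaling_mode", "point_axis", "point_index", "group", "process", "active",
]


def _serialize_nominal(p: ParameterDef) -> str:
    if p.kind == "scalar":
        return repr(float(p.nominal))
    c: Curve = p.nominal  # type: ignore[assignment]
    return ";".join(repr(v) for v in c.x) + "|" + ";".join(repr(v) for v in c.y)


def _parse_nominal(kind: str, text: str) -> float | Curve:
    if kind == "scalar":
        return float(text)
    xs, ys = text.split("|")
    return Curve(
        tuple(float(v) for v in xs.split(";")),
        tuple(float(v) for v in ys.split(";")),
    )


def save_registry(registry: Registry, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for p in registry:
            w.writerow([
                p.name, p.kind, _serialize_nominal(p), p.units,
                "" if p.hard_lower is None else repr(p.hard_lower),
                "" if p.hard_upper is None else repr(p.hard_upper),
                p.scaling_mode, p.point_axis or "",
                "" if p.point_index is None else p.point_index,
                p.group or "", p.process, int(p.active),
            ])


def load_registry(path) -> Registry:
    params: list[ParameterDef] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            params.append(ParameterDef(
                name=row["name"],
                kind=row["kind"],
                nominal=_parse_nominal(row["kind"], row["nominal"]),
                units=row["units"],
                hard_lower=float(row["hard_lower"]) if row["hard_lower"] else None,
                hard_upper=float(row["hard_upper"]) if row["hard_upper"] else None,
                scaling_mode=row["scaling_mode"],
                point_axis=row["point_axis"] or None,
                point_index=int(row["point_index"]) if row["point_index"] else None,
                group=row["group"] or None,
                process=row["process"],
                active=bool(int(row["active"])),
            ))
    return Registry(params)
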