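"""Parameter space of the *Pantoea* individual-based model.

Thirteen parameters define a run.  Seven are *active* — varied across a
simulation campaign — and six are *fixed* at literature / experiment-derived
values.  Active parameters live on discrete grids (a range plus an
increment); the campaign sampler draws uniformly and independently from
those grids.

Active: ``umax_pa`` (maximum specific growth rate, h⁻¹), ``steptime``
(minutes of simulated time per tick), ``diffusion_coefficient`` (fraction of
a patch's nutrient mass redistributed per tick), ``pmax`` (cell capacity per
patch), ``glucose`` (initial glucose, mM), ``depth`` (medium depth, μm) and
``microorganism`` (initial cell count).

Fixed: ``efficiency`` (biomass yield of post-maintenance carbon, 0.37),
``energy_maintenance_pa`` (0.0015 gC_glucose·gC_biomass⁻¹·h⁻¹), ``rep_pa``
(minimum inter-division time, 20 min), ``max_time_viability_pa`` (maximum
survivable starvation, 83 min), ``ammonium`` (18.7 mM) and
``total_length_world`` (605 μm).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "ParameterValidationError",
    "ACTIVE_PARAMETERS",
    "FIXED_PARAMETERS",
    "CAMPAIGN_STEPTIMES",
    "validate_parameters",
    "sample_configurations",
    "load_parameter_file",
    "configurations_to_frame",
]

#: the four tick lengths (minutes) used in a sweep campaign
CAMPAIGN_STEPTIMES: tuple[float, ...] = (0.1, 0.6, 1.1, 1.6)


@dataclass(frozen=True)
class ParameterSet:
    """One complete assignment of the 13 model parameters."""

    # fixed (defaults are the standard values)
    efficiency: float = 0.37
    energy_maintenance_pa: float = 0.0015
    rep_pa: float = 20.0
    max_time_viability_pa: float = 83.0
    ammonium: float = 18.7
    total_length_world: float = 605.0
    # active (defaults: mid-range single-run values)
    umax_pa: float = 5.0
    steptime: float = 0.6
    diffusion_coefficient: float = 0.5
    pmax: int = 5
    glucose: float = 50.0
    depth: float = 30.0
    microorganism: int = 100

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def active_values(self) -> dict:
        return {name: getattr(self, name) for name in ACTIVE_PARAMETERS}


class ParameterValidationError(ValueError):
    """A parameter is outside its allowed range or off its increment grid."""


@dataclass(frozen=True)
class _GridSpec:
    low: float
    high: float
    step: float
    integer: bool = False

    def grid(self) -> np.ndarray:
        n = int(round((self.high - self.low) / self.step)) + 1
        vals = self.low + self.step * np.arange(n)
        return np.round(vals, 10)

    def contains(self, x: float) -> bool:
        if not (self.low - 1e-9 <= x <= self.high + 1e-9):
            return False
        k = (x - self.low) / self.step
        return abs(k - round(k)) < 1e-6


#: active-parameter grids: range [low, high] with the stated increment
ACTIVE_PARAMETERS: dict[str, _GridSpec] = {
    "pmax": _GridSpec(1, 10, 1, integer=True),
    "microorganism": _GridSpec(10, 1000, 1, integer=True),
    "depth": _GridSpec(10, 50, 1),
    "umax_pa": _GridSpec(0.1, 10.0, 0.1),
    "diffusion_coefficient": _GridSpec(0.0, 1.0, 0.01),
    "glucose": _GridSpec(0.0, 100.0, 0.1),
    # steptime is special-cased: campaign sampling uses CAMPAIGN_STEPTIMES,
    # validation accepts any value in (0, 2]
    "steptime": _GridSpec(0.1, 2.0, 0.5),
}

FIXED_PARAMETERS: dict[str, float] = {
    "efficiency": 0.37,
    "energy_maintenance_pa": 0.0015,
    "rep_pa": 20.0,
    "max_time_viability_pa": 83.0,
    "ammonium": 18.7,
    "total_length_world": 605.0,
}


def validate_parameters(p: ParameterSet) -> ParameterSet:
    """Check every field against its allowed range and increment grid.

    Returns ``p`` unchanged when valid; raises
    :class:`ParameterValidationError` naming the offending field otherwise.
    Range checks use closed intervals.  ``umax_pa`` is accepted down to 0 so
    that degenerate no-growth runs remain expressible, and ``steptime`` may
    be any value in (0, 2] for single runs.
    """
    for name, value in p.as_dict().items():
        if not isinstance(value, (int, float)) or not math.isfinite(value):
            raise ParameterValidationError(f"{name} must be finite and numeric, got {value!r}")

    if not (0.0 <= p.umax_pa <= 10.0):
        raise ParameterValidationError(
            f"umax_pa={p.umax_pa} outside [0, 10] h^-1 (sampling grid is 0.1-10 [0.1])"
        )
    if p.umax_pa > 0 and not (
        ACTIVE_PARAMETERS["umax_pa"].contains(p.umax_pa) or _on_grid(p.umax_pa, 0.0, 0.1)
    ):
        raise ParameterValidationError(f"umax_pa={p.umax_pa} not on the 0.1 h^-1 increment grid")

    if not (0.0 < p.steptime <= 2.0):
        raise ParameterValidationError(f"steptime={p.steptime} outside (0, 2] min")

    for name in ("pmax", "microorganism", "depth", "diffusion_coefficient", "glucose"):
        spec = ACTIVE_PARAMETERS[name]
        value = getattr(p, name)
        if not spec.contains(value):
            raise ParameterValidationError(
                f"{name}={value} outside {spec.low}-{spec.high} "
                f"[increment {spec.step}]"
            )

    for name, default in FIXED_PARAMETERS.items():
        value = getattr(p, name)
        if value < 0:
            raise ParameterValidationError(f"{name}={value} must be non-negative")
    return p


def _on_grid(x: float, low: float, step: float) -> bool:
    k = (x - low) / step
    return abs(k - round(k)) < 1e-6


def sample_configurations(n: int, seed: int) -> list[ParameterSet]:
    """Draw ``n`` distinct parameter sets for a sweep campaign.

    Each active parameter is drawn uniformly and independently from its
    increment grid; ``steptime`` is drawn uniformly from the four campaign
    values.  Fixed parameters keep their standard values.  Duplicates are
    resampled so all ``n`` configurations differ.  The same ``(n, seed)``
    always yields the same list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grids = {
        name: spec.grid()
        for name, spec in ACTIVE_PARAMETERS.items()
        if name != "steptime"
    }
    n_points = np.prod(
        [len(g) for g in grids.values()], dtype=float
    ) * len(CAMPAIGN_STEPTIMES)
    if n > n_points:
        raise ValueError(f"n={n} exceeds the {int(n_points)} distinct grid points")

    rng = np.random.default_rng(seed)
    seen: set[tuple] = set()
    out: list[ParameterSet] = []
    while len(out) < n:
        draw = {name: g[rng.integers(len(g))] for name, g in grids.items()}
        draw["steptime"] = CAMPAIGN_STEPTIMES[rng.integers(len(CAMPAIGN_STEPTIMES))]
        key = tuple(sorted((k, float(v)) for k, v in draw.items()))
        if key in seen:
            continue
        seen.add(key)
        out.append(
            ParameterSet(
                umax_pa=float(draw["umax_pa"]),
                steptime=float(draw["steptime"]),
                diffusion_coefficient=float(draw["diffusion_coefficient"]),
                pmax=int(draw["pmax"]),
                glucose=float(draw["glucose"]),
                depth=float(draw["depth"]),
                microorganism=int(draw["microorganism"]),
            )
        )
    return out


def load_parameter_file(path) -> ParameterSet:
    """Read a key-value (YAML) config whose keys mirror the parameter names.

    Hyphenated aliases (``diffusion-coefficient``, ``total-length-world``,
    ``min/steptime``) are accepted.  Missing keys fall back to defaults; the
    result is validated.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    aliases = {
        "diffusion-coefficient": "diffusion_coefficient",
        "total-length-world": "total_length_world",
        "min/steptime": "steptime",
        "max-time-viability_pa": "max_time_viability_pa",
    }
    fields = {f.name for f in dataclasses.fields(ParameterSet)}
    kwargs = {}
    for key, value in raw.items():
        name = aliases.get(key, str(key).lower())
        if name not in fields:
            raise ParameterValidationError(f"unknown parameter {key!r}")
        kwargs[name] = value
    p = ParameterSet(**kwargs)
    return validate_parameters(p)


def configurations_to_frame(configs: Iterable[ParameterSet]):
    """Tabulate configurations, one row each, with a ``config_id`` column."""
    import pandas as pd

    rows = []
    for i, p in enumerate(configs):
        row = {"config_id": i}
        row.update(p.active_values)
        rows.append(row)
    return pd.DataFrame(rows)
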