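"""Core data model and plumbing for π–A isotherms.

An :class:`Isotherm` is one compression run of a Langmuir film: ordered
(area, pressure) points plus subphase temperature and film composition.
The canonical internal order is *compression order* — area strictly
descending — regardless of how the file was recorded; exact duplicate
areas (barrier jitter) are averaged on construction.

The module also provides

* a plain-text CSV dialect (``#``-prefixed YAML metadata block followed by
  ``area_A2,pressure_mN_m`` columns) with a bit-stable writer,
* Savitzky–Golay pressure smoothing (prerequisite for differentiating
  data recorded with a ±0.01 mN/m Wilhelmy sensor),
* extraction of the pre-collapse branch and shape-preserving monotone
  regridding A(π) used by the excess-thermodynamics integrals.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .errors import ParseError, PressureRangeError, ValidationError

__all__ = [
    "Component",
    "Isotherm",
    "MixtureSeries",
    "load_isotherm",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "isotherm_to_json",
    "isotherm_from_json",
    "smooth_pressure",
    "pre_collapse_branch",
    "monotone_branch",
    "area_at_pressure",
]

#: Roles a film component may play in a (pseudo-)binary analysis.
COMPONENT_ROLES = ("phospholipid", "sphingolipid", "sterol", "pseudo")

#: Most negative surface pressure tolerated as sensor drift (mN/m).
MIN_PRESSURE = -0.5

#: Minimum number of points for a usable compression run.
MIN_POINTS = 10

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Component:
    """A film component, optionally with molecular geometry.

    ``geometry`` is ``(V, a, l_c)``: hydrocarbon-chain volume in Å³,
    head-group area in Å² and critical chain length in Å — the inputs of
    the critical packing parameter.
    """

    component_id: str
    role: str = "phospholipid"
    geometry: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.component_id:
            raise ValueError("component_id must be a non-empty string")
        if self.role not in COMPONENT_ROLES:
            raise ValueError(
                f"role {self.role!r} not one of {COMPONENT_ROLES}"
            )
        if self.geometry is not None:
            v, a, lc = self.geometry
            if not (v > 0 and a > 0 and lc > 0):
                raise ValueError(
                    f"geometry values must be strictly positive, got {self.geometry}"
                )


@dataclass(frozen=True, eq=False)
class Isotherm:
    """One compression run: π(A) plus metadata.

    Parameters
    ----------
    area
        Area per molecule, Å²/molecule. Normalized to strictly
        descending order; exact duplicates are averaged.
    pressure
        Surface pressure, mN/m. Values in [-0.5, 0) are retained as
        sensor drift; anything more negative is rejected.
    temperature
        Subphase temperature, °C.
    components
        Sequence of ``(component_id, mole_fraction)``; fractions must
        sum to 1 within 1e-9.
    provenance
        Free-text metadata (compression rate, subphase, preset name...).
    """

    area: np.ndarray
    pressure: np.ndarray
    temperature: float
    components: tuple[tuple[str, float], ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.area, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        if a.ndim != 1 or p.ndim != 1 or a.size != p.size:
            raise ValidationError("area and pressure must be 1-D and equal length")
        a, p = _normalize(a, p)
        if a.size < MIN_POINTS:
            raise ValidationError(
                f"isotherm has {a.size} points after normalization; "
                f"at least {MIN_POINTS} required"
            )
        if np.any(a <= 0):
            raise ValidationError("areas must be strictly positive")
        if np.any(p < MIN_PRESSURE):
            bad = float(p.min())
            raise ValidationError(
                f"pressure {bad:.3f} mN/m below {MIN_PRESSURE} mN/m drift allowance"
            )
        comps = tuple((str(c), float(x)) for c, x in self.components)
        if not comps:
            raise ValidationError("at least one component required")
        for cid, x in comps:
            if not (0.0 <= x <= 1.0):
                raise ValidationError(
                    f"mole fraction of {cid!r} is {x}, outside [0, 1]"
                )
        total = sum(x for _, x in comps)
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                f"mole fractions sum to {total!r}, not 1 "
                f"(components: {[c for c, _ in comps]})"
            )
        object.__setattr__(self, "area", a)
        object.__setattr__(self, "pressure", p)
        object.__setattr__(self, "temperature", float(self.temperature))
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "provenance", dict(self.provenance))

    # -- convenience -------------------------------------------------
    @property
    def n_points(self) -> int:
        return int(self.area.size)

    @property
    def max_pressure(self) -> float:
        return float(self.pressure.max())

    def composition(self) -> dict[str, float]:
        return dict(self.components)

    def with_pressure(self, pressure: np.ndarray) -> "Isotherm":
        return replace(self, pressure=np.asarray(pressure, dtype=float))


def _normalize(area: np.ndarray, pressure: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort into compression order and average exact duplicate areas.

    Stable sort so locally non-monotone recordings keep their relative
    order before duplicate averaging; idempotent by construction.
    """
    order = np.argsort(-area, kind="stable")
    a, p = area[order], pressure[order]
    uniq, inverse, counts = np.unique(-a, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        p_sum = np.zeros(uniq.size)
        np.add.at(p_sum, inverse, p)
        a = -uniq
        p = p_sum / counts
    return a, p


@dataclass(frozen=True, eq=False)
class MixtureSeries:
    """Isotherms of one (pseudo-)binary pair across mole fractions.

    ``members`` maps x₂ (mole fraction of ``endpoint_2``, by convention
    the sterol) to the corresponding isotherm. Pure endpoints x₂ = 0 and
    x₂ = 1 are mandatory; all members must share the temperature.
    """

    endpoint_1: Component
    endpoint_2: Component
    members: tuple[tuple[float, Isotherm], ...]
    temperature: float

    def __post_init__(self) -> None:
        members = tuple(sorted(((float(x), iso) for x, iso in self.members),
                               key=lambda m: m[0]))
        xs = np.array([x for x, _ in members])
        if np.any((xs < 0) | (xs > 1)):
            raise ValidationError("mole fractions must lie in [0, 1]")
        if xs.size < 2 or np.any(np.diff(xs) <= 0):
            raise ValidationError("compositions must be unique and sorted")
        if abs(xs[0]) > _FRACTION_TOL or abs(xs[-1] - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                "series must include both pure endpoints x2 = 0 and x2 = 1"
            )
        for x, iso in members:
            if abs(iso.temperature - self.temperature) > 1e-6:
                raise ValidationError(
                    f"member x2={x} recorded at {iso.temperature} °C, "
                    f"series temperature is {self.temperature} °C"
                )
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "temperature", float(self.temperature))

    @property
    def compositions(self) -> np.ndarray:
        return np.array([x for x, _ in self.members])

    def member(self, x2: float, tol: float = 1e-9) -> Isotherm:
        for x, iso in self.members:
            if abs(x - x2) <= tol:
                return iso
        raise KeyError(f"no member at x2 = {x2}")


# ---------------------------------------------------------------------------
# file dialect
# ---------------------------------------------------------------------------

_HEADER = "area_A2,pressure_mN_m"


def _metadata_dict(iso: Isotherm) -> dict:
    return {
        "temperature_C": iso.temperature,
        "components": {cid: x for cid, x in iso.components},
        "provenance": dict(iso.provenance),
    }


def write_isotherm_csv(iso: Isotherm, path) -> None:
    """Write the CSV dialect: ``#``-prefixed YAML metadata, then columns.

    Floats are serialized with ``repr`` (shortest round-trip form), so
    write → read → write is bit-identical.
    """
    meta = yaml.safe_dump(_metadata_dict(iso), sort_keys=True).rstrip("\n")
    lines = ["# " + ln for ln in meta.split("\n")]
    lines.append(_HEADER)
    for a, p in zip(iso.area.tolist(), iso.pressure.tolist()):
        lines.append(f"{a!r},{p!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_isotherm_csv(path) -> Isotherm:
    """Read the CSV dialect back into a validated :class:`Isotherm`."""
    with open(path) as fh:
        text = fh.read()
    return _parse_isotherm_text(text, source=str(path))


def load_isotherm(path) -> Isotherm:
    """Alias of :func:`read_isotherm_csv` (spec-facing name)."""
    return read_isotherm_csv(path)


def _parse_isotherm_text(text: str, source: str = "<text>") -> Isotherm:
    meta_lines, data_lines = [], []
    for ln in text.splitlines():
        if ln.startswith("#"):
            meta_lines.append(ln[1:].removeprefix(" "))
        elif ln.strip():
            data_lines.append(ln)
    try:
        meta = yaml.safe_load("\n".join(meta_lines)) or {}
    except yaml.YAMLError as exc:
        raise ParseError(f"{source}: bad metadata block: {exc}") from exc
    if not data_lines or data_lines[0].strip() != _HEADER:
        raise ParseError(
            f"{source}: expected header line {_HEADER!r}, "
            f"got {data_lines[0]!r}" if data_lines else f"{source}: no data"
        )
    try:
        frame = pd.read_csv(
            io.StringIO("\n".join(data_lines)),
            dtype=float,
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise ParseError(f"{source}: non-numeric cell in data table: {exc}") from exc
    if "temperature_C" not in meta:
        raise ValidationError(f"{source}: metadata lacks temperature_C")
    comps = meta.get("components")
    if not comps:
        raise ValidationError(f"{source}: metadata lacks components")
    return Isotherm(
        area=frame["area_A2"].to_numpy(),
        pressure=frame["pressure_mN_m"].to_numpy(),
        temperature=float(meta["temperature_C"]),
        components=tuple(comps.items()),
        provenance=meta.get("provenance") or {},
    )


def isotherm_to_json(iso: Isotherm) -> str:
    """JSON export including metadata; units fixed by the schema."""
    payload = _metadata_dict(iso)
    payload["area_A2"] = iso.area.tolist()
    payload["pressure_mN_m"] = iso.pressure.tolist()
    return json.dumps(payload, sort_keys=True)


def isotherm_from_json(text: str) -> Isotherm:
    payload = json.loads(text)
    return Isotherm(
        area=np.array(payload["area_A2"]),
        pressure=np.array(payload["pressure_mN_m"]),
        temperature=payload["temperature_C"],
        components=tuple(payload["components"].items()),
        provenance=payload.get("provenance") or {},
    )


# ---------------------------------------------------------------------------
# smoothing & regridding
# ---------------------------------------------------------------------------


def smooth_pressure(iso: Isotherm, window: int = 11, polyorder: int = 2) -> Isotherm:
    """Savitzky–Golay smoothing of the pressure channel.

    Local polynomial least squares; areas untouched. Endpoints are
    handled by polynomial extrapolation of the edge fits (scipy's
    ``mode='interp'``). Exactly reproduces data polynomial in the point
    index (hence in area, for evenly spaced areas) of degree ≤ polyorder.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 3 <= window <= iso.n_points:
        raise ValueError(
            f"window must satisfy 3 <= window <= n_points={iso.n_points}, got {window}"
        )
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    smoothed = savgol_filter(iso.pressure, window, polyorder, mode="interp")
    return iso.with_pressure(smoothed)


def pre_collapse_branch(iso: Isotherm) -> tuple[np.ndarray, np.ndarray]:
    """Points up to and including the first attainment of max pressure.

    Post-collapse points are retained on the isotherm but excluded from
    interpolation and integration.
    """
    i_max = int(np.argmax(iso.pressure))
    return iso.area[: i_max + 1], iso.pressure[: i_max + 1]


def monotone_branch(iso: Isotherm) -> tuple[np.ndarray, np.ndarray]:
    """Maximal strictly-increasing-π subsequence of the pre-collapse branch.

    Negative drift pressures are clipped to 0 first. Scanning backwards
    from the pressure maximum keeps, at any flat stretch, the most
    compressed (smallest-area) point, so the gas-phase toe collapses to
    a single node at the lift-off and transition plateaus resolve to
    their condensed side.
    """
    a, p = pre_collapse_branch(iso)
    p = np.clip(p, 0.0, None)
    keep: list[int] = []
    last = np.inf
    for i in range(p.size - 1, -1, -1):
        if p[i] < last:
            keep.append(i)
            last = p[i]
    idx = np.array(keep[::-1])
    return a[idx], p[idx]


def area_at_pressure(iso: Isotherm, grid: Sequence[float] | np.ndarray) -> np.ndarray:
    """Regrid A(π) on the requested pressure grid.

    Shape-preserving (PCHIP) interpolation on the maximal monotone
    pre-collapse branch, so returned areas are non-increasing in π.
    Below the branch's lowest recorded pressure the area is extended
    flat at the lift-off value (the film is in its gas phase there);
    above the branch maximum a :class:`PressureRangeError` names the
    offending grid point.
    """
    grid = np.asarray(grid, dtype=float)
    a, p = monotone_branch(iso)
    if p.size < 2:
        raise PressureRangeError("monotone pre-collapse branch has < 2 points")
    if np.any(grid < 0):
        bad = float(grid[grid < 0][0])
        raise PressureRangeError(f"grid pressure {bad} mN/m is negative")
    p_max = p[-1]
    if np.any(grid > p_max):
        bad = float(grid[grid > p_max][0])
        raise PressureRangeError(
            f"grid pressure {bad} mN/m exceeds branch maximum {p_max:.3f} mN/m"
        )
    interp = PchipInterpolator(p, a, extrapolate=False)
    out = np.empty_like(grid)
    below = grid < p[0]
    out[below] = a[0]
    out[~below] = interp(grid[~below])
    return out


def area_at_pressure_table(iso: Isotherm, grid: Iterable[float]) -> pd.DataFrame:
    """DataFrame variant of :func:`area_at_pressure` for export."""
    grid = np.asarray(list(grid), dtype=float)
    return pd.DataFrame(
        {"pressure_mN_m": grid, "area_A2": area_at_pressure(iso, grid)}
    )
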