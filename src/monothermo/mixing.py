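"""Excess mixing thermodynamics of (pseudo-)binary monolayers.

For a mixed film, deviation from ideal (additive) mixing at a given
surface pressure is the excess area

    A^exc(π, X) = A₁₂(π) − [A₁(π)·X₁ + A₂(π)·X₂],

and its pressure integral scaled by Avogadro's number is the excess
free enthalpy of mixing

    ΔG^exc(π*) = N_A ∫₀^{π*} A^exc dπ   [J/mol],

negative for attractive, film-stabilizing interactions. With areas in
Å²/molecule and pressures in mN/m the unit bridge is exactly
6.02214076 J/mol per Å²·mN/m.

The default reporting pressure is 30 mN/m — via the monolayer–bilayer
correspondence, films at 30–35 mN/m mimic the lateral packing of a
bilayer leaflet — and tables are also emitted on a 5–35 mN/m grid.
Integration is plain trapezoid on a uniform π grid (default step
0.1 mN/m): isotherm data are tabulated, not functional, so adaptive
quadrature would only interpolate noise. The composition of strongest
interaction is reported at measured compositions; a parabolic
refinement is available behind a flag but off by default.

Miscibility is assessed through the collapse-pressure criterion: in a
miscible film the collapse pressure moves with composition, while a
phase-separated film collapses at the pressure of its least stable
pure component regardless of composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import collapse_pressure as _collapse_pressure
from .errors import (
    InsufficientDataError,
    NoCollapseError,
    PressureRangeError,
)
from .isotherm import Component, Isotherm, MixtureSeries, area_at_pressure
from .units import J_PER_MOL_PER_A2_MNM

__all__ = [
    "ExcessTable",
    "CompositionScan",
    "MiscibilityResult",
    "excess_area",
    "excess_area_surface",
    "excess_gibbs_energy",
    "gibbs_composition_scan",
    "as_pseudo_component",
    "miscibility_from_collapse",
    "DEFAULT_PI_TARGET",
    "DEFAULT_PI_GRID",
]

#: Bilayer-equivalent reporting pressure, mN/m.
DEFAULT_PI_TARGET = 30.0

#: Pressure grid for excess-area tables, mN/m.
DEFAULT_PI_GRID = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)

#: |A^exc| below this is reported as sign "0" (Å²/molecule).
SIGN_BAND = 0.05


def excess_area(a12, a1, a2, x1):
    """A^exc = A₁₂ − (A₁X₁ + A₂X₂), element-wise; areas in Å²/molecule."""
    a12 = np.asarray(a12, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if np.any(a12 <= 0) or np.any(a1 <= 0) or np.any(a2 <= 0):
        raise ValueError("molecular areas must be strictly positive")
    if np.any((x1 < 0) | (x1 > 1)):
        raise ValueError("mole fraction x1 must lie in [0, 1]")
    out = a12 - (a1 * x1 + a2 * (1.0 - x1))
    return float(out) if out.ndim == 0 else out


def _sign_label(value: float) -> str:
    if value > SIGN_BAND:
        return "positive"
    if value < -SIGN_BAND:
        return "negative"
    return "zero"


@dataclass(frozen=True, eq=False)
class ExcessTable:
    """A^exc over a (π, X) grid plus ΔG^exc at a reporting pressure."""

    pressures: np.ndarray          # (n_pi,) mN/m
    compositions: np.ndarray       # (n_x,) sterol mole fraction X2
    a_exc: np.ndarray              # (n_pi, n_x) Å²/molecule
    dg_exc: np.ndarray             # (n_x,) J/mol at pi_target
    pi_target: float

    @property
    def signs(self) -> np.ndarray:
        return np.vectorize(_sign_label)(self.a_exc)

    def to_long_frame(self) -> pd.DataFrame:
        """Long form (pi, x, a_exc, sign) for export."""
        pi, x = np.meshgrid(self.pressures, self.compositions, indexing="ij")
        return pd.DataFrame(
            {
                "pi_mN_m": pi.ravel(),
                "x2": x.ravel(),
                "a_exc_A2": self.a_exc.ravel(),
                "sign": self.signs.ravel(),
            }
        )

    def to_bubble_frame(self) -> pd.DataFrame:
        """Bubble-plot-ready columns: radius ∝ |A^exc|, polarity."""
        frame = self.to_long_frame()
        frame["radius"] = frame["a_exc_A2"].abs()
        frame["polarity"] = np.where(frame["a_exc_A2"] >= 0, "bright", "dark")
        return frame.drop(columns=["sign"])

    def dg_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x2": self.compositions, "dg_exc_J_mol": self.dg_exc}
        )


@dataclass(frozen=True, eq=False)
class CompositionScan:
    """ΔG^exc = f(X₂) at one reporting pressure."""

    compositions: np.ndarray
    dg_exc: np.ndarray
    pi_target: float
    refined_argmin: float | None = None

    @property
    def argmin_x(self) -> float:
        return float(self.compositions[int(np.argmin(self.dg_exc))])

    @property
    def min_dg(self) -> float:
        return float(self.dg_exc.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x2": self.compositions, "dg_exc_J_mol": self.dg_exc})

    def summary(self) -> dict:
        return {
            "pi_target_mN_m": self.pi_target,
            "argmin_x2": self.argmin_x,
            "min_dg_exc_J_mol": self.min_dg,
            "refined_argmin_x2": self.refined_argmin,
        }


@dataclass(frozen=True, eq=False)
class MiscibilityResult:
    """Collapse-pressure-vs-composition table and the verdict."""

    table: pd.DataFrame            # columns x2, pi_coll_mN_m, mode
    verdict: str                   # miscible | immiscible-indication | inconclusive
    band: float

    def summary(self) -> dict:
        return {
            "verdict": self.verdict,
            "band_mN_m": self.band,
            "collapse_pressures": self.table.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# core computations
# ---------------------------------------------------------------------------


def _coverage_check(series: MixtureSeries, pi_max: float) -> None:
    failures = []
    for x, iso in series.members:
        top = iso.max_pressure
        if top < pi_max:
            failures.append(f"x2={x:g} covers only {top:.2f} mN/m")
    if failures:
        raise PressureRangeError(
            f"grid extends to {pi_max:g} mN/m beyond members: " + "; ".join(failures)
        )


def excess_area_surface(
    series: MixtureSeries,
    pressures=DEFAULT_PI_GRID,
    pi_target: float = DEFAULT_PI_TARGET,
    grid_step: float = 0.1,
) -> ExcessTable:
    """A^exc over (π, X) by regridding every member to common pressures.

    Endpoint columns are identically zero by the definition of the
    excess; ΔG^exc at ``pi_target`` is attached for each composition.
    """
    pressures = np.asarray(list(pressures), dtype=float)
    _coverage_check(series, float(max(pressures.max(), pi_target)))
    xs = series.compositions
    a1 = area_at_pressure(series.member(0.0), pressures)
    a2 = area_at_pressure(series.member(1.0), pressures)
    a_exc = np.empty((pressures.size, xs.size))
    for j, (x2, iso) in enumerate(series.members):
        a12 = area_at_pressure(iso, pressures)
        a_exc[:, j] = excess_area(a12, a1, a2, 1.0 - x2)
    dg = np.array(
        [excess_gibbs_energy(series, x2, pi_target, grid_step) for x2 in xs]
    )
    return ExcessTable(
        pressures=pressures, compositions=xs, a_exc=a_exc,
        dg_exc=dg, pi_target=pi_target,
    )


def excess_gibbs_energy(
    series: MixtureSeries,
    x2: float,
    pi_target: float = DEFAULT_PI_TARGET,
    grid_step: float = 0.1,
) -> float:
    """ΔG^exc = N_A ∫₀^{π*} A^exc dπ by trapezoid, in J/mol.

    ``x2`` must be a measured composition of the series. The lower limit
    is exactly π = 0; below the lift-off threshold the regridded area is
    held flat, where the integrand is ~0 by construction anyway.
    """
    if pi_target < 0:
        raise ValueError("pi_target must be >= 0")
    if pi_target == 0:
        return 0.0
    mix = series.member(x2)
    n = int(round(pi_target / grid_step)) + 1
    grid = np.linspace(0.0, pi_target, n)
    failures = []
    areas = {}
    for key, iso in (("mix", mix), ("e1", series.member(0.0)), ("e2", series.member(1.0))):
        top = iso.max_pressure
        if top < pi_target:
            failures.append(
                f"{key} (x2={dict(mix=x2, e1=0.0, e2=1.0)[key]:g}) covers only {top:.2f} mN/m"
            )
    if failures:
        raise PressureRangeError(
            f"pi_target={pi_target:g} mN/m beyond: " + "; ".join(failures)
        )
    a12 = area_at_pressure(mix, grid)
    a1 = area_at_pressure(series.member(0.0), grid)
    a2 = area_at_pressure(series.member(1.0), grid)
    a_exc = a12 - ((1.0 - x2) * a1 + x2 * a2)
    return float(J_PER_MOL_PER_A2_MNM * np.trapezoid(a_exc, grid))


def gibbs_composition_scan(
    series: MixtureSeries,
    pi_target: float = DEFAULT_PI_TARGET,
    grid_step: float = 0.1,
    refine: bool = False,
) -> CompositionScan:
    """ΔG^exc per measured composition, endpoints exactly zero.

    ``refine=True`` adds a parabolic interpolation of the minimum
    through its two neighbours; off by default because composition
    grids are coarse and the refined value is convention, not data.
    """
    xs = series.compositions
    if xs.size < 3:
        raise InsufficientDataError(
            f"need >= 3 compositions including endpoints, have {xs.size}"
        )
    failures = []
    dg = np.empty(xs.size)
    for i, x2 in enumerate(xs):
        try:
            dg[i] = excess_gibbs_energy(series, x2, pi_target, grid_step)
        except PressureRangeError as exc:
            failures.append(str(exc))
    if failures:
        raise PressureRangeError("; ".join(failures))
    refined = None
    if refine:
        k = int(np.argmin(dg))
        if 0 < k < xs.size - 1:
            x3, y3 = xs[k - 1 : k + 2], dg[k - 1 : k + 2]
            denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
            a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2]) + x3[0] * (y3[2] - y3[1])) / denom
            b = (x3[2] ** 2 * (y3[0] - y3[1]) + x3[1] ** 2 * (y3[2] - y3[0]) + x3[0] ** 2 * (y3[1] - y3[2])) / denom
            if a > 0:
                refined = float(-b / (2 * a))
    return CompositionScan(
        compositions=xs, dg_exc=dg, pi_target=pi_target, refined_argmin=refined
    )


def as_pseudo_component(
    iso: Isotherm, label: str | None = None
) -> tuple[Component, Isotherm]:
    """Wrap a fixed-ratio mixed film as a single pseudo-component.

    Lets a ternary film (e.g. POPC:SM 1:1 plus a sterol) be analyzed as
    a pseudo-binary scan over the sterol mole fraction.
    """
    if len(iso.components) < 2:
        raise ValueError(
            "pseudo-component requires a mixed film with >= 2 components; "
            f"got {[c for c, _ in iso.components]}"
        )
    if label is None:
        fractions = np.array([x for _, x in iso.components])
        ratio = fractions / fractions.min()
        ratio_txt = ":".join(f"{r:g}" for r in ratio)
        ids = ":".join(c for c, _ in iso.components)
        label = f"{ids}({ratio_txt})"
    component = Component(label, role="pseudo")
    wrapped = Isotherm(
        area=iso.area, pressure=iso.pressure, temperature=iso.temperature,
        components=((label, 1.0),),
        provenance={**iso.provenance, "pseudo_of": dict(iso.components)},
    )
    return component, wrapped


def miscibility_from_collapse(
    series: MixtureSeries, band: float = 0.6
) -> MiscibilityResult:
    """Collapse-pressure miscibility criterion.

    ``band`` is the significance band (default 3× the ~0.2 mN/m collapse
    detection uncertainty). Verdicts:

    * ``miscible`` — π_coll spans more than the band and interior
      compositions do not merely echo one endpoint;
    * ``immiscible-indication`` — every interior collapse coincides with
      one endpoint's collapse within the band (the film fails at the
      pressure of its least stable pure component);
    * ``inconclusive`` — π_coll barely varies or neither pattern holds.
    """
    rows = []
    for x2, iso in series.members:
        try:
            pi_c, mode = _collapse_pressure(iso)
        except (NoCollapseError, InsufficientDataError):
            continue
        rows.append({"x2": x2, "pi_coll_mN_m": pi_c, "mode": mode})
    if len(rows) < 3:
        raise InsufficientDataError(
            f"collapse detected for only {len(rows)} compositions; need >= 3"
        )
    table = pd.DataFrame(rows)
    pis = table["pi_coll_mN_m"].to_numpy()
    xs = table["x2"].to_numpy()
    spread = pis.max() - pis.min()
    interior = pis[(xs > 0) & (xs < 1)]
    endpoints = pis[(xs == 0) | (xs == 1)]
    verdict = "inconclusive"
    if interior.size:
        echoes_endpoint = any(
            np.all(np.abs(interior - pe) <= band) for pe in endpoints
        )
        if echoes_endpoint and spread > band:
            verdict = "immiscible-indication"
        elif spread > band:
            verdict = "miscible"
    return MiscibilityResult(table=table, verdict=verdict, band=band)


def scan_summary_json(scan: CompositionScan, miscibility: MiscibilityResult | None = None) -> str:
    """JSON summary (argmin, minimum, verdict) for pipeline output."""
    payload = scan.summary()
    if miscibility is not None:
        payload["miscibility"] = miscibility.summary()
    return json.dumps(payload, sort_keys=True)
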