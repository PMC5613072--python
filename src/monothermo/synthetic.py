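"""Synthetic π–A isotherms with analytic ground truth.

Raw film-balance data for the lipids this package targets are not
publicly deposited, so every analysis stage is validated against a
forward model whose characteristic points are known exactly:

* **Pure films** follow a 2-D equation of state — Volmer
  (π = f·kT/(A − ω) − π_coh, liquid-expanded), a linear condensed
  branch, or a piecewise LE → transition-plateau → condensed form —
  with an optional programmed collapse (hard plateau or pressure drop).
* **Mixed films** blend the pure equations of state ideally and add a
  Margules-type excess area
  A^exc(π, X) = X(1−X)·[α₀ + α₁(1−2X)]·g(π),
  whose pressure integral (hence ΔG^exc) has a closed form.
* **Instrument noise**: Gaussian π noise per point (default σ = 0.05
  mN/m, five times the 0.01 mN/m Wilhelmy sensor resolution, allowing
  for drift) and a Gaussian per-replicate area calibration offset
  (default σ = 1 Å², reproducing the ±2 Å²/molecule replicate envelope
  at 2σ). Within one mixture series the area offset is shared by all
  members — one spreading/calibration session — so it cancels in
  excess quantities, as it does on a real trough.

Shipped presets are calibrated only to published characteristic points
(lift-offs 91/78 Å², collapses 69/50/46 mN/m and the 43–47 mN/m
temperature trend, modulus maxima 150/300/830/160 mN/m); every other
parameter is a free, labelled choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .isotherm import Component, Isotherm, MixtureSeries
from .units import J_PER_MOL_PER_A2_MNM, thermal_area_pressure

__all__ = [
    "EOSModel",
    "PseudoEOS",
    "ExcessModel",
    "volmer_from_anchors",
    "simulate_pure_isotherm",
    "simulate_mixture_series",
    "analytic_excess_gibbs",
    "pure_preset",
    "series_preset",
    "PURE_PRESETS",
    "SERIES_PRESETS",
]

#: Default per-point pressure noise, mN/m.
SIGMA_PI = 0.05
#: Default per-replicate area calibration offset, Å².
SIGMA_AREA = 1.0


# ---------------------------------------------------------------------------
# equations of state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EOSModel:
    """Forward 2-D equation of state for a pure film.

    kind
        ``volmer`` | ``linear_condensed`` | ``piecewise_le_plateau_lc``.
    omega
        Volmer co-area, Å² (excluded area per molecule).
    pi_coh
        Volmer cohesion pressure, mN/m.
    thermal_scale
        Dimensionless factor multiplying kT in the Volmer branch
        (default 1). Values > 1 emulate chain cooperativity: they keep a
        liquid-expanded film compressible up to a high collapse, which a
        bare single-molecule Volmer term cannot do.
    area_zero
        π = 0 intercept of a linear condensed branch, Å².
    slope
        Condensed-branch steepness, mN/m per Å² (positive).
    plateau_pi / plateau_span / plateau_rise
        Transition plateau for the piecewise kind: onset pressure,
        (A_lo, A_hi) span, and the small pressure rise across the span
        (real transition plateaus are slanted; an exactly flat plateau
        would make A(π) multivalued).
    collapse_pi / collapse_mode
        Programmed film failure: ``plateau`` holds π at collapse_pi,
        ``drop`` lets π fall at 10% of collapse_pi per 2 Å² beyond the
        failure area.
    """

    kind: str
    omega: float = 0.0
    pi_coh: float = 0.0
    thermal_scale: float = 1.0
    area_zero: float = 0.0
    slope: float = 0.0
    plateau_pi: float | None = None
    plateau_span: tuple[float, float] | None = None
    plateau_rise: float = 0.5
    collapse_pi: float | None = None
    collapse_mode: str = "plateau"

    def __post_init__(self) -> None:
        if self.kind not in ("volmer", "linear_condensed", "piecewise_le_plateau_lc"):
            raise ValueError(f"unknown EOS kind {self.kind!r}")
        if self.kind != "linear_condensed" and not self.omega > 0:
            raise ValueError("omega must be > 0")
        if self.collapse_pi is not None and self.plateau_pi is not None:
            if self.collapse_pi <= self.plateau_pi + self.plateau_rise:
                raise ValueError("collapse_pi must exceed the transition plateau")
        if self.collapse_mode not in ("plateau", "drop"):
            raise ValueError(f"unknown collapse mode {self.collapse_mode!r}")

    # -- forward: π(A) on the un-collapsed branch ---------------------
    def base_pressure(self, area: np.ndarray, temperature: float) -> np.ndarray:
        area = np.asarray(area, dtype=float)
        kt = self.thermal_scale * thermal_area_pressure(temperature)
        if self.kind == "volmer":
            if np.any(area <= self.omega):
                raise ValueError(
                    f"area range intersects A <= omega = {self.omega} A^2"
                )
            return np.clip(kt / (area - self.omega) - self.pi_coh, 0.0, None)
        if self.kind == "linear_condensed":
            return np.clip(self.slope * (self.area_zero - area), 0.0, None)
        # piecewise: LE (volmer) above A_hi, slanted plateau, linear LC below A_lo
        a_lo, a_hi = self.plateau_span
        pi_t, rise = self.plateau_pi, self.plateau_rise
        le = np.clip(kt / (np.maximum(area, a_hi) - self.omega) - self.pi_coh, 0.0, None)
        ramp = pi_t + (a_hi - area) / (a_hi - a_lo) * rise
        lc = pi_t + rise + self.slope * (a_lo - area)
        out = np.where(area >= a_hi, le, np.where(area >= a_lo, ramp, lc))
        return out

    def pressure_of(self, area: np.ndarray, temperature: float) -> np.ndarray:
        """π(A) including the programmed collapse shaping."""
        pi = self.base_pressure(area, temperature)
        if self.collapse_pi is None:
            return pi
        pc = self.collapse_pi
        if self.collapse_mode == "plateau":
            return np.minimum(pi, pc)
        a_c = self.area_of(pc, temperature)
        area = np.asarray(area, dtype=float)
        failed = area < a_c
        drop = pc * (1.0 - 0.1 * (a_c - area) / 2.0)
        return np.where(failed, np.maximum(drop, 0.0), pi)

    # -- inverse: A(π) on the pre-collapse branch ---------------------
    def area_of(self, pressure, temperature: float):
        """Closed-form inverse A(π) for 0 ≤ π ≤ collapse_pi."""
        pi = np.asarray(pressure, dtype=float)
        kt = self.thermal_scale * thermal_area_pressure(temperature)
        if self.kind == "volmer":
            out = self.omega + kt / (pi + self.pi_coh)
        elif self.kind == "linear_condensed":
            out = self.area_zero - pi / self.slope
        else:
            a_lo, a_hi = self.plateau_span
            pi_t, rise = self.plateau_pi, self.plateau_rise
            le = self.omega + kt / (np.maximum(pi, 1e-12) + self.pi_coh)
            ramp = a_hi - (pi - pi_t) / rise * (a_hi - a_lo)
            lc = a_lo - (pi - pi_t - rise) / self.slope
            out = np.where(pi < pi_t, np.minimum(le, 1e9),
                           np.where(pi <= pi_t + rise, ramp, lc))
        return float(out) if np.isscalar(pressure) else out

    def lift_off_at(self, temperature: float) -> float:
        """Area at which π first exceeds zero (closed-form inverse at π = 0)."""
        return float(self.area_of(0.0, temperature))

    def suggested_area_range(self, temperature: float) -> tuple[float, float]:
        """Default compression window: gas toe through the collapse tail."""
        lift = self.lift_off_at(temperature)
        if self.collapse_pi is not None:
            a_c = self.area_of(self.collapse_pi, temperature)
            tail = 3.0 if self.collapse_mode == "plateau" else 2.5
            lo = a_c - tail
        else:
            lo = self.omega + 1.0 if self.kind == "volmer" else self.area_zero * 0.6
        return (lo, lift * 1.08 + 2.0)


def volmer_from_anchors(
    lift_off: float, anchor_area: float, anchor_pi: float,
    temperature: float, thermal_scale: float = 1.0,
) -> tuple[float, float]:
    """(omega, pi_coh) of a Volmer branch through π(lift_off) = 0 and
    π(anchor_area) = anchor_pi."""
    if not anchor_area < lift_off:
        raise ValueError("anchor_area must be below lift_off")
    kt = thermal_scale * thermal_area_pressure(temperature)
    d = lift_off - anchor_area
    u = (-d + math.sqrt(d * d + 4.0 * kt * d / anchor_pi)) / 2.0
    omega = anchor_area - u
    pi_coh = kt / (lift_off - omega)
    return omega, pi_coh


@dataclass(frozen=True)
class PseudoEOS:
    """Ideal fixed-ratio blend of pure equations of state.

    Used as the pseudo-component endpoint of a ternary film analyzed as
    a pseudo-binary (e.g. POPC:SM 1:1 versus a sterol). Collapse of the
    blend defaults to the weighted mean of the member collapses.
    """

    members: tuple[tuple[EOSModel, float], ...]
    collapse_pi: float | None = None
    collapse_mode: str = "plateau"

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"blend weights sum to {total}, not 1")
        if self.collapse_pi is None:
            pcs = [m.collapse_pi for m, _ in self.members]
            if all(pc is not None for pc in pcs):
                object.__setattr__(
                    self, "collapse_pi",
                    float(sum(pc * w for pc, (_, w) in zip(pcs, self.members))),
                )

    def area_of(self, pressure, temperature: float):
        pi = np.asarray(pressure, dtype=float)
        out = sum(w * m.area_of(pi, temperature) for m, w in self.members)
        return float(out) if np.isscalar(pressure) else out

    def lift_off_at(self, temperature: float) -> float:
        return float(self.area_of(0.0, temperature))


# ---------------------------------------------------------------------------
# excess model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExcessModel:
    """Margules-type parametric excess area.

    A^exc(π, X) = X(1−X)·[α₀ + α₁(1−2X)]·g(π) with X the mole fraction
    of endpoint 2 (the sterol, by convention). α₀ < 0 means net
    attraction; α₁ skews the composition of strongest interaction
    (α₁ = α₀ puts the ΔG^exc minimum at X = 1/3). g is either constant
    (1) or a linear decay 1 − π/π_ref clipped at zero — condensed films
    leave less room for excess packing. Both choices give the pressure
    integral, hence ΔG^exc, in closed form.
    """

    alpha0: float = 0.0
    alpha1: float = 0.0
    pressure_profile: str = "constant"
    pi_ref: float = 60.0

    def __post_init__(self) -> None:
        if self.pressure_profile not in ("constant", "linear_decay"):
            raise ValueError(f"unknown pressure profile {self.pressure_profile!r}")
        if self.pressure_profile == "linear_decay" and not self.pi_ref > 0:
            raise ValueError("pi_ref must be > 0")

    def g(self, pressure):
        pi = np.asarray(pressure, dtype=float)
        if self.pressure_profile == "constant":
            out = np.ones_like(pi)
        else:
            out = np.clip(1.0 - pi / self.pi_ref, 0.0, None)
        return float(out) if np.isscalar(pressure) else out

    def g_integral(self, pi_target: float) -> float:
        """∫₀^{π*} g dπ in mN/m."""
        if pi_target < 0:
            raise ValueError("pi_target must be >= 0")
        if self.pressure_profile == "constant":
            return pi_target
        if pi_target >= self.pi_ref:
            return self.pi_ref / 2.0
        return pi_target - pi_target**2 / (2.0 * self.pi_ref)

    def interaction(self, x2) -> float:
        """X(1−X)·[α₀ + α₁(1−2X)], the composition factor in Å²."""
        x = np.asarray(x2, dtype=float)
        out = x * (1.0 - x) * (self.alpha0 + self.alpha1 * (1.0 - 2.0 * x))
        return float(out) if np.isscalar(x2) else out

    def a_exc(self, pressure, x2):
        """Excess area A^exc(π, X) in Å²/molecule."""
        return self.interaction(x2) * self.g(pressure)


IDEAL = ExcessModel()


def analytic_excess_gibbs(excess: ExcessModel, x2: float, pi_target: float) -> float:
    """Closed-form ΔG^exc = N_A ∫₀^{π*} A^exc dπ, in J/mol."""
    return J_PER_MOL_PER_A2_MNM * excess.interaction(x2) * excess.g_integral(pi_target)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def simulate_pure_isotherm(
    model: EOSModel,
    temperature: float = 20.0,
    n_points: int = 500,
    area_range: tuple[float, float] | None = None,
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
    components: tuple[tuple[str, float], ...] = (("lipid", 1.0),),
    provenance: dict | None = None,
) -> Isotherm:
    """One seeded compression run of a pure film.

    noise = (σ_π, σ_A): per-point Gaussian pressure noise and a single
    Gaussian area calibration offset applied to the whole run. Noise-free
    output is the equation of state exactly; identical seeds give
    identical isotherms.
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    if area_range is None:
        area_range = model.suggested_area_range(temperature)
    lo, hi = area_range
    if not lo < hi:
        raise ValueError(f"empty area range {area_range}")
    area = np.linspace(hi, lo, n_points)
    pressure = model.pressure_of(area, temperature)
    sigma_pi, sigma_a = noise
    if sigma_pi or sigma_a:
        rng = np.random.default_rng(seed)
        if sigma_a:
            area = area + rng.normal(0.0, sigma_a)
        if sigma_pi:
            pressure = pressure + rng.normal(0.0, sigma_pi, size=pressure.size)
    prov = {"generator": model.kind, "seed": seed, **(provenance or {})}
    return Isotherm(
        area=area, pressure=pressure, temperature=temperature,
        components=components, provenance=prov,
    )


def simulate_mixture_series(
    endpoint_1: EOSModel | PseudoEOS,
    endpoint_2: EOSModel | PseudoEOS,
    x_list,
    excess: ExcessModel = IDEAL,
    temperature: float = 20.0,
    n_points: int = 500,
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
    labels: tuple[str, str] = ("component_1", "component_2"),
    roles: tuple[str, str] = ("phospholipid", "sterol"),
    collapse_map=None,
) -> MixtureSeries:
    """Seeded mixture series A₁₂(π) = X₁A₁(π) + X₂A₂(π) + A^exc(π, X₂).

    The collapse pressure of each member interpolates linearly between
    the endpoint collapses unless ``collapse_map(x2) -> π`` overrides
    it. Per-member pressure-noise streams derive reproducibly from the
    master seed; the area calibration offset is drawn once and shared by
    every member (one spreading session), so it cancels in excess
    quantities exactly as replicate calibration does on a real trough.
    """
    xs = np.array(sorted(float(x) for x in x_list))
    if np.any((xs < 0) | (xs > 1)):
        raise ValueError("mole fractions must lie in [0, 1]")
    if xs[0] != 0.0 or xs[-1] != 1.0:
        raise ValueError("x_list must include the pure endpoints 0 and 1")
    pc1, pc2 = endpoint_1.collapse_pi, endpoint_2.collapse_pi
    if collapse_map is None:
        if pc1 is None or pc2 is None:
            raise ValueError("endpoints need collapse_pi or pass collapse_map")
        collapse_map = lambda x: (1.0 - x) * pc1 + x * pc2  # noqa: E731

    sigma_pi, sigma_a = noise
    seq = np.random.SeedSequence(seed)
    offset = (
        np.random.default_rng(seq).normal(0.0, sigma_a) if sigma_a else 0.0
    )
    children = seq.spawn(xs.size)

    members = []
    for x2, child in zip(xs, children):
        pi_c = float(collapse_map(x2))

        def a12(pi):
            return (
                (1.0 - x2) * endpoint_1.area_of(pi, temperature)
                + x2 * endpoint_2.area_of(pi, temperature)
                + excess.a_exc(pi, x2)
            )

        # sample uniformly in area, as a constant barrier speed does:
        # invert the fine-grained A12(pi) branch, prepend a short gas
        # toe at pi = 0 and append the collapse tail.
        fine = np.linspace(0.0, pi_c, 4000)
        a_fine = a12(fine)
        a0, a_c = a_fine[0], a_fine[-1]
        mode = endpoint_1.collapse_mode if x2 < 0.5 else endpoint_2.collapse_mode
        depth = 3.0 if mode == "plateau" else 2.5
        # gas toe sampled separately so the lift-off area a0 is an exact
        # grid point (no interpolation bias at the pi = 0 kink)
        n_toe = max(10, n_points // 12)
        toe = np.linspace(a0 + 5.0, a0, n_toe, endpoint=False)
        area = np.concatenate([toe, np.linspace(a0, a_c - depth, n_points - n_toe)])
        pressure = np.where(
            area >= a0,
            0.0,
            np.interp(area, a_fine[::-1], fine[::-1]),
        )
        failed = area < a_c
        if mode == "plateau":
            pressure[failed] = pi_c
        else:
            pressure[failed] = pi_c * (1.0 - 0.1 * (a_c - area[failed]) / 2.0)
        area = area + offset
        if sigma_pi:
            rng = np.random.default_rng(child)
            pressure = pressure + rng.normal(0.0, sigma_pi, size=pressure.size)
        if x2 == 0.0:
            comps = ((labels[0], 1.0),)
        elif x2 == 1.0:
            comps = ((labels[1], 1.0),)
        else:
            comps = ((labels[0], 1.0 - x2), (labels[1], x2))
        members.append(
            (
                float(x2),
                Isotherm(
                    area=area, pressure=pressure, temperature=temperature,
                    components=comps,
                    provenance={"generator": "mixture", "seed": seed, "x2": float(x2)},
                ),
            )
        )
    return MixtureSeries(
        endpoint_1=Component(labels[0], roles[0]),
        endpoint_2=Component(labels[1], roles[1]),
        members=tuple(members),
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _sm_brain(temperature: float) -> EOSModel:
    omega, pi_coh = volmer_from_anchors(91.0, 80.0, 5.0, temperature)
    return EOSModel(
        kind="piecewise_le_plateau_lc", omega=omega, pi_coh=pi_coh,
        plateau_pi=5.0, plateau_span=(50.0, 80.0), plateau_rise=0.5,
        slope=3.0, collapse_pi=69.0, collapse_mode="plateau",
    )


def _sm_egg(temperature: float) -> EOSModel:
    omega, pi_coh = volmer_from_anchors(78.0, 70.0, 6.0, temperature)
    return EOSModel(
        kind="piecewise_le_plateau_lc", omega=omega, pi_coh=pi_coh,
        plateau_pi=6.0, plateau_span=(50.0, 70.0), plateau_rise=0.5,
        slope=6.0, collapse_pi=69.0, collapse_mode="plateau",
    )


def _popc(temperature: float) -> EOSModel:
    return EOSModel(
        kind="volmer", omega=25.0, pi_coh=13.0, thermal_scale=3.0,
        collapse_pi=50.0, collapse_mode="plateau",
    )


def _chol(temperature: float) -> EOSModel:
    return EOSModel(
        kind="linear_condensed", area_zero=40.0, slope=20.75,
        collapse_pi=46.0, collapse_mode="drop",
    )


def _7kc(temperature: float) -> EOSModel:
    # collapse falls with subphase temperature: 47 at 10 C, 46 at 20 C, 43 at 30 C
    pc = float(np.interp(temperature, [10.0, 20.0, 30.0], [47.0, 46.0, 43.0]))
    return EOSModel(
        kind="linear_condensed", area_zero=62.0, slope=160.0 / 62.0,
        collapse_pi=pc, collapse_mode="drop",
    )


PURE_PRESETS = {
    "sm-brain": _sm_brain,
    "sm-egg": _sm_egg,
    "popc": _popc,
    "chol": _chol,
    "7kc": _7kc,
}

_PRESET_META = {
    "sm-brain": ("SM_brain", "sphingolipid"),
    "sm-egg": ("SM_egg", "sphingolipid"),
    "popc": ("POPC", "phospholipid"),
    "chol": ("CHOL", "sterol"),
    "7kc": ("7KC", "sterol"),
}


def pure_preset(name: str, temperature: float = 20.0) -> EOSModel:
    """Calibrated pure-film preset; see module docstring for targets."""
    try:
        return PURE_PRESETS[name](temperature)
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PURE_PRESETS)}"
        ) from None


#: (endpoint_1, endpoint_2, excess model) for the studied pairs; the
#: sterol is always endpoint 2, matching the X_sterol axis convention.
#: α₀ magnitudes are free choices; the Chol:7-KC 2:1 ratio with POPC and
#: the α₁ = α₀ skew (minimum at X = 1/3) with SM are the calibrated bits.
SERIES_PRESETS = {
    "chol-popc": ("popc", "chol",
                  ExcessModel(alpha0=-10.0, pressure_profile="linear_decay", pi_ref=60.0)),
    "7kc-popc": ("popc", "7kc",
                 ExcessModel(alpha0=-5.0, pressure_profile="linear_decay", pi_ref=60.0)),
    "chol-sm": ("sm-brain", "chol",
                ExcessModel(alpha0=-8.0, alpha1=-8.0,
                            pressure_profile="linear_decay", pi_ref=60.0)),
    "7kc-sm": ("sm-brain", "7kc",
               ExcessModel(alpha0=-9.0, alpha1=-9.0,
                           pressure_profile="linear_decay", pi_ref=60.0)),
    "chol-popcsm": ("popc:sm", "chol",
                    ExcessModel(alpha0=-7.0, pressure_profile="linear_decay", pi_ref=60.0)),
    "7kc-popcsm": ("popc:sm", "7kc",
                   ExcessModel(alpha0=-12.0, pressure_profile="linear_decay", pi_ref=60.0)),
}


def _endpoint_model(key: str, temperature: float):
    if key == "popc:sm":
        return PseudoEOS(
            members=((pure_preset("popc", temperature), 0.5),
                     (pure_preset("sm-brain", temperature), 0.5)),
        )
    return pure_preset(key, temperature)


def series_preset(
    name: str,
    x_list=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    temperature: float = 20.0,
    n_points: int = 500,
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
) -> MixtureSeries:
    """Calibrated mixture-series preset (binary or pseudo-binary)."""
    try:
        e1, e2, excess = SERIES_PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown series preset {name!r}; available: {sorted(SERIES_PRESETS)}"
        ) from None
    m1 = _endpoint_model(e1, temperature)
    m2 = _endpoint_model(e2, temperature)
    label1 = "POPC:SM(1:1)" if e1 == "popc:sm" else _PRESET_META[e1][0]
    role1 = "pseudo" if e1 == "popc:sm" else _PRESET_META[e1][1]
    label2, role2 = _PRESET_META[e2]
    return simulate_mixture_series(
        m1, m2, x_list, excess=excess, temperature=temperature,
        n_points=n_points, noise=noise, seed=seed,
        labels=(label1, label2), roles=(role1, role2),
    )


def preset_excess(name: str) -> ExcessModel:
    """Ground-truth excess model behind a series preset."""
    try:
        return SERIES_PRESETS[name][2]
    except KeyError:
        raise ConfigError(
            f"unknown series preset {name!r}; available: {sorted(SERIES_PRESETS)}"
        ) from None
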