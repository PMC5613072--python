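"""Per-isotherm characteristic quantities.

Everything a film-balance study tabulates for a single compression run:

* the compression-modulus curve C_s⁻¹(π) = −A·dπ/dA,
* the physical-state label (G / LE / LC / S) from the modulus maximum,
* lift-off area (where π first rises measurably above zero),
* limiting area (π = 0 intercept of the last rectilinear segment),
* collapse pressure and its signature (plateau / drop / kink),
* phase-transition pressures (modulus minima between two maxima).

State bands follow the Davies–Rideal convention: below 12.5 mN/m the
film is gaseous, 12.5–100 liquid-expanded (the 50–100 stretch is
transitional LE/LC and is labelled LC with a ``transitional`` flag),
100–250 liquid-condensed, above 250 solid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    NoCollapseError,
    NoLiftOffError,
    NoLinearSegmentError,
)
from .isotherm import Isotherm, monotone_branch, pre_collapse_branch, smooth_pressure

__all__ = [
    "ModulusCurve",
    "DescriptorSet",
    "LimitingAreaFit",
    "STATE_BANDS",
    "compression_modulus_curve",
    "classify_state",
    "is_transitional",
    "lift_off_area",
    "limiting_area",
    "collapse_pressure",
    "transition_pressures",
    "describe",
]

#: Upper C_s⁻¹ bound (mN/m) of each state band, in condensation order.
STATE_BANDS: tuple[tuple[float, str], ...] = (
    (12.5, "G"),
    (50.0, "LE"),
    (100.0, "LC"),   # transitional LE/LC, flagged
    (250.0, "LC"),
    (float("inf"), "S"),
)

#: Default sustain count: a threshold crossing or plateau must hold for
#: this many consecutive points (robust to ±0.01 mN/m sensor noise).
SUSTAIN = 5


@dataclass(frozen=True, eq=False)
class ModulusCurve:
    """C_s⁻¹ along the pre-collapse branch, in compression order."""

    area: np.ndarray
    pressure: np.ndarray
    cs: np.ndarray
    n_floored: int = 0  # negative (noise) values floored at zero

    @property
    def cs_max(self) -> float:
        return float(self.cs.max())

    @property
    def cs_max_pressure(self) -> float:
        return float(self.pressure[int(np.argmax(self.cs))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pressure_mN_m": self.pressure,
                "cs_inverse_mN_m": self.cs,
                "area_A2": self.area,
            }
        )


@dataclass(frozen=True)
class LimitingAreaFit:
    """Result of the last-rectilinear-segment extrapolation."""

    limiting_area: float
    slope: float            # dπ/dA over the segment, mN/m per Å²
    r_squared: float
    segment_bounds: tuple[float, float]   # (A_min, A_max) of the segment
    n_points: int


@dataclass(frozen=True)
class DescriptorSet:
    """Characteristic points of one compression run."""

    lift_off_area: float | None
    limiting_area: float | None
    collapse_pressure: float | None
    collapse_area: float | None
    collapse_mode: str               # "plateau" | "drop" | "kink" | "absent"
    cs_max: float
    cs_max_pressure: float
    state: str
    transitional: bool
    transitions: tuple[float, ...]
    limiting_fit: LimitingAreaFit | None = field(default=None, repr=False)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["transitions"] = list(self.transitions)
        return json.dumps(payload, sort_keys=True)


# ---------------------------------------------------------------------------
# modulus & state
# ---------------------------------------------------------------------------


def compression_modulus_curve(
    iso: Isotherm,
    smooth_window: int | None = None,
    polyorder: int = 2,
) -> ModulusCurve:
    """C_s⁻¹ = −A·dπ/dA by centred finite differences.

    Evaluated on the pre-collapse branch of the (optionally smoothed)
    isotherm; negative values from residual noise are floored at 0 and
    counted in ``n_floored``. No spline differentiation: splines
    over-smooth transition plateaus.
    """
    if smooth_window is not None:
        iso = smooth_pressure(iso, min(smooth_window, iso.n_points | 1), polyorder)
    a, p = pre_collapse_branch(iso)
    if a.size < 3:
        raise InsufficientDataError(
            f"pre-collapse branch has {a.size} points; need >= 3 to differentiate"
        )
    dpda = np.gradient(p, a)
    cs = -a * dpda
    n_floored = int(np.sum(cs < 0))
    cs = np.clip(cs, 0.0, None)
    return ModulusCurve(area=a, pressure=p, cs=cs, n_floored=n_floored)


def classify_state(cs_max: float) -> str:
    """Physical-state label from the maximum compression modulus."""
    if not cs_max > 0:
        raise ValueError(f"cs_max must be > 0, got {cs_max}")
    for upper, label in STATE_BANDS:
        if cs_max <= upper:
            return label
    raise AssertionError("unreachable")


def is_transitional(cs_max: float) -> bool:
    """True in the 50–100 mN/m band, where LE and LC domains coexist."""
    return 50.0 < cs_max <= 100.0


# ---------------------------------------------------------------------------
# characteristic points
# ---------------------------------------------------------------------------


def lift_off_area(
    iso: Isotherm,
    noise_sigma: float = 0.0,
    sustain: int = SUSTAIN,
) -> float:
    """Largest area at which π rises above the noise floor and stays there.

    The threshold is max(3·noise_sigma, 0.1 mN/m); the crossing is
    refined by linear interpolation between the bracketing points.
    """
    threshold = max(3.0 * noise_sigma, 0.1)
    a, p = pre_collapse_branch(iso)
    above = p >= threshold
    if not above.any():
        raise NoLiftOffError(
            f"pressure never reaches the {threshold:.3f} mN/m lift-off threshold"
        )
    n = p.size
    for i in np.flatnonzero(above):
        if i == 0:
            raise NoLiftOffError(
                "first recorded point already above the lift-off threshold; "
                "compression does not start in the gas phase"
            )
        j = min(i + sustain, n)
        if np.all(p[i:j] >= threshold):
            frac = (threshold - p[i - 1]) / (p[i] - p[i - 1])
            return float(a[i - 1] + frac * (a[i] - a[i - 1]))
    raise NoLiftOffError(
        f"no crossing of {threshold:.3f} mN/m sustained for {sustain} points"
    )


def limiting_area(
    iso: Isotherm,
    min_frac: float = 0.15,
    r2_min: float = 0.999,
    min_points: int = 8,
    pressure_floor: float = 0.5,
) -> LimitingAreaFit:
    """π = 0 intercept of the last rectilinear segment.

    "Last" is taken literally: the fitted window is anchored at the
    most-compressed end of the pre-collapse branch (a transition plateau
    earlier in the run can be long and perfectly straight, but it is not
    the condensed terminal regime). The window is grown backwards from
    the branch end to the longest length, at least ``min_frac`` of the
    branch (and ≥ ``min_points``), that keeps R² ≥ ``r2_min``; if no
    length qualifies the anchor is allowed to retreat by up to 5% of the
    branch (collapse-onset remnants). Points below ``pressure_floor``
    mN/m are excluded — the gas-phase toe is flat and would masquerade
    as a perfect line with no usable intercept.
    """
    a, p = monotone_branch(iso)
    mask = p >= pressure_floor
    a, p = a[mask], p[mask]
    n = a.size
    L_min = max(min_points, int(np.ceil(min_frac * n)))
    if n < L_min:
        raise NoLinearSegmentError(
            f"only {n} points above the {pressure_floor} mN/m floor"
        )
    # cumulative sums for O(1) per-window least squares
    ca = np.concatenate(([0.0], np.cumsum(a)))
    cp = np.concatenate(([0.0], np.cumsum(p)))
    caa = np.concatenate(([0.0], np.cumsum(a * a)))
    cpp = np.concatenate(([0.0], np.cumsum(p * p)))
    cap = np.concatenate(([0.0], np.cumsum(a * p)))
    def window_fit(start: int, end: int):
        L = end - start
        sa = ca[end] - ca[start]
        sp = cp[end] - cp[start]
        var_a = caa[end] - caa[start] - sa * sa / L
        var_p = cpp[end] - cpp[start] - sp * sp / L
        cov = cap[end] - cap[start] - sa * sp / L
        if var_a <= 0 or var_p <= 0:
            return 0.0, 0.0, 0.0
        r2 = cov * cov / (var_a * var_p)
        slope = cov / var_a
        intercept = (sp - slope * sa) / L
        return r2, slope, intercept

    retreat = max(1, int(0.05 * n))
    for end in range(n, n - retreat - 1, -1):
        best = None
        for L in range(end, L_min - 1, -1):
            r2, slope, intercept = window_fit(end - L, end)
            if r2 >= r2_min and slope != 0:
                best = (L, r2, slope, intercept)
                break
        if best is not None:
            L, r2, slope, intercept = best
            return LimitingAreaFit(
                limiting_area=float(-intercept / slope),
                slope=float(slope),
                r_squared=float(r2),
                segment_bounds=(float(a[end - 1]), float(a[end - L])),
                n_points=L,
            )
    raise NoLinearSegmentError(
        f"no terminal window of >= {L_min} points reaches R^2 >= {r2_min}"
    )


def collapse_pressure(
    iso: Isotherm,
    slope_eps: float = 0.5,
    sustain: int = SUSTAIN,
    drop_tol: float = 0.5,
    kink_ratio: float = 3.0,
    smooth_window: int | None = 11,
) -> tuple[float, str]:
    """Collapse onset pressure and its signature.

    Three signatures are tried on the (optionally smoothed) run:

    ``drop``
        π falls by more than ``drop_tol`` mN/m after its maximum;
        onset is the maximum.
    ``plateau``
        |dπ/dA| stays below ``slope_eps`` for ``sustain`` points after
        the modulus maximum; onset is the first point of the run.
    ``kink``
        the mean |dπ/dA| ratio across a breakpoint in the upper half of
        the pressure range exceeds ``kink_ratio``.

    If drop and plateau both fire, the lower-π onset is reported.
    """
    if smooth_window is not None and iso.n_points >= smooth_window:
        work = smooth_pressure(iso, smooth_window, 2)
    else:
        work = iso
    a = iso.area
    p_raw = iso.pressure
    p = work.pressure  # smoothed channel drives slope-based detection
    if a.size < 3 + sustain:
        raise InsufficientDataError("too few points for collapse detection")
    candidates: list[tuple[float, str]] = []

    # drop: raw data — the peak value is the onset, and smoothing
    # flattens an asymmetric peak toward the shallow side. The onset is
    # refined by intersecting straight-line fits on either flank, which
    # removes the sampling bias of the discrete maximum.
    i_raw_max = int(np.argmax(p_raw))
    if i_raw_max < p_raw.size - 1 and p_raw[i_raw_max] - p_raw[i_raw_max + 1 :].min() > drop_tol:
        pi_drop = float(p_raw[i_raw_max])
        k = max(sustain, 5)
        lo, hi = i_raw_max - 1 - k, i_raw_max + 2 + k
        if lo >= 0 and hi <= p_raw.size:
            c1 = np.polyfit(a[lo : i_raw_max - 1], p_raw[lo : i_raw_max - 1], 1)
            c2 = np.polyfit(a[i_raw_max + 2 : hi], p_raw[i_raw_max + 2 : hi], 1)
            if c1[0] != c2[0]:
                a_star = (c2[1] - c1[1]) / (c1[0] - c2[0])
                pi_star = float(np.polyval(c1, a_star))
                if a[hi - 1] <= a_star <= a[lo] and pi_star >= pi_drop - drop_tol:
                    pi_drop = pi_star
        candidates.append((pi_drop, "drop"))

    dpda = np.gradient(p, a)
    i_max = int(np.argmax(p))
    cs = np.clip(-a * dpda, 0.0, None)
    i_cs = int(np.argmax(cs[: i_max + 1]))
    flat = np.abs(dpda) < slope_eps
    j = i_cs
    while j <= p.size - sustain:
        if np.all(flat[j : j + sustain]):
            candidates.append((float(np.median(p_raw[j : j + sustain])), "plateau"))
            break
        j += 1

    if not candidates:
        half = p >= 0.5 * p[i_max]
        k = sustain
        for j in np.flatnonzero(half):
            if j - k < 0 or j + k >= p.size:
                continue
            before = np.abs(dpda[j - k : j]).mean()
            after = np.abs(dpda[j : j + k]).mean()
            if after > 0 and before / after > kink_ratio:
                candidates.append((float(p_raw[j]), "kink"))
                break

    if not candidates:
        raise NoCollapseError("no plateau, drop or kink collapse signature found")
    pi_coll, mode = min(candidates, key=lambda c: c[0])
    return pi_coll, mode


def transition_pressures(
    curve: ModulusCurve,
    threshold: float = 20.0,
    peak_min: float = 30.0,
    min_run: int = SUSTAIN,
) -> list[float]:
    """Pressures of LE→LC-type transitions.

    A transition is a contiguous run of at least ``min_run`` modulus
    values below ``threshold`` flanked on both sides by maxima above
    ``peak_min`` (an interior modulus minimum between two maxima); the
    run-length requirement rejects single-point noise dips. The
    reported π is the run onset — the conventional transition pressure,
    where the plateau begins. Runs touching either end of the branch
    are the gas toe or the collapse region, not transitions.
    """
    cs, p = curve.cs, curve.pressure
    below = cs < threshold
    transitions: list[float] = []
    i = 0
    n = cs.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if i > 0 and j < n and j - i >= min_run:
                if cs[:i].max() >= peak_min and cs[j:].max() >= peak_min:
                    transitions.append(float(p[i]))
            i = j
        else:
            i += 1
    return transitions


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def describe(
    iso: Isotherm,
    noise_sigma: float = 0.0,
    smooth_window: int | None = 11,
) -> DescriptorSet:
    """Full descriptor report for one isotherm.

    Missing features (no collapse, no rectilinear segment, no lift-off)
    are recorded as absent rather than raised.
    """
    curve = compression_modulus_curve(iso, smooth_window=smooth_window)
    cs_max = curve.cs_max
    try:
        lift = lift_off_area(iso, noise_sigma=noise_sigma)
    except NoLiftOffError:
        lift = None
    try:
        fit = limiting_area(iso)
        lim = fit.limiting_area
    except NoLinearSegmentError:
        fit, lim = None, None
    try:
        pi_coll, mode = collapse_pressure(iso, smooth_window=smooth_window)
        from .isotherm import area_at_pressure  # local import, cheap

        coll_area = float(area_at_pressure(iso, [min(pi_coll, curve.pressure[-1])])[0])
    except (NoCollapseError, InsufficientDataError):
        pi_coll, mode, coll_area = None, "absent", None
    return DescriptorSet(
        lift_off_area=lift,
        limiting_area=lim,
        collapse_pressure=pi_coll,
        collapse_area=coll_area,
        collapse_mode=mode,
        cs_max=cs_max,
        cs_max_pressure=curve.cs_max_pressure,
        state=classify_state(cs_max),
        transitional=is_transitional(cs_max),
        transitions=tuple(transition_pressures(curve)),
        limiting_fit=fit,
    )
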