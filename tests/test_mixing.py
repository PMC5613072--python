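"""Excess mixing thermodynamics: areas, free enthalpies, miscibility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from monothermo import (
    EOSModel,
    ExcessModel,
    InsufficientDataError,
    PressureRangeError,
    analytic_excess_gibbs,
    as_pseudo_component,
    excess_area,
    excess_area_surface,
    excess_gibbs_energy,
    gibbs_composition_scan,
    miscibility_from_collapse,
    pure_preset,
    series_preset,
    simulate_mixture_series,
    simulate_pure_isotherm,
)
from monothermo.synthetic import preset_excess

POPC = pure_preset("popc")
CHOL = pure_preset("chol")


def ideal_series(x_list=(0.0, 0.25, 0.5, 0.75, 1.0), **kw):
    return simulate_mixture_series(POPC, CHOL, x_list, **kw)


class TestExcessArea:
    def test_ideal_mixing_is_zero(self):
        assert excess_area(50.0, 40.0, 60.0, 0.5) == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        assert excess_area(45.0, 40.0, 60.0, 0.5) == pytest.approx(-5.0)

    def test_endpoint_identity(self):
        assert excess_area(43.0, 40.0, 60.0, 1.0) == pytest.approx(3.0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            excess_area(0.0, 40.0, 60.0, 0.5)

    @given(
        st.floats(10, 100), st.floats(10, 100), st.floats(0, 1)
    )
    @settings(max_examples=100, deadline=None)
    def test_additive_blend_always_zero(self, a1, a2, x1):
        blend = a1 * x1 + a2 * (1 - x1)
        assert excess_area(blend, a1, a2, x1) == pytest.approx(0.0, abs=1e-9)


class TestExcessSurface:
    def test_ideal_surface_is_flat_zero(self):
        table = excess_area_surface(ideal_series())
        assert np.max(np.abs(table.a_exc)) <= 0.05
        assert np.all(table.signs[:, [0, -1]] == "zero")

    def test_margules_surface_matches_closed_form(self):
        """Noise-free surface equals alpha0*X(1-X)*g(pi) to <= 0.5%."""
        excess = ExcessModel(alpha0=-8.0, pressure_profile="linear_decay", pi_ref=60.0)
        series = simulate_mixture_series(POPC, CHOL, (0, 0.25, 0.5, 0.75, 1), excess=excess)
        table = excess_area_surface(series)
        pi, x = np.meshgrid(table.pressures, table.compositions, indexing="ij")
        expected = -8.0 * x * (1 - x) * (1 - pi / 60.0)
        interior = expected != 0
        rel = np.abs(table.a_exc[interior] - expected[interior]) / np.abs(expected[interior])
        assert rel.max() <= 0.005

    def test_attractive_preset_negative_at_30(self):
        series = series_preset("chol-popc", x_list=(0, 0.25, 0.5, 0.75, 1))
        table = excess_area_surface(series, pressures=[30.0])
        assert np.all(table.a_exc[0, 1:-1] < 0)

    def test_bubble_frame_polarity(self):
        excess = ExcessModel(alpha0=6.0)
        series = simulate_mixture_series(POPC, CHOL, (0, 0.5, 1), excess=excess)
        frame = excess_area_surface(series).to_bubble_frame()
        mid = frame[(frame.x2 == 0.5)]
        assert (mid.polarity == "bright").all()
        assert np.allclose(mid.radius, mid.a_exc_A2.abs())

    def test_member_not_covering_grid_is_named(self):
        series = ideal_series()
        with pytest.raises(PressureRangeError, match="x2=1"):
            excess_area_surface(series, pressures=[48.0], pi_target=48.0)


class TestExcessGibbs:
    def test_unit_bridge(self):
        """Constant A^exc = 1 A^2 to pi = 1 mN/m -> 6.022 J/mol."""
        excess = ExcessModel(alpha0=4.0)  # X(1-X)*4 = 1 at X = 0.5
        series = simulate_mixture_series(POPC, CHOL, (0, 0.5, 1), excess=excess)
        assert excess_gibbs_energy(series, 0.5, 1.0) == pytest.approx(6.022, abs=5e-4)

    def test_linear_excess_closed_form(self):
        """A^exc = b*pi gives N_A*b*pi^2/2; trapezoid within 0.5%."""
        # linear_decay with pi_ref=30 at pi_target=30: integral = 15,
        # i.e. triangular profile; use direct quadratic identity instead
        excess = ExcessModel(alpha0=-4.0, pressure_profile="linear_decay", pi_ref=60.0)
        series = simulate_mixture_series(POPC, CHOL, (0, 0.5, 1), excess=excess)
        got = excess_gibbs_energy(series, 0.5, 30.0)
        # independent closed form: 6.02214076 * (-1) * (30 - 30^2/120)
        expected = 6.02214076 * (-1.0) * (30.0 - 900.0 / 120.0)
        assert got == pytest.approx(expected, rel=0.005)

    def test_ideal_is_null_and_endpoints_exact_zero(self):
        series = ideal_series()
        for x in (0.25, 0.5, 0.75):
            assert abs(excess_gibbs_energy(series, x, 30.0)) <= 1.0
        assert excess_gibbs_energy(series, 0.0, 30.0) == 0.0
        assert excess_gibbs_energy(series, 1.0, 30.0) == 0.0
        assert excess_gibbs_energy(series, 0.5, 0.0) == 0.0

    def test_additivity_over_pressure(self):
        excess = ExcessModel(alpha0=-8.0, pressure_profile="linear_decay", pi_ref=60.0)
        series = simulate_mixture_series(POPC, CHOL, (0, 0.5, 1), excess=excess)
        full = excess_gibbs_energy(series, 0.5, 30.0)
        lo = excess_gibbs_energy(series, 0.5, 18.0)
        # trapezoid of the 18->30 stretch on the same 0.1 grid
        from monothermo import area_at_pressure

        grid = np.linspace(18.0, 30.0, 121)
        mix = series.member(0.5)
        a_exc = (
            area_at_pressure(mix, grid)
            - 0.5 * area_at_pressure(series.member(0.0), grid)
            - 0.5 * area_at_pressure(series.member(1.0), grid)
        )
        upper = 6.02214076 * np.trapezoid(a_exc, grid)
        assert full == pytest.approx(lo + upper, abs=0.1)

    def test_target_beyond_collapse_raises(self):
        series = ideal_series()
        with pytest.raises(PressureRangeError, match="49"):
            excess_gibbs_energy(series, 0.5, 49.0)


class TestCompositionScan:
    def test_symmetric_attractive_minimum_at_half(self):
        series = series_preset("chol-popc", x_list=np.arange(0, 1.01, 0.1))
        scan = gibbs_composition_scan(series, 30.0)
        assert scan.argmin_x == pytest.approx(0.5)
        assert scan.min_dg < 0

    def test_asymmetric_minimum_near_one_third(self):
        series = series_preset("chol-sm", x_list=np.arange(0, 1.01, 0.1))
        scan = gibbs_composition_scan(series, 30.0)
        assert scan.argmin_x == pytest.approx(0.3)

    def test_repulsive_preset_positive_interior(self):
        excess = ExcessModel(alpha0=6.0)
        series = simulate_mixture_series(POPC, CHOL, (0, 0.25, 0.5, 0.75, 1), excess=excess)
        scan = gibbs_composition_scan(series, 30.0)
        interior = scan.dg_exc[1:-1]
        assert np.all(interior > 0)
        assert scan.argmin_x in (0.0, 1.0)
        assert scan.min_dg == pytest.approx(0.0, abs=1e-9)

    def test_parabolic_refinement_opt_in(self):
        series = series_preset("chol-popc", x_list=(0, 0.3, 0.5, 0.7, 1))
        plain = gibbs_composition_scan(series, 30.0)
        refined = gibbs_composition_scan(series, 30.0, refine=True)
        assert plain.refined_argmin is None
        assert refined.refined_argmin == pytest.approx(0.5, abs=0.02)

    def test_two_compositions_insufficient(self):
        series = ideal_series(x_list=(0.0, 1.0))
        with pytest.raises(InsufficientDataError):
            gibbs_composition_scan(series, 30.0)

    def test_noisy_recovery_all_presets(self):
        """Median |dG_exc error| over seeded replicates stays within
        max(10 J/mol, 5% of truth) for every shipped preset."""
        for name in ("chol-popc", "7kc-popc", "chol-sm", "7kc-sm"):
            truth = analytic_excess_gibbs(preset_excess(name), 0.5, 30.0)
            errs = []
            for seed in range(40):
                series = series_preset(
                    name, x_list=(0, 0.5, 1), noise=(0.05, 1.0), seed=seed
                )
                errs.append(abs(excess_gibbs_energy(series, 0.5, 30.0) - truth))
            assert np.median(errs) <= max(10.0, 0.05 * abs(truth)), name


class TestPseudoComponent:
    def test_wraps_one_to_one_mixture(self):
        iso = simulate_pure_isotherm(
            POPC, components=(("POPC", 0.5), ("SM", 0.5))
        )
        comp, wrapped = as_pseudo_component(iso)
        assert comp.component_id == "POPC:SM(1:1)"
        assert comp.role == "pseudo"
        assert wrapped.components == ((comp.component_id, 1.0),)

    def test_pure_film_rejected(self):
        iso = simulate_pure_isotherm(POPC, components=(("POPC", 1.0),))
        with pytest.raises(ValueError):
            as_pseudo_component(iso)

    def test_ideal_pseudo_binary_scan_is_null(self):
        from monothermo import PseudoEOS

        blend = PseudoEOS(members=((POPC, 0.5), (pure_preset("sm-brain"), 0.5)))
        series = simulate_mixture_series(
            blend, CHOL, (0, 0.25, 0.5, 0.75, 1),
            labels=("POPC:SM(1:1)", "CHOL"), roles=("pseudo", "sterol"),
        )
        scan = gibbs_composition_scan(series, 30.0)
        assert np.max(np.abs(scan.dg_exc)) <= 1.0


class TestMiscibility:
    def test_composition_dependent_collapse_is_miscible(self):
        """pi_coll varying linearly 69 -> 46 mN/m across X."""
        series = series_preset("chol-sm", x_list=(0, 0.25, 0.5, 0.75, 1))
        result = miscibility_from_collapse(series)
        assert result.verdict == "miscible"
        pis = result.table.sort_values("x2").pi_coll_mN_m.to_numpy()
        assert pis[0] == pytest.approx(69.0, abs=0.3)
        assert pis[-1] == pytest.approx(46.0, abs=0.3)
        assert np.all(np.diff(pis) < 0)

    def test_interior_echoing_endpoint_indicates_immiscibility(self):
        series = simulate_mixture_series(
            POPC, CHOL, (0, 0.25, 0.5, 0.75, 1),
            collapse_map=lambda x: 46.0 if x < 1.0 else 60.0,
        )
        result = miscibility_from_collapse(series)
        assert result.verdict == "immiscible-indication"

    def test_two_compositions_insufficient(self):
        series = ideal_series(x_list=(0.0, 1.0))
        with pytest.raises(InsufficientDataError):
            miscibility_from_collapse(series)


class TestAnalyticOracle:
    def test_endpoints_zero(self):
        excess = ExcessModel(alpha0=-8.0, alpha1=2.0)
        assert analytic_excess_gibbs(excess, 0.0, 30.0) == 0.0
        assert analytic_excess_gibbs(excess, 1.0, 30.0) == 0.0

    def test_constant_profile_algebra(self):
        excess = ExcessModel(alpha0=-8.0)
        got = analytic_excess_gibbs(excess, 0.25, 20.0)
        assert got == pytest.approx(6.02214076 * 0.25 * 0.75 * (-8.0) * 20.0)

    def test_linear_decay_matches_fine_quadrature(self):
        excess = ExcessModel(alpha0=-8.0, alpha1=3.0,
                             pressure_profile="linear_decay", pi_ref=45.0)
        x2, pi_t = 0.3, 30.0
        grid = np.arange(0.0, pi_t + 0.005, 0.01)
        numeric = 6.02214076 * np.trapezoid(excess.a_exc(grid, x2), grid)
        assert analytic_excess_gibbs(excess, x2, pi_t) == pytest.approx(numeric, rel=1e-3)
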