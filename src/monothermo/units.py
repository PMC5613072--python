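"""Unit system of the package.

Everything is carried in the units film-balance practitioners use:

* area per molecule  ``A``  in Å²/molecule,
* surface pressure   ``π``  in mN/m,
* temperature               in °C (converted internally to K).

Two derived constants do all the bridging:

``kT`` expressed in Å²·mN/m
    1 Å²·mN/m = 1e-20 m² · 1e-3 N/m = 1e-23 J, so
    k_B·T [Å²·mN/m] = 1.380649e-23 / 1e-23 · T[K] = 1.380649 · T[K].
    At 20 °C this is ≈ 404.7 Å²·mN/m.

``J_PER_MOL_PER_A2_MNM``
    N_A · 1e-23 J = 6.02214076 J/mol per (Å²·mN/m per molecule) — the
    factor that turns the excess-area integral ∫ A^exc dπ into a molar
    excess free enthalpy.
"""

#: Boltzmann constant in Å²·mN/m per kelvin.
BOLTZMANN_A2_MNM = 1.380649

#: Avogadro bridge: J/mol per (Å²·mN/m per molecule).
J_PER_MOL_PER_A2_MNM = 6.02214076

ZERO_CELSIUS_K = 273.15


def kelvin(temperature_c: float) -> float:
    """Convert °C to K."""
    return temperature_c + ZERO_CELSIUS_K


def thermal_area_pressure(temperature_c: float) -> float:
    """k_B·T in Å²·mN/m at a subphase temperature given in °C."""
    return BOLTZMANN_A2_MNM * kelvin(temperature_c)
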