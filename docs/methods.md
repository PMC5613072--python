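# Methods

This note documents the models, numerical choices and limitations
behind `monothermo`. Units throughout: area per molecule in
Å²/molecule, surface pressure π in mN/m, temperature in °C (K
internally), molar energies in J/mol. The single conversion constant is
k_B·T = 1.380649·T[K] Å²·mN/m, and the Avogadro bridge
1 Å²·mN/m per molecule = 6.02214076 J/mol.

## Isotherm model and preprocessing

An isotherm is one compression run. The canonical internal order is
compression order (area strictly descending); input order is
auto-detected and normalized with a stable sort, and exact duplicate
areas (barrier jitter) are averaged. Validation requires ≥ 10 points,
positive areas, mole fractions summing to 1 within 1e-9, and pressures
≥ −0.5 mN/m: small negative pressures are Wilhelmy-plate drift and are
retained (clipped to 0 for integration), anything lower indicates a
corrupted run and is rejected.

Smoothing is Savitzky–Golay (default window 11 points, order 2),
conservative for ≥ 200-point runs: it preserves the curvature of
transition plateaus that spline smoothing flattens, which matters
because plateau detection feeds both the transition and the collapse
logic. The filter reproduces polynomials of the fitted order exactly
when areas are evenly spaced and is idempotent up to numerical noise on
such data.

Regridding A(π) — needed to evaluate A₁₂, A₁, A₂ at common pressures —
uses shape-preserving PCHIP interpolation on the *maximal monotone
pre-collapse branch*: points up to the first attainment of the pressure
maximum, thinned to strictly increasing π by a backward scan that keeps
the most-compressed point of any flat stretch. This collapses the
gas-phase toe to a single node at the lift-off; below the lowest
recorded pressure the area is extended flat at that node. The
extension is the integration convention for the ΔG^exc lower limit of
exactly π = 0: data below the noise floor are unreliable, but the
integrand contributes ~0 there by construction.

## Descriptors

**Compression modulus.** C_s⁻¹ = −A·(dπ/dA) by centred finite
differences (`numpy.gradient`) on the optionally smoothed branch;
negative values arising from residual noise are floored at 0 and
counted. On noise-free Volmer films with ≥ 500 points the numerical
curve matches the closed form A·kT/(A−ω)² to well under 1% (the error
is O(h²·(A−ω)⁻²)). A known artifact: at slope discontinuities (plateau
onsets, linear-branch kinks) the smoothed derivative can overshoot by
up to ~6%, so recovered modulus maxima on piecewise synthetic films sit
slightly above the programmed value; tests budget 10% for this.

**State bands.** The literature names the states but not the
boundaries. We use the Davies–Rideal-style partition: C_s⁻¹max ≤ 12.5
gaseous, 12.5–50 liquid-expanded, 50–100 transitional (labelled LC with
a `transitional` flag), 100–250 liquid-condensed, > 250 solid. This is
consistent with the published assignments for brain SM (150 → LC), egg
SM (300 → S), 7-ketocholesterol (160 → LC) and cholesterol (830 → S).

**Lift-off.** The largest area at which π crosses
max(3σ_noise, 0.1 mN/m) and stays above it for 5 consecutive points
(robust to the ±0.01 mN/m sensor), the crossing refined by linear
interpolation. On an exactly linear film this sits threshold/slope
below the π = 0 intercept, so the invariant lift-off ≥ limiting area
holds only up to that (≤ 0.05 Å²) allowance in the degenerate case.

**Limiting area.** "Extrapolation of the last rectilinear segment" is
implemented literally: the fit window is anchored at the
most-compressed end of the branch and grown backwards to the longest
length (≥ 15% of the branch, ≥ 8 points) with R² ≥ 0.999; the anchor
may retreat by up to 5% of the branch past collapse-onset remnants.
Points below 0.5 mN/m are excluded (the flat gas toe is a perfect line
with a meaningless intercept). Anchoring matters: an LE→LC transition
plateau is long and straight but is not the condensed terminal regime.

**Collapse.** Three signatures, evaluated with slope analysis on the
smoothed channel but *reported from raw pressures* (smoothing biases
values at kinks): a pressure *drop* > 0.5 mN/m after the maximum, with
the onset refined by intersecting line fits on both flanks; a *plateau*
where |dπ/dA| < 0.5 mN/m/Å² holds for 5 points after the modulus
maximum (onset = median raw π over the first such run); and a *kink*
fallback via the slope ratio across a breakpoint. If drop and plateau
both fire, the lower-π onset wins. Both the onset and the mode are
reported; an undetected collapse is recorded as absent rather than
raised in the descriptor pipeline.

**Transitions.** A transition is a run of ≥ 5 modulus values below
20 mN/m flanked by maxima above 30 mN/m; the reported pressure is the
run onset, the conventional transition pressure. Runs touching either
end of the branch (gas toe, collapse region) are excluded, as are
sub-run-length noise dips.

## Mixing thermodynamics

A^exc and ΔG^exc follow the standard excess formalism (see README).
Integration is trapezoidal on a uniform π grid (default step
0.1 mN/m) from exactly 0 to the target; isotherm data are tabulated,
not functional, so adaptive quadrature would only chase interpolation
noise. The default reporting pressure is 30 mN/m (monolayer–bilayer
correspondence at 30–35 mN/m); tables are also emitted on a
5–35 mN/m grid because published bubble plots do not state their
pressures. The ΔG^exc minimum is reported at measured compositions
only; parabolic refinement exists behind a flag but is off by default —
composition grids are coarse and a refined minimum is convention, not
data. The sterol is endpoint 2 throughout (X = X_sterol), and ternary
films are treated strictly pseudo-binary (the 1:1 blend wrapped as one
endpoint); no Gibbs-triangle analysis.

Miscibility: the verdict is `miscible` when π_coll spans more than a
significance band (default 0.6 mN/m, three times the collapse-detection
uncertainty) and interior compositions do not merely echo one endpoint;
`immiscible-indication` when every interior collapse coincides with one
endpoint's value within the band; otherwise `inconclusive`.

## Synthetic data generator

The generator is the package's ground truth, standing in for
unpublished raw isotherms. Pure films follow one of three equations of
state:

* **Volmer** π = f·kT/(A − ω) − π_coh for liquid-expanded films. The
  dimensionless factor f (default 1) scales the thermal term; f > 1 is
  chain-cooperativity phenomenology, needed because a bare
  single-molecule Volmer film compressed to a 50 mN/m collapse
  necessarily shows C_s⁻¹ = (π+π_coh)²·A/kT well above the LE range.
* **Linear condensed** π = slope·(A₀ − A) for sterol-like films.
* **Piecewise LE/plateau/LC**: a Volmer LE branch meeting a transition
  plateau that *rises by 0.5 mN/m across its span* (real plateaus are
  slanted; an exactly flat plateau makes A(π) multivalued and poisons
  regridding with an arbitrary convention), then a linear condensed
  branch. Branch continuity is enforced at construction.

Collapse is programmed either as a hard plateau at π_coll or as a drop
of 10% of π_coll per 2 Å² beyond the failure area. Mixtures blend the
endpoint inverses ideally and add a Margules-type excess
A^exc = X(1−X)[α₀ + α₁(1−2X)]·g(π), g constant or a clipped linear
decay, chosen so ΔG^exc has a closed form (`analytic_excess_gibbs`).
Setting α₁ = α₀ puts the minimum at X = 1/3, the 2:1 complex
stoichiometry. Members are sampled uniformly in *area* (as a constant
barrier speed does), with the lift-off area an exact grid point to
avoid interpolation bias at the π = 0 kink, plus a gas toe and a
collapse tail.

**Noise model.** Two Gaussian components, chosen because the source
experiments state bounds, not distributions: per-point pressure noise
σ_π = 0.05 mN/m (five times the stated 0.01 mN/m sensor sensitivity,
allowing for drift) and a per-replicate area calibration offset
σ_A = 1 Å², which reproduces the stated ±2 Å²/molecule replicate
envelope at the 95% level. Within one mixture series the area offset
is *shared* by all members — one spreading/calibration session — so it
cancels exactly in excess quantities, as a common calibration error
does on a real trough; pure-film replicates draw independent offsets.
An independent per-member offset would instead inject ~200 J/mol of
spurious ΔG^exc scatter at 30 mN/m, which no published excess analysis
exhibits. Generators are pure functions of (parameters, seed).

**Presets.** Five pure films (`sm-brain`, `sm-egg`, `popc`, `chol`,
`7kc`) are calibrated *only* to published characteristic points:
lift-offs 91/78 Å² (brain/egg SM), collapses 69 (SM), 50 (POPC),
46 mN/m (sterols, with the 7-KC value following the published
temperature trend 47/46/43 mN/m at 10/20/30 °C), and modulus maxima
150/300/830/160 mN/m. All other parameters (plateau pressures, slopes,
Volmer constants) are free choices labelled as such. Six series
presets pair the sterols with POPC, brain SM and the POPC:SM 1:1
pseudo-component; the calibrated features are the 2:1
cholesterol:7-KC excess-magnitude ratio with POPC, the α₁ = α₀ skew
(minimum near X = 1/3) with SM, and the stronger 7-KC interaction in
the ternary system. Excess magnitudes themselves (α₀ of −5 to −12 Å²)
are plausible free choices: published ΔG^exc axes are unlabelled, so
magnitudes cannot be validated — only signs, minimum locations and
ratios.

## What the synthetic data do and do not show

The generator emulates: LE films, plateau-type transitions, condensed
films, collapse plateaus and drops, sensor noise and replicate
reproducibility. It does not emulate: curvature of real condensed
branches, hysteresis, barrier-speed or pH effects, nucleation kinetics
before collapse, or multi-component chain-length heterogeneity. Tests
passing on synthetic data therefore demonstrate the *analysis* is
correct and noise-robust at realistic levels; they do not validate the
equations of state as descriptions of any particular lipid.

## Problem sizes and determinism

Default runs use 500-point isotherms; oracle checks use 800–2000
points; Monte-Carlo properties use 100–200 seeded replicates, with the
acceptance script deriving all replicate seeds from a single `--seed`.
These sizes keep the full test suite and the acceptance script within
seconds on one CPU while leaving discretization errors one to two
orders of magnitude below the tolerances they are tested against.

## Known limitations

* The Margules excess form cannot produce a sign change that brackets
  an interior negative window (e.g. negative only for 0.4 < X < 0.8);
  reproducing such a pattern would need a higher-order composition
  polynomial.
* Collapse-pressure values for plateau collapses are plateau onsets;
  whether published values are onsets or pressure maxima is generally
  unstated, and for drop collapses the two coincide.
* The LE/LC/S band boundaries and the packing-parameter shape bands
  are conventions; users comparing against other work should check the
  boundary choices documented here and in `monothermo.geometry`.
* `describe()` uses an 11-point smoothing window by default; for very
  sparse isotherms (< ~100 points) pass a smaller window or `None`.
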