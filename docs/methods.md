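# Methods

## Scope and design

`nrpathways` separates a *data layer* — a synthetic study domain with a
closed-form chemistry surrogate — from an *analysis layer* (health burden,
attainment metrics, efficiency/regime diagnostics, pathway optimisation)
that only sees gridded concentration fields, populations and cost curves.
The analysis layer therefore works unchanged on fields from a full
chemistry-transport model; the NetCDF schema written by the pipeline
(dimensions `scenario, month, level, lat, lon`; species in µmol·m⁻³, mass in
µg·m⁻³; region mask and cell areas as auxiliary variables) documents the
drop-in interface.

## The SIA equilibrium surrogate

Per cell, month and level the surrogate resolves the ammonium-sulfate /
ammonium-nitrate partitioning in closed form:

* total ammonia availability `A = a_tot · E_NH3 · m_NH3 · (1 − x)`,
* total nitrate availability `TN = n_tot · E_NOx · m_NOx · (1 − y)^p_ox`,
* sulfate is neutralized first: `NH4_sulfate = min(A, 2·SO4)`, sulfate mass
  itself is unaffected by Nr controls,
* free ammonia `FA = max(0, A − 2·SO4)` forms ammonium nitrate:
  `NO3 = ε · smoothmin(FA, TN)`, `NH4 = NH4_sulfate + NO3`,
* `PM2.5 = background + 96·SO4 + 62·NO3 + 18·NH4` (g·mol⁻¹ weights).

Assumptions and their motivations:

* **`p_ox ≥ 1`** (default 2.0) encodes the oxidant feedback — deep NOₓ cuts
  reduce the atmospheric oxidising capacity, so HNO₃ responds
  sub-proportionally and β_NOx declines with depth. The true functional form
  of this feedback is not constrained here; a single exponent reproduces the
  qualitative decline and keeps the model invertible.
* **Monthly nitrate yield `ε`** (Jan 0.9, Apr 0.8, Jul 0.3, Oct 0.8)
  captures the thermodynamic suppression of ammonium nitrate in warm months.
  The G-ratio diagnostic is flagged unreliable for months with ε < 0.05.
* **Smooth minimum** (log-sum-exp with sharpness 25 by default) keeps the
  response surface kink-free for spline interpolation and finite-difference
  gradients; it never exceeds the exact minimum, so clipping at zero keeps
  all concentrations non-negative. Exact `min` (sharpness `None`) is used for
  analytic limit tests and the regime-equivalence sweep.
* **Mass closure is exact**: gas + aerosol ammonia equals `A`, gas + aerosol
  nitrate equals `TN`, so the surrogate conserves nitrogen by construction
  and PM₂.₅ is monotone non-increasing in both controls for any valid
  parameters (property-tested over random parameter draws).

With exact min, ε = 1 and fully neutralized sulfate, the per-mole
sensitivities of PM₂.₅ to `A` and to `TN` are 80 µg per µmol on the limiting
side and 0 on the other, so they cross exactly where `FA = TN`, i.e. at
G = 1 — the analytic anchor recomputed by `scripts/acceptance.py`.

## The synthetic domain and its calibration

The default grid is 10 × 14 cells over a European-like lat/lon box, split
West/East along a fixed longitude, with spherical cell areas; all regional
statistics are area-weighted (the weighting convention is the package's
choice). Annual means are arithmetic means of four representative months
(Jan, Apr, Jul, Oct).

Emissions are log-normal fields with shared hotspots. Regional totals are
fixed shares of the domain totals (defaults 4.4 Tg N NH₃, 3.7 Tg N NOₓ,
the 2015 European anthropogenic magnitudes used for calibration), with
Western-to-Eastern density ratios of 2.0 (NH₃) and 1.8 (NOₓ). NH₃ uses the
shared spatial pattern raised to the 1.8 power: ammonia is more concentrated
in source regions than NOₓ, so clean cells are relatively ammonia-poor.
Monthly factors peak in April for NH₃ (agricultural spring) and January for
NOₓ (heating/traffic winter), each averaging 1 over the four months.
Sulfate follows the NOₓ (combustion) pattern with exponent 0.7, normalized
to a domain-mean 0.025 µmol·m⁻³. The non-SIA background is composed of BC,
OC, dust and sea salt with SOA = 3×OC in July and 2×OC otherwise; the
Eastern region carries a roughly twice-heavier organic background.

These defaults were calibrated once, before the test suite was frozen, to
the qualitative structure the analyses presuppose: a Western region that is
NH₃-rich in its source areas (base G ≈ 2.9) with an Nr share of ≈ 30 %, an
Eastern region with a heavier background and Nr share ≈ 10 %, and clean
near-guideline Western cells that sit in the NH₃-limited regime so ammonia
control is what carries them below the annual guideline. The calibration
targets are soft (they tune the fixture); no test asserts them as
equalities.

What the generator does **not** emulate: transport and mixing between cells,
meteorology-driven variability, deposition, ozone chemistry, aerosol water
feedbacks, bidirectional ammonia exchange, or realistic emission inventories.
Passing tests therefore demonstrate the correctness and internal consistency
of the analysis chain on a structurally faithful response surface — not
quantitative agreement with any real airshed. Regional tipping points, for
example, land near the values a full transport model produces only because
the chemical regime structure is similar, not because the domain is Europe.

## Health burden

The hazard-ratio function is evaluated as
`exp(θ·log(z/α + 1)·logistic((z − μ)/υ))` with `z = max(0, c − cf)` and
cf = 2.4 µg·m⁻³. The `log(z/α + 1)` reading (rather than a literal
`log(z/(α+1))`, which is −∞ at z = 0) is the only one that yields RR = 1 at
the counterfactual and a continuous, non-decreasing risk curve; it is the
standard shape in this model family. Attributable deaths use the
attributable fraction `Base·Pop·(1 − 1/RR)`; the historical total-mortality
form `Base·Pop/RR` is available behind `as_printed=True` for audits.

Shape parameters (θ, SE, α, μ, υ per 12 adult age groups, 25–29 … 80+) are
study inputs read from CSV; the bundled `gemm_synthetic.csv` is a synthetic
fixture with plausible magnitudes, not published estimates. Only θ is
sampled in the Monte Carlo (Normal(θ, SE), independent across age groups,
10 000 draws, empirical 2.5/97.5 percentiles): θ carries the reported
uncertainty in this model family, and sampling the shape parameters would
require a covariance no input provides.

## Attainment metrics

Annual achievement is the area-weighted fraction of cells strictly below the
5 µg·m⁻³ annual guideline. Daily exceedance applies the 15 µg·m⁻³ threshold
to the regional-mean daily series; daily values are synthesized as
mean-preserving log-normal fluctuations about monthly regional means
(default CV 0.35, 30 days per represented month) — enough to exercise the
exceedance logic without a transport model. Required-reduction maps invert
the monotone control response per cell by bisection to 10⁻³ control
fraction, flag cells unreachable even at 100 % control, and resolve boundary
ties to the smaller reduction.

## Efficiency, regime, tipping points

β is computed on the 11-level grid from PCHIP-interpolated scenario values
(knots at 0/30/60/80/100 % are reproduced exactly; PCHIP cannot overshoot
between knots). Stencils: forward at L1, centred at L2–L10, backward at L11;
emissions are linear in the level, so denominators are the 10 % or 20 %
level gaps. Against fine-grid finite differences of the surrogate the
stencils agree to their truncation order (one-sided: (h/2)·|pm″|; centred:
(h²/6)·|pm‴|; verified on 100 random fixtures with derivative bounds
estimated from a 10⁻³ scan). Five knots cannot resolve the regime-crossover
region to better than a few percent of the response span; the measured
interpolation accuracy on a sharp single-cell fixture is stated in the tests
as < 8 % of the span.

The regional β is computed on the regional-mean curve (the per-cell
alternative is available by applying the same functions cellwise; the
regional-mean curve is the default because the scenario values being
interpolated are regional means). Tipping points interpolate the first sign
change of β_NH3 − β_NOx or G − 1 from the 0 % side; multiple crossings
report the first, matching the narrative that the difference turns positive
as cuts deepen. Molar normalisation divides β by the species' molar
emission total, making cross-species comparison per mole of N removed; in
the exact-min box model the molar equivalence point coincides with the G = 1
crossing up to the stencil width.

## Response surface and pathways

The 13 scenarios lie on the two axes and the diagonal of the control plane.
The surface is reconstructed by 1-D PCHIP splines along each ray plus a
triangular between-ray interpolation: a point with x ≥ y blends linearly
between the NH₃-only ray and the diagonal ray at level x (symmetrically for
y ≥ x). This choice was made after the more common separable-plus-correction
(Coons) blend proved badly non-monotone on min-structured chemistry,
corrupting the node values through the monotone clip. The triangular scheme
is exact on all three rays, exact for planar surfaces, continuous across the
diagonal, and monotone whenever the joint-control ray lies below the
single-species rays; a cumulative-minimum clip remains as a safety net.
Interior accuracy versus direct surrogate evaluation is stated in the tests
as < 25 % of the response span — a 13-point reconstruction of a
min-structured surface is a coarse object, and the tests measure rather than
hide that.

Gradients use centred differences inside, one-sided at the edges (matching
the β stencils on the axes, where −∂PM/∂x / PM_base equals β exactly).

The PM-optimal pathway is greedy steepest descent on the lattice with 10 %
steps, ties broken toward NH₃ (configurable by swapping the move order);
it stops at (1, 1) or when no move lowers PM₂.₅. Greedy descent is the
discrete reading of "follow the gradient"; it is *not* globally optimal for
increasing-returns surfaces, so an exhaustive monotone-lattice enumeration
oracle and a `path_optimality_gap` report are part of the public API. On
diminishing-returns (concave) surfaces greedy provably matches the
enumerated optimum at every path length; on general monotone surfaces the
gap is measured and reported.

Cost curves interpolate anchor scenarios (origin + printed cost checkpoints)
with monotone PCHIP and extend linearly at the spline's end derivative up to
the 50 % cap, beyond which evaluation is refused — cost data above 50 %
reductions are an extrapolation, and the mild linear extension deliberately
avoids inflating deep-control costs. Anchor sets are validated for strict
increase and convex chords. Cost surfaces are additive across species (the
underlying scenario structure is per-species and provides no cross-terms).
The cost-optimal path spends a total control budget of 0.5 ("halving Nr
emissions") in 10 % steps, each step taking the lowest incremental cost per
µg·m⁻³ abated; free moves with no abatement are allowed, paid moves with no
abatement are not.

## Numerical choices

* Seeds are explicit everywhere; the pipeline derives per-purpose sub-seeds
  from the config seed via SHA-256, so stages are independently reproducible
  and no global random state exists.
* G is masked (NaN), not infinite, where total nitrate < 10⁻⁹ µmol·m⁻³;
  area-weighted statistics drop masked cells.
* Monte-Carlo CIs are clamped to bracket the point estimate (relevant only
  in the degenerate SE → 0 limit, where draws and point coincide).
* Bisection searches run ⌈log₂(1/tol)⌉ iterations; required-reduction ties
  at the guideline resolve to the smaller control fraction (strict `<`
  comparison throughout, matching the attainment definition).
* The default pipeline domain (10 × 14 × 1, four months, 13 scenarios,
  10⁴ Monte-Carlo draws) runs end to end in a few seconds; problem sizes in
  the test suite are chosen at the same scale.

## Known limitations

* The surrogate's vertical structure (exponential decay of Nr faster than
  sulfate) is a placeholder that yields the qualitative G-declines-with-
  height profile; it is not a boundary-layer model.
* Cost anchors mix two published snapshots that are not mutually consistent
  at the percent level; the defaults follow the 10 %/30 % cost-effectiveness
  checkpoints, and the alternative feasibility anchors are exercised through
  explicitly supplied anchor sets.
* Greedy pathways on a 10 % lattice inherit the lattice resolution: the
  "optimal" pathway is optimal among lattice walks under the greedy rule,
  with the gap to the enumerated optimum reported, not bounded a priori.
* The daily-exceedance metric thresholds the regional-mean series (one
  value per day per region); per-cell daily exceedance aggregation is a
  different statistic and is out of scope.
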