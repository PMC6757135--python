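# Methods

## The damage model

Total p-tau damage is modelled as an area fraction multiplicatively
decomposed into three independently evolving internal state variables
(ISVs): nucleation η (number density of damaged regions, 1/cm²), growth v
(damaged area, cm²) and coalescence c (dimensionless interaction factor),

    φ(t) = η(t) · v(t) · c(t).

η·v already carries the units of an area fraction (1/cm² × cm²); c scales
it up as regions begin to interact. Nucleation and growth follow integrated
exponential laws in an effective strain surrogate ε(t), as does the
nearest-neighbor distance (NND) between region centroids; the coalescence
*rate* is driven by proximity,

    ċ(t) = C_coeff · (4d / NND(t))^ζ,

with d the characteristic region diameter (√area). At NND = 4d the rate
equals C_coeff exactly, and it grows steeply as regions approach within a
few diameters — the regime where stress-field interaction between
neighboring damaged regions accelerates damage. c(t) is obtained by
integration: in closed form whenever ε(t) = K·t (the integrand is then a
single exponential; the degenerate Q·ζ·K = 0 case is linear), or by
adaptive quadrature for arbitrary monotone schedules. The two routes agree
to better than 1e-8 relative over the calibration horizon and are checked
against each other, and against a refined-trapezoid oracle, in the tests.

### The strain schedule ε(t)

The laws are written in effective strain, but observations are indexed by
time (approximate age at death, or years of play). The package's default is
normalized time, ε(t) = t / t_ref with t_ref = 1, which makes fitted
exponents per-unit-normalized-time and directly comparable to the published
constants. Linear (ε = K·t) and tabulated monotone schedules are available;
built-in forms satisfy ε(0) = 0. The microstructural content of M, Z, Q —
each is in truth a lumped function of microstructure and local stress
state — is beyond what slice photographs can constrain and is not modelled.

### Constants and presets

Two published constant sets ship as presets:

| parameter | `section31_text` (default) | `table1` |
|---|---|---|
| η_coeff, M | 0.01, 5.338 | 0.01, 5.065 |
| v_coeff, Z | 0.016, 0.105 | 0.016, 0.105 |
| NND_coeff, Q | 9.36 cm, −0.114 | 117, −0.145 |
| C_coeff, d, ζ | 1.15, 0.024 cm, 2.9 | 1.15, 0.024 cm, 2.9 |

The sets disagree on the nucleation exponent and the NND pair; the source
does not reconcile them (the table pair may reflect a different ε(t)
normalization). The text values are the default because the stated
fit-quality claims are tied to them. Neither is altered here; both are
selectable by name.

The coalescence initial condition c₀ is not stated in the source; the
package uses c₀ = 1 (so φ = η·v before any interaction accrues), and it is
configurable. d is treated as a single fitted constant, not as the
time-varying √v(t); a time-varying mode would couple the growth and
coalescence laws and is deliberately not the default.

## Histology quantification

Slice images are thresholded globally (fixed value or Otsu; dark-object
convention: damage ≤ threshold, matching common particle-analysis
practice and well-defined on already-binary masks), connected components
are labeled (8-connectivity by default, 4 available), and per slice the
package reports the region count, nucleation density (count / A_total),
damaged area, damage % (100·A_damage/A_total) and the mean centroid-to-
centroid NND (an edge-to-edge variant is provided; the distance definition
used by the original analysis is not stated, and centroid distance is what
the standard NND plugins compute). A_total defaults to the full image frame
since the original background-exclusion rule is unknown; a tissue mask can
restrict it. The pixel→cm scale is a required explicit input — the source's
conversion is described only as approximate and is not recoverable.
Coordinates are pixel centers, x right / y down, 0-based; areas are pixel
counts × scale². Areas can be emitted in cm² or mm² (the source itself
prints both for the growth data, without reconciling them; the package
defaults to cm² and makes the unit explicit in column names).

With fewer than two regions the NND is reported as undefined (NaN /
explicit error), never zero — a zero would masquerade as "touching
regions" downstream of the coalescence law.

## Data conditioning and fitting

The source histology lacks per-slice ages, so each measured series is
sorted — nucleation, damaged area and damage % ascending, NND descending —
and paired positionally with an approximate-age grid. The default grid is
evenly spaced between the stage-1 and stage-4 mean ages at death
(28.3 → 77.4 years); this is a documented reconstruction of an unstated
rule, not the original grid, and is configurable. Damage stages map to
years of play as 7 / 13 / 15 / 20 (stages 1–4), obtained by splitting the
upstream cohort's two-level staging into two stages each.

Exponential laws are fitted by log-linear ordinary least squares by default
(positive data, exact on noiseless exponential inputs; nonpositive values
are rejected with their indices named). Nonlinear least squares on the
natural scale is available for comparison; the two agree to 1e-6 on
noiseless data. R² is reported in the space the loss was minimized in.
C_coeff, d and ζ are **not identifiable** from NND-vs-time data alone (they
enter only through c(t), which slices do not measure); they are adopted
from the chosen preset unless a measured coalescence series is supplied, in
which case ζ and C_coeff are fitted on log ċ vs log(4d/NND).

Noiseless round-trip recovery (generate from a preset → refit → same
constants to 1e-6 relative) is the core correctness surface and is tested
for both presets at the study's sample size (76 points).

## Synthetic data

The original 76 slice photographs are not deposited, so the generator
emulates exactly the features the pipeline measures:

* **Masks** — regions are built as the k nearest pixels to a sampled center
  (Euclidean metric for disks, Chebyshev for squares), which makes the
  damaged pixel count, and hence the area fraction, exact by construction;
  the per-stage fixtures use a 200×200 px canvas on which every published
  stage fraction (0.03–20.85%) is an integer pixel count, so quantification
  recovers the printed percentages exactly. Centers are placed by rejection
  sampling under a minimum-separation constraint (uniform placement — the
  source gives no spatial statistics beyond the NND); infeasible packings
  raise an error rather than silently truncating. Region counts and area
  fractions are seed-invariant; only placement varies.
* **Trajectories** — drawn from the ISV laws; noise, when requested, is
  multiplicative lognormal with unit mean (damage quantities are positive;
  the source states no error model). The coefficient of variation is the
  single noise knob.
* **Exposure tables** — largest-remainder apportionment of an annual impact
  total over G-level bins (ties toward higher G, conservative for injury
  exposure); the per-G-level proportions are an external measurement the
  source does not print, so they are a required user input and the bundled
  distribution is explicitly synthetic illustration.

What passing tests on these data do **not** show: robustness to staining
artifacts, anatomy (sulci, background tissue boundaries), heterogeneous
real region shapes, or the true age-assignment of the original analysis.
They show the measurement chain, the laws, the fitting procedure and the
exposure arithmetic are each correct and mutually consistent.

## Fatigue-life construction

Annual impact counts (lineman anchor 10,128/yr; quarterback 307/yr rescaled
by the cross-instrumentation ratio 10128·307/798 ≈ 3896) are binned by
G-level and accumulated over each stage's years of play. The strain-life
curve is the two-term form amplitude(2N) = A_e(2N)^b + A_p(2N)^c (elastic/
Basquin plus plastic/Coffin–Manson, both slopes negative, plastic steeper),
fitted on log axes with the elastic term initialized from the high-cycle
half of the data. The LCF/HCF transition is the asymptote intersection
2N_t = (A_p/A_e)^(1/(b−c)); parallel asymptotes or absent plastic term make
it undefined (error, not a sentinel value). Internally the cycle axis is
reversals 2N, with one head impact counted as one reversal, so reported
impact counts and reversals coincide. Data lying exactly on a single power
law are reported as pure-elastic rather than forcing a spurious second
term.

## Numerical choices

* Exponential laws are evaluated with `exp` directly; the coalescence rate
  is computed in log space (robust for tiny NND with large ζ).
* Quadrature tolerances: epsabs 1e-13 / epsrel 1e-11; closed-form vs
  quadrature agreement asserted at 1e-8 relative.
* Identity checks (φ = η·v·c) at 1e-12 relative.
* Largest-remainder apportionment uses a stable lexicographic sort
  (remainder, then G-level) so results are deterministic.
* Degenerate inputs fail loudly: zero total area, < 2 regions for NND,
  nonpositive values under a log loss, infeasible mask packings, fractions
  not summing to one, parallel asymptotes.

## Problem sizes

Tests and the acceptance script run at the study's own scale: 76-point
trajectories, 200×200 px fixture masks, 20-point strain-life sets, and
Monte-Carlo recovery over 200 seeds at 10% noise. These sizes were chosen
to mirror the study; the whole suite completes in seconds.

## Known limitations

* The model is a first-order continuum description; no biochemical cascade,
  finite-element stress field, or creep constitutive law is included (the
  source describes post-career progression qualitatively as tertiary creep
  but gives no equation).
* ε(t) and the original age grid are reconstructions; absolute exponent
  values are only meaningful relative to the chosen schedule normalization.
* The coalescence constants are preset-bound unless c(t) measurements
  exist, which slice histology does not provide.
* The published per-G-level impact distribution underlying the position
  curves is not available, so position-specific transition readings (e.g.
  a specific G-level at the LCF/HCF crossover) are out of scope; the
  construction procedure is implemented and tested on supplied tables.
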