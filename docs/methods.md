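# Methods

This note documents the models behind `carborne`, the assumptions they
make, the defaults and why, and what the test suite does and does not
demonstrate about real survey data.

## Energy bin scheme

The analysis grid is 22 contiguous bins over 0–3.2 MeV (nothing
terrestrial emits above the 2.615 MeV ²⁰⁸Tl line, so higher energies
index cosmic rays).  Five bins are fixed by the unfolding scheme:
bin 14 = 1.39–1.54 MeV (⁴⁰K), bin 16 = 1.69–1.84 and
bin 18 = 2.10–2.31 MeV (²¹⁴Bi), bin 20 = 2.51–2.72 MeV (²⁰⁸Tl), and
bin 22 = 3.0–3.2 MeV (cosmic index).  The remaining edges are not
uniquely determined by any published source; this package freezes a
tiling (`carborne.response.BIN_EDGES_MEV`) whose widths grow with
energy, roughly tracking NaI resolution.  This choice is an assumption;
any scheme honouring the five anchored bins would serve.

## Gamma line libraries

`carborne.nucdata` carries Beck-style line lists for ⁴⁰K, the ²³⁸U
series and the ²³²Th series under secular equilibrium, trimmed to lines
with intensity ≳1 % per parent decay (⁴⁰K: one line; U series: 22
lines, dominated by ²¹⁴Pb/²¹⁴Bi; Th series: 23 lines, dominated by
²¹²Pb/²²⁸Ac/²⁰⁸Tl, with the 35.9 % ²⁰⁸Tl branching folded in).
Disequilibrium (e.g. radon loss from soil) is out of scope: one
activity per series describes all daughters.

## Unit-flux library (semi-infinite ground source)

Flux densities 1 m above ground per unit activity concentration are
computed by a one-dimensional plane-geometry Monte Carlo
(`build_unit_flux_library`):

* geometry: homogeneous soil half-space (quartz-like dry soil,
  ρ = 1.6 g/cm³) under an infinite air layer (ρ = 1.205 mg/cm³);
  the source is uniform in the soil.
* sampling: emission depth uniform down to 10 mean free paths at the
  line energy (deeper emission cannot reach the surface at any relevant
  level); isotropic direction; lines chosen in proportion to intensity.
* transport: analog.  Total attenuation from embedded NIST-style
  μ/ρ tables (air, SiO₂ soil surrogate); Compton scattering with
  Klein–Nishina sampling of the scattered energy and angle;
  photoelectric absorption and pair production treated as absorption
  (annihilation photons are neglected — a percent-level effect at the
  2.615 MeV line only); photons are killed below 30 keV.
* tally: plane-crossing estimator w/|μ| at the detector height, with
  |μ| floored at 0.02 (a sub-percent bias that suppresses the
  estimator's log-divergent variance), split into primary (uncollided)
  and scattered components and binned at the crossing energy.

The uncollided flux has the closed form S_v/(2μ_s)·E₂(μ_a h), which the
test suite uses as an independent oracle; the Monte Carlo tally agrees
to better than a percent at 10⁵ histories.

Air kerma folds the binned flux with E·(μ_en/ρ)_air at each bin's
representative energy (the photopeak line for anchored bins, else the
bin centre).  The resulting kerma-per-activity coefficients are
0.042 (⁴⁰K), ≈0.39 (²³⁸U series) and ≈0.53 (²³²Th series) nGy/h per
Bq/kg at the defaults.  The ratios embedded in the published spot table
are 0.0418, 0.440 and 0.650: the model reproduces ⁴⁰K essentially
exactly and under-predicts the two series by 10–20 %, consistent with
the simplifications above (binned kerma folding, soil surrogate
composition, trimmed line lists, no annihilation photons).  The 25 %
agreement band used in the acceptance tests reflects this intended
fidelity.

Default 10⁶ histories per nuclide (a few seconds each, vectorised);
the test suite builds its shared library at 3×10⁵ histories to keep the
suite fast — Monte Carlo noise on the coefficients is then still well
below a percent.

## Detector response

The 22 × 22 response matrix is analytic, not a transport calculation:
for each incident energy, a Gaussian full-energy peak carrying the
photofraction plus a flat-in-energy Compton shelf from zero to the
Compton edge, scaled by a total-efficiency model (mean projected area
68.4 cm² and mean chord 5.08 cm of the 3 × 3 in cylinder with NaI
attenuation).  Photofraction and NaI μ/ρ come from coarse embedded
tables.  Escape peaks, backscatter and the edge-to-peak valley fill are
not modelled.  Because the synthetic spectra are generated with the
same column model evaluated on channel edges, simulation and analysis
are exactly consistent; agreement with a *real* NaI line shape is only
qualitative.

Resolution follows FWHM(E) = f₆₆₂·√(0.662·E) with f₆₆₂ = 7.5 % by
default.  DEF (diagonal-elements fitting) rebuilds the photopeaks for a
specific detector from FWHMs measured at 1.464 and 2.615 MeV via a
least-squares √E fit; the continuum is untouched and column sums are
conserved (peak mass is renormalised over the covered range).

## Calibration chain

Spot spectra are smoothed by truncated Fourier reconstruction (default
128 of 512 harmonics — chosen on synthetic fixtures as the smallest
order that neither biases peak location nor passes appreciable noise;
the DC term is kept so total counts are conserved exactly).  The ⁴⁰K
and ²⁰⁸Tl peaks are located by windowed maxima with log-parabolic
interpolation (exact for a Gaussian); windows are ±7 % around the
channels predicted by the header gain hint, wide enough for the few
percent of thermal gain drift the generator emulates while excluding
neighbouring spectral structure.  A two-point affine map (gain, offset)
follows; NaI zero offset is generally nonzero, hence affine rather than
proportional.

Environmental photopeaks sit on Compton continua and neighbouring peak
tails, which biases any local peak estimate by a fraction of a channel
(~0.5 % in gain).  `refine_calibration` removes this bias by
self-consistency: trial (gain, offset, f₆₆₂) → rebin → unfold →
project the unfolded flux back to channel space through the same
detector model → minimise the Poisson-weighted misfit (Nelder–Mead,
fit window fixed in channel space).  The true parameters are an exact
fixed point, so a noise-free spectrum calibrates itself to ~10⁻⁴
relative; on noisy spectra the refinement behaves like a template fit.
Thirty-second mobile records are never calibrated individually — their
statistics cannot support it — and enter only as total counts.

Rebinning apportions channel counts to energy bins by exact fractional
overlap via a piecewise-linear cumulative; total counts are conserved
exactly, with energies above 3.2 MeV dropped and sub-offset channels
folded into bin 1.

## Backgrounds

* Cosmic: modelled flat in energy above 0.5 MeV with amplitude indexed
  by the 3.0–3.2 MeV bin content; subtraction scales the template to
  the measured bin-22 content and clips negatives (flagged).  The flat
  shape and the default amplitude (0.3 cps in bin 22) are assumptions —
  no instrument background magnitudes are published for this survey.
* PMT ⁴⁰K: a pure-⁴⁰K response shape at a fixed instrument rate
  (default 1 cps, equally an assumption), subtracted as a known
  background spectrum scaled by live time.

## Unfolding and activity estimation

Counts → flux is a nonnegative least-squares solve against the response
matrix (condition number ≈ 10, so noise amplification is mild); Poisson
count variances propagate through the unconstrained pseudo-inverse,
which is exact wherever the nonnegativity constraint is inactive.
Activities come from the key-bin groups {14}, {16+18}, {20} via
successive approximation in the order Th → U → K; the interference
matrix is triangular in that order (nothing terrestrial above the
²⁰⁸Tl bin; ⁴⁰K emits nothing above bin 14), so the iteration converges
to the direct 3 × 3 solve, typically in two passes.  Covariances
propagate through the solve; per-nuclide kerma components are
activity × coefficient and percentage contributions are rounded
half-up.  The published survey quotes statistical errors of 2 % (kerma),
2 % (K), 6–8 % (U) and 4–5 % (Th) from an unpublished integral-kerma
formula; this package's linear propagation is a surrogate with the same
order of magnitude but a different dependence on the mix (here U is
usually the best-determined series because its group pools two
photopeak bins).

## Survey dose chain

K_out = 2·N_in·1.47·0.00244 nGy/h (the factor 2 converts a 30-s count
to cpm) and H = K_out·0.7·8760 converted to mSv/y.  Both calibration
factors are through-origin slopes — zero count rate must mean zero
kerma — fitted by least squares.  Region summaries report mean, median,
minimum and maximum dose at two significant figures (matching the
published table's precision), the coefficient of variation of the
*kerma rates*, and the fraction of records above 1 mSv/y.  Rasters use
fixed lon/lat cells (default 0.005°) anchored to cell multiples, cell
value = mean of contained points, empty cells flagged missing; exports
are CSV and GeoJSON.  Coordinates are WGS-84 decimal degrees;
distances use a local equirectangular scale, adequate at the ~20 km
scale of a Taluk.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of the real measurement —
photopeak positions and widths under gain drift, Compton continua,
cosmic and PMT backgrounds, Poisson counting noise, 30-s track
sampling at 40 km/h, coastal Th hotspots over a smooth background —
with every parameter known.  Defaults follow the survey's stated
conditions: 300/600/900 s spot live times, 30-s mobile interval,
1.47 / 0.00244 / 0.7 / 8760 constants, activities spanning the
published 42–2374 Bq/kg range.  It does not emulate real NaI spectral
detail (escape peaks, backscatter, summing), real soil stratigraphy or
moisture, radon washout, road geometry, or GPS error.  Passing tests
therefore demonstrate the *internal* correctness and statistical
calibration of the chain, not field accuracy; the only contact with
reality is the published spot and regional tables, used for the dose
arithmetic and the kerma-per-activity ratios.

The track simulator converts field kerma to expected counts through the
same two factors used in analysis, so the count → kerma round trip is
self-consistent by construction; its kerma coefficients default to
standard literature values (0.0417/0.462/0.604 nGy/h per Bq/kg) rather
than a Monte Carlo run, so tracks can be generated without transport.

## Numerical choices and degenerate inputs

* Successive approximation: relative tolerance 10⁻³, 50-pass cap,
  negatives floored at zero with a flag rather than silently truncated.
* NNLS is used for the unfold; an ill-conditioned matrix (cond > 10⁸)
  raises with the condition estimate.
* Noise-free "exactness" checks use long live times (3000 s): expected
  channel counts are quantised to integers, and at 300 s that
  quantisation — not the analysis — limits agreement to ~0.1 %.
* All randomness flows from explicit seeds (`numpy` Generators); the
  pipeline derives stage seeds from one root seed, and identical
  configurations produce byte-identical artifacts.
* An all-zero spectrum passes through smoothing unchanged with a
  warning; a flat spectrum raises a calibration-failure signal so a
  caller can fall back to a previous calibration.

## Known limitations

* The response model and soil surrogate cap the absolute accuracy of
  activity estimates at the 10–20 % level against real instruments;
  relative and statistical behaviour is faithful.
* The 3 × 3 group scheme assumes the U series contributes nothing above
  2.51 MeV and K nothing above 1.54 MeV — true for the line libraries
  used, but a detector with significant summing would violate it.
* Occupancy factors and building shielding are deliberately excluded:
  reported doses assume permanent outdoor exposure and so overestimate
  individual dose.
* Published per-Panchayat statistics depend on the undeposited 2053
  mobile records and cannot be recomputed here; the pipeline reproduces
  the arithmetic and the qualitative coastal/inland variability
  contrast instead.
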