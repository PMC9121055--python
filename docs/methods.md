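# Methods

This note documents the model implemented by `linacvsm`, its assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The virtual source model

The model is *purely binned*: no functional form is fitted to any particle
distribution. The scored conditional histograms are converted directly into
inverse-CDF lookup tables and sampled by inverse transform. The only fitted
quantity in the entire pipeline is the focal-spot Gaussian used to *split*
photons into two sources; it never shapes a sampled distribution.

### Dual-source photon split

Primary photons (bremsstrahlung from the target) form a narrow Gaussian
footprint when reverse-transported to the focal plane (Z = 0); photons
scattered in the flattening filter or collimators form a broad pedestal.
The classifier fits `A·exp(−(t−μ)²/2σ²)` per axis to the focal-plane
histograms (bin width 0.02 cm) restricted to |t| ≤ 0.5 cm — roughly 5σ for
a ~1 mm spot, far enough out to anchor the peak, close enough in that the
scatter pedestal stays nearly flat — with no baseline term by default (a
constant offset is available via `fit_baseline=True`). A Sheppard
correction `σ ← √(σ̂² − h²/12)` removes the variance inflation that binned
least squares would otherwise carry (h = 0.02 cm inflates a 0.05 cm spot by
~0.7%, a meaningful bias at the 5% recovery tolerance the package holds
itself to). The classification window is μ ± n_sigma·σ per axis with
n_sigma = 3 by default and exposed as a parameter; narrowing it (e.g. 2.5)
strictly shrinks the primary set.

Electrons and positrons are never classified: they are pooled into a single
charged group treated as pure scatter, because they are <1% of the beam and
splitting them would starve the histogram statistics.

### Histogram bank

Per group, five families: x; y conditioned on the x bin; kinetic energy
conditioned on the radial ring (rings of 0.5 cm up to R = 5.5 cm, one
overflow ring beyond — 12 rings); and direction residuals U′−U per x bin
and V′−V per y bin, with U′ ≡ X/Z, V′ ≡ Y/Z at Z = 26.7 cm. Residuals
rather than raw cosines are scored because particle directions follow their
geometric position on average, with small position-dependent fluctuations.

Bin widths — photons: 0.1 cm positions, 0.02 MeV energy, 0.0005 residuals;
charged: 0.2 cm, 0.05 MeV, 0.02 (coarser to reduce noise in the sparse
contaminant sample). The position support is fixed at ±5.5 cm rather than
data-driven so that the table geometry — and hence the model size — is
reproducible; out-of-support records are counted into the edge bins and
tallied in clipping counters. The residual support is ±1.25, which covers
any physically reachable residual for an in-support forward-going ray. The
energy support (0, E_max] is taken from the build options or, by default,
the data maximum rounded up to the next MeV (6 or 10 for the clinical beam
energies).

### Inverse-CDF tables

Each histogram is trimmed to its occupied extent, its CDF is linearly
interpolated within bins (piecewise-uniform density reconstruction), and
the generalised inverse is tabulated on the probability grid
{0, 0.00005, …, 1} — 20,001 points including both endpoints, so p = 0 and
p = 1 return the occupied support edges and no extrapolation ever occurs.
Interior zero-count bins are jumped across by dropping edges where the CDF
does not increase. Tables are monotone by construction and stored as
little-endian float32. Empty conditional histograms (sparse charged bins)
fall back to the group's marginal table so sampling stays total; fallbacks
are counted in the model provenance.

One beam configuration yields 864 tables: 3 x-marginals, 275 y|x
(110 + 110 photon bins + 55 charged), 36 E|R, 275 du|x, 275 dv|y — at
20,001 × 4 bytes each, 69,123,456 bytes of table data plus a ~3 kB JSON
metadata block (fit, fractions, geometry, index, provenance). Sizes are
reported in MB in the binary (2²⁰) sense used by `ls -h`/`du`.

### Sampling

Seven uniforms per particle, consumed in a fixed order (species;
primary/scatter or, for charged particles, electron/positron by the stored
positron share — the second uniform is otherwise unused for that branch;
x; y|x; du|x; dv|y; E|R). The conditioning bin is always the bin containing
the continuously sampled value, mirroring how the histograms were scored.
If a draw lands on u² + v² ≥ 1 the residuals are redrawn with fresh
uniforms (up to 100 times, counted); for physical models this is vanishingly
rare. The generator is numpy's PCG64 seeded explicitly, and each batch
draws its (n, 7) uniform block row-major, so streams are replayable and
chunked draws equal monolithic ones.

### First-order collimator transport

Between planes, straight-line propagation `x += (u/w)·dz` leaves
directions and energy untouched. Jaws are slabs with straight faces; MLC
leaves have tips modelled as a single circular arc (default radius 8 cm, a
typical rounded-leaf class value, configurable) tangent to the leaf faces
with no tip angle. Path lengths are exact chords from interval arithmetic
in the (axis, z) plane; an axial ray offset d from the tip-circle centre
sees the chord 2√(ρ²−d²). Transmission is first order: scattered-group
photons survive with probability exp(−Σμ(E)t) (analog) or carry it as a
weight; primary photons may additionally undergo exactly one Compton
interaction, with cos θ drawn by rejection from the Klein–Nishina
differential cross-section (the unnormalised density never exceeds its
forward value 2, so a flat envelope of height 2 is exact at every energy)
and uniform azimuth. In weighted mode both photon groups receive pure
attenuation weights; the single-Compton branch is analog-only. Charged
contaminants are absorbed on any geometric strike. μ(E) is a tabulated,
log-log-interpolated curve; a small approximate tungsten-like table is
built in for tests and defaults, and any table can be supplied.

### Validation statistics

Two histograms with counts n1i, n2i and totals N1, N2 are compared with

    X² = Σᵢ (N2·n1i − N1·n2i)² / (N1·N2·(n1i + n2i))

over non-empty bins, with dof = (non-empty bins) − 1. The model-vs-source
report samples the model, transports both populations to each requested
plane, and compares global x, y per plane plus single global u, v, E
histograms — at the scoring plane with the model's own 0.1 cm binning, at
downstream planes with 0.5 cm bins over ±50 cm, directions at 0.005,
energy at 0.02 MeV. Truncated comparisons keep ±18.5 cm downstream, ±0.19
in the cosines, and (0.1, E_max − 0.3) MeV, all overridable; the retained
probability fraction accompanies every truncated result. The negative
control (`shuffled_energy_model`) cyclically permutes the E|R tables,
which corrupts the energy marginal through radial softening while leaving
positions intact.

The gamma comparator uses global normalisation to the reference maximum
(the common QA convention), a low-dose threshold of 10% of that maximum,
and an exhaustive search of evaluated points within 3× the
distance-to-agreement criterion; no sub-grid interpolation is performed,
so γ is exact up to the evaluated grid's discretisation.

## Synthetic ground truth

The generator emulates a 6 MV-class beam scored 26.7 cm from the focal
spot: primaries originate from a Gaussian focal spot (σx = σy = 0.10 cm),
scatter and charged particles from a broad Gaussian plane (σ = 1.5 cm at
z = 10 cm); endpoints are uniform over the ±5.5 cm field window
(optionally x-y correlated through a Gaussian copula); directions are the
normalised origin→endpoint vectors plus Gaussian jitter (2×10⁻⁴ for
primaries — small enough that focal-plane blur, ≈ z·jitter ≈ 0.005 cm,
does not bias σ recovery; 0.05 for scatter); energies follow E·exp(−E/1.2 MeV)
for primaries and exponentials (0.5 / 0.8 MeV) for scattered/charged
particles, truncated to (0, 6] MeV, with characteristic energies scaled by
1 − 0.3·R/5.5 (floored at 0.3) to reproduce radial softening. Defaults:
84% of photons primary, 0.5% charged contamination, 10% of it positrons.

`truth_expectations` returns what the classifier should recover: the
jitter-blurred focal σ, the closed-form in-window probability
erf(3/√2)² = 0.994608 for a pure Gaussian beam, and the scatter leakage
into the window by quadrature over the exact reverse-transport relation
x0 = (1−a)·x + a·xs, a = Z/(Z−zs). Passing a fitted window evaluates the
same integrals for the window actually used, so classifier and oracle are
compared under identical conditions.

What the generator does **not** emulate: flattening-filter spectral
structure beyond the radial-softening knob, field-size-dependent scatter,
multiple scatter sources, non-unit statistical weights, or any fidelity to
a specific vendor head. Passing round-trip tests therefore demonstrates
that the model machinery is self-consistent and recovers known parameters —
not that it reproduces any particular clinical beam.

## Problem sizes and tolerances

The test suite and acceptance script run everything at desk scale, chosen
as the smallest sizes at which the statistical assertions have useful
power: models are built from 10⁶ particles in unit tests and 5×10⁶ in
end-to-end checks; χ² round trips sample 10⁶ particles per seed over 20
seeds and require every truncated comparison to pass p > 0.05 in ≥ 95% of
seeds; classifier recovery holds fitted σ within 5% at 10⁶ photons and the
pure-Gaussian classified fraction within 3 binomial σ of the closed form.
Statistical tests with a fixed seed are derandomised at seeds verified to
be unremarkable across neighbouring seeds, not selected for extremity.

## Known limitations

* The dual-source split is positional only; no energy- or angle-dependent
  classification, and no third photon source.
* Conditional structure is preserved only at histogram-bin resolution;
  correlations finer than a position bin (0.1 cm) are smoothed.
* First-order collimator transport ignores tongue-and-groove, interleaf
  leakage, leaf tilt, and all charged-particle transport in the modifiers.
* The built-in attenuation table is approximate and for testing; a
  measured μ(E) table should be supplied for any physical study.
* Statistical weights are carried through I/O but the modelling assumes
  unit weights throughout.
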