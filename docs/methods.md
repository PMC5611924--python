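# Methods

## The measurement being modelled

A pulsed near-infrared source (785 nm, repetition period 12.5 ns) at the tip
of an optical fibre embedded in turbid tissue emits photons within the
fibre's numerical-aperture cone. Photons reaching the imaged tissue surface
are collected by a lens onto a 32×32 SPAD array that timestamps single
photon arrivals in 50 ps TDC bins over the 12.5 ns window, accumulating a
per-pixel TCSPC histogram — a data cube of shape (32, 32, 250) — over many
pulse repetitions. Ballistic photons arrive at the geometric minimum
`t = d·n/c`; snake photons (few scattering events, path close to straight)
arrive slightly later; the diffuse cloud arrives with nanosecond-scale
delays and little spatial information. Localization rests on a single idea:
*the pixel whose histogram rises first marks the tip*, regardless of which
pixels are brightest.

## Photon transport

Transport is a voxel-resolved Monte Carlo walk:

- **Free paths** are sampled against the voxel-local scattering coefficient
  (`-ln u / μs`), traversing voxel boundaries exactly (DDA stepping), so
  heterogeneous media — e.g. a low-attenuation channel through a slab — are
  handled without approximation.
- **Absorption** uses continuous implicit-capture weighting: the statistical
  weight is multiplied by `exp(-μa·ℓ)` along every path segment rather than
  photons being absorbed at interaction sites. This makes the pure-absorber
  limit exact (exit weight `exp(-μa·d)`, Beer–Lambert) and lowers variance
  at the low-absorption conditions of the NIR optical window. Weights below
  1e-4 enter Russian roulette (survival probability 0.1, weight boosted
  1/0.1 on survival), applied both at scattering sites and during voxel
  traversals so that pure absorbers also terminate.
- **Scattering** uses the Henyey–Greenstein phase function (the standard
  single-parameter tissue model) via its closed-form inverse CDF; `g = 0`
  reduces to isotropic.
- **Boundaries are index-matched**: no Fresnel reflection or refraction at
  the exit face. Photons terminate on leaving the grid; only exits through
  the designated imaged face produce records.
- **Randomness** is counter-based: photon *i* of a run with seed *s*
  consumes its own splitmix64 substream derived from (s, i), so results are
  bit-reproducible and independent of batching or parallel order. The
  per-photon kernel is compiled with numba; the test suite contains a pure
  Python scalar mirror that consumes identical substreams and must agree
  record-for-record.

Transit time is `path × n / c` with `c = 29.9792458 cm/ns`, held exactly
(it is computed from the path, not accumulated separately). Classification
uses the **excess time** over the straight tip-to-exit flight: ballistic at
excess ≤ 1e-6 ps, snake up to 100 ps (~2 TDC bins), diffuse beyond 1000 ps
— thresholds chosen against the nanosecond-order delays of heavily
scattered light, and configurable.

## Camera model

- **Projection** is orthographic: exit position divided by the object-plane
  pixel pitch (1 cm default), half-open binning, with an angular acceptance
  gate (15° half-angle default) standing in for the lens aperture.
- **Detection** thins records by `PDE × fill factor × weight` (defaults 0.2
  and 0.01; the low fill factor is characteristic of early SPAD arrays and
  is what the throughput-rescaling estimate addresses).
- **Exposure scaling.** The `n` transported photons are treated as an
  unbiased sample of the per-pulse exit flux: a record contributes an
  expected `(pulse_count / n) × PDE × fill × weight` detections over the
  exposure, drawn as Poisson counts per record (default mode). This keeps
  expected cube totals independent of the simulated photon budget — the
  budget controls sampling noise, the exposure controls counting noise —
  at the cost of "blocky" histograms when very few records represent many
  counts. First-photon mode instead Poissonizes *candidate* arrivals per
  pixel, assigns them to frames of `m` pulses (default 160) and keeps only
  the earliest per frame, reproducing pileup distortion; it converges to
  the Poisson mode when per-frame occupancy is ≲1%.
- **IRF** jitter defaults to a Gaussian of 200 ps FWHM (σ ≈ 84.9 ps); a
  tabulated per-bin kernel (e.g. fast rise, slow tail) can be supplied.
  A 500 ps electronic trigger delay places the signal away from the window
  edge, as in any real TCSPC acquisition. Late (or jittered-negative)
  photons are discarded by default; a wrap-around mode exists.
- **Noise**: dark counts (default 40 Hz per pixel) and unsynchronised
  ambient background are Poisson and uniform across bins — unsynchronised
  light adds a *constant* offset to a TCSPC histogram, which is what makes
  operation under room lighting possible and baseline subtraction trivial.

## Localization pipeline

1. **Baseline subtraction**: per pixel, subtract the median over bins
   (default; robust while the pulse occupies a minority of bins), a
   pre-trigger mean, or a known rate; clamp at zero. Clamping intentionally
   breaks count conservation — subtracted cubes are analysis objects, not
   acquisitions, and are not persisted.
2. **Leading edge**: boxcar-smooth each trace (3 bins), find its peak,
   reject pixels below 10 peak counts, and interpolate the crossing of
   25% of the peak **on the peak's rising flank** (scanning back from the
   argmax to the last sub-threshold sample, then interpolating linearly
   between bin centres). Anchoring the crossing to the peak's own rise is
   the standard constant-fraction discriminator form; a first-crossing-
   anywhere rule proved fragile, latching onto isolated pre-pulse noise
   residues in weak pixels and faking early arrivals.
3. **Earliest arrival**: the valid pixel with the minimum leading-edge time
   wins. Ties within half a TDC bin are broken by the larger early-gate
   count (4 bins from the pixel's own edge), then by lowest (y, x) — fully
   deterministic. The margin to the second-earliest valid pixel and the
   runner-up list are reported as confidence diagnostics. Physical position
   is the pixel centre, `(pixel + 0.5) × pitch`, in field-of-view
   coordinates.

The early-gate width (4 bins = 200 ps) is a declared design choice: "early"
is not defined quantitatively by the measurement itself.

## Scenarios (what the generator emulates — and what it does not)

- **`milk_tank`**: homogeneous colloid (μs = 15 cm⁻¹, μa = 0.02 cm⁻¹,
  g = 0.8, n = 1.33, 15 cm tank), fibre 3 cm deep pointing perpendicular to
  the camera axis, so every detected photon has scattered at least once —
  the detected "ballistic" arrivals are in truth early snake photons, as in
  any realistic deep-tissue geometry.
- **`lung_slab`** (the localization study): 32×32×4 cm slab, μs = 10 cm⁻¹,
  g = 0.9, μa = 0.05 cm⁻¹, n = 1.4, tip 2 cm deep at (15.5, 15.5) cm,
  axis perpendicular to the camera; 10⁶ photons, 10 s exposure.
- **`torso_slab`**: thicker (8 cm), denser (μs = 12 cm⁻¹, μa = 0.07 cm⁻¹),
  tip 4 cm deep, 17 s exposure — a harder, lower-SNR regime.
- **`fibre_coil`**: light circulating a closed 16 cm loop imaged directly
  (no tissue); a point at arc position `s` on circuit `k` emits at
  `(s + k·C)·n_group/c` with intensity `loss^k`. The default group index
  1.3125 makes the circuit period ~700 ps for C = 16 cm; silica's ~1.47
  would give ~784 ps — the builder exposes both parameters rather than
  fixing one, since the two printed figures (period and circumference) are
  individually approximate. Defaults: 5 circuits, 50% loss per circuit,
  0.25 cm pitch so the ~5 cm coil fills the view.

Tissue optical coefficients for real organs are not established constants;
the presets are representative of soft tissue in the NIR, not calibrated to
any specimen. The generator omits anatomical structure (ribs, airways —
approximated only by the optional low-attenuation channel), Fresnel
boundaries, polarization, fluorescence, wavelength dependence, detector
dead-time/afterpulsing/crosstalk, and lens blur. Passing tests therefore
demonstrate the *method* — that earliest-arrival statistics localize a
buried source where amplitude does not — under idealized but
scattering-dominated conditions; they do not certify performance on any
particular organ.

## Numerical choices and problem sizes

- Voxel edge 0.5 cm for all tissue phantoms (media are piecewise
  homogeneous; the grid exists for heterogeneous variants).
- Photon budgets: 10⁶ for the slab studies (a single run takes on the order
  of ten seconds), 3×10⁵ for the milk tank (its higher μs makes each photon
  ~5× costlier), 10⁴ for smoke tests. The 20-seed recovery study runs at
  the full 10⁶ budget per seed.
- Leading-edge interpolation references bin centres; a trace already above
  threshold at bin 0 gets the first bin centre as its edge.
- Tie tolerance for localization: 0.5 TDC bin (25 ps).
- The transport kernel caps a photon at 4×10⁶ scattering events (a photon
  surviving roulette that long is terminated as absorbed); non-finite
  states raise with the photon index.
- Degenerate inputs: zero-exit runs return an empty record set with a
  warning (not an error); an all-invalid arrival map raises
  `InsufficientPhotonsError` carrying peak-count diagnostics.

## Known limitations

- The exposure-scaling model reuses each transported record for many
  expected detections; per-pixel histograms built from few records
  understate arrival-time diversity even though totals are unbiased.
- Orthographic projection ignores perspective and defocus; pixel pitch is
  taken as exact on the object plane.
- With the fibre perpendicular to the camera, the earliest-exit spot is
  biased by up to about one transport mean free path toward the emission
  direction — visible as the systematic one-pixel offset in the worked
  example, and inherent to the geometry rather than to the estimator.
- The first-photon mode models pileup within a frame but not TDC dead-time
  within a pulse train or inter-frame readout effects.
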