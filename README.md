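# fibreloc

Locating the tip of a fibre-optic probe deep inside scattering tissue by
imaging the **ballistic and snake photons** that escape with little or no
scattering, using a time-resolved single-photon camera.

Optical endomicroscopes and similar fibre devices are routinely pushed
beyond direct visual guidance (e.g. past a bronchoscope tip into a distal
lung segment), leaving the clinician with no precise knowledge of where the
fibre tip sits. In the near-infrared optical window (~700–900 nm, absorption
< 0.1 cm⁻¹), a pulsed source at the tip sends a small fraction of photons
almost straight through centimetres of tissue. These least-scattered photons
arrive at the surface *first*: ballistic photons at the geometric minimum
time `t = d·n/c`, weakly scattered "snake" photons slightly later, and the
diffuse cloud — bright but spatially uninformative — nanoseconds behind.
A SPAD array with per-pixel time-correlated single photon counting (TCSPC)
resolves this ordering, and the pixel with the earliest photon arrival marks
the fibre tip to roughly one pixel (~1 cm on the object plane).

`fibreloc` implements this measurement end to end as a simulator plus
analysis pipeline, for anyone studying time-gated imaging through turbid
media:

- **`fibreloc.transport`** — Monte Carlo photon migration from the fibre tip
  through a voxelized phantom (Henyey–Greenstein phase function, continuous
  absorption weighting, Russian roulette), with ballistic / snake / diffuse
  classification by excess transit time.
- **`fibreloc.camera`** — a 32×32 SPAD/TCSPC camera model: orthographic
  projection with angular acceptance, detection efficiency × fill factor,
  IRF jitter (200 ps FWHM default), 50 ps TDC binning over a 12.5 ns window,
  dark counts and unsynchronised ambient background (a flat histogram
  offset), and an optional first-photon pileup mode.
- **`fibreloc.scenarios`** — parameterized builders emulating canonical
  experiments: a fibre in a milk tank, lung-like and torso-like tissue
  slabs, and light-in-flight around a coil of fibre.
- **`fibreloc.localize`** — baseline subtraction, per-pixel leading-edge
  arrival estimation (constant fraction of the peak, interpolated on its
  rising flank), earliest-arrival localization with timing-over-amplitude
  tie-breaking, time-sliced images and spread statistics.
- **`fibreloc.cubeio` / CLI** — HDF5 cube container (schema v1), multi-page
  TIFF / PNG rendering, and a `fibreloc` command-line tool.

## Worked example

Simulate the lung-like slab (fibre tip 2 cm deep in a scattering slab with
μs = 10 cm⁻¹, g = 0.9, μa = 0.05 cm⁻¹, n = 1.4; 10⁶ photons) and localize
the tip:

```python
import fibreloc as fl

scenario = fl.get_scenario("lung_slab")
records, cube = fl.simulate(scenario, seed=1)
result = fl.locate_fibre(cube)
print("true pixel:", scenario.true_pixel())
print("located pixel:", result.pixel)
print("leading edge: %.1f ps, margin %.1f ps" % (result.arrival_ps,
                                                 result.margin_ps))
```

which prints

```
true pixel: (15, 15)
located pixel: (16, 15)
leading edge: 475.2 ps, margin 0.1 ps
```

The tip is recovered one pixel (1 cm) from truth. The leading edge sits
~93 ps (2 cm × 1.4 / c) plus IRF rise after the 500 ps trigger delay; the
tiny margin to the runner-up reflects that the neighbouring pixel over the
tip arrives essentially simultaneously — both are within the 1-pixel
resolution of the method. In the same cube, the image frame at the earliest
arrival time confines the source to 2 pixels above half maximum, while the
total (non-time-resolved) image spreads over the whole diffuse exit spot.

The same pipeline runs from the shell:

```sh
fibreloc simulate --scenario lung_slab --seed 1 -o lung.h5
fibreloc locate lung.h5 -o result.json
fibreloc render lung.h5 --stride 4 -o flight.tiff   # 200 ps per frame
fibreloc scenarios list
```

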