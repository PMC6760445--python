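# microed-tools

Conversion and quantitative diagnostics for microcrystal electron
diffraction (MicroED) movie stacks recorded on direct electron detectors.

The package provides:

- **frame_io** — readers for MRC2014 and TIA/SER movie stacks, the
  pedestal/negative-pixel policy (add a per-data-set constant, clip what
  stays negative, report the clipped fraction per frame), and a
  standards-compliant SMV writer whose header (DISTANCE, WAVELENGTH,
  OSC_START/OSC_RANGE, PIXEL_SIZE, BEAM_CENTER, ...) lets downstream
  data-reduction suites (MOSFLM/DIALS/XDS) reconstruct the diffraction
  geometry. No dark-current or flat-field corrections are ever applied.
- **geometry** — relativistic electron wavelength, resolution at a
  detector radius / at the detector edge, spot-separation estimates,
  per-frame oscillation, exposure ledgers and detector linear-range
  thresholds.
- **gain** — detector gain estimation from background pixels assuming
  Poisson counting statistics (index of dispersion var/mean), with
  optional spot exclusion by quantile and read-noise de-biasing.
- **reflection_tools** — asymmetric-unit mapping and unique-set
  generation for Laue groups −1 and 4/mmm, and merging statistics
  (completeness, multiplicity, R_merge, CC1/2, mean I/σ) on plain-text
  reflection tables (`h k l frame intensity sigma [tilt]`).
- **dose_analysis** — per-frame mean-intensity series with tilt and
  resolution filters, the shared exponential dose-decay fit
  `A_cryst * exp(-B_cam * x)` with derived D50 = ln 2 / B,
  completeness/multiplicity versus exposure, and Gaussian rocking-curve
  fitting.
- **synthetic_movie** — a ground-truth simulator (Poisson background ×
  gain, Gaussian-footprint Bragg spots, read noise, decay, rocking,
  subframe averaging) so every analysis is testable without real data.

## Command-line interface

All functionality is exposed through the `microed` entry point:

```sh
# synthesize a ground-truth movie + reflection table
microed simulate --preset falcon3 --frames 10 --size 256 --seed 1 --out sim/

# convert a native stack to per-frame SMV images
microed convert sim/movie.mrc --camera falcon3 --distance-mm 2380 --out smv/

# geometry calculators
microed geom edge-res --distance-mm 2380 --voltage-kv 200 --pixels 2048 --pixel-um 14 --bin 2
microed geom spot-sep --cell-a 68.2 --dmin 2.1 --half-width-px 256

# analytics
microed gain sim/movie.mrc --pedestal 0 --quantile 0.99
microed merge-stats table.txt --cell 68.2,104 --laue 4/mmm --dmin 2.7
microed decay c1.txt c2.txt c3.txt --cell 68.2,104 --rate 0.01 --texp 1.0
microed completeness table.txt --cell 68.2,104 --dmin 2.7 --cutoffs 0.2,0.4,0.8 --csv
```

Camera presets (`falcon3`, `cetad`) fill pedestal (8 / 128 ADU), gain
(1.0 / 14), subframe averaging (40 / 1) and rotation-speed defaults;
explicit flags always win over presets.

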