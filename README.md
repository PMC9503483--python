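# radarvitals

Simulation and analysis toolkit for studying how receiver delay-and-sum
beamforming affects phase-based vital-sign (breathing and heart rate)
extraction with a 60 GHz FMCW MIMO radar, across a grid of target distances
and arrival angles.

Because no human-subject radar recordings are available, a synthetic-data
pipeline stands in for them: a point-like chest target whose radial
micro-displacement is a sum of a breathing and a heartbeat sinusoid, observed
by a 2 TX x 4 RX radar forming an 8-element half-wavelength virtual uniform
linear array, with optional static clutter, additive complex noise, and a
parametric antenna-gain taper that weakens returns away from boresight.

## Modules

| module | contents |
| --- | --- |
| `radarvitals.scene` | chest-motion model, cosine-power antenna taper, scene assembly |
| `radarvitals.simulate` | chirp/IF-signal synthesis per virtual channel, frame/recording generation |
| `radarvitals.cube` | range FFT, radar data cube, chirp-averaged slow-time cube |
| `radarvitals.beamform` | steering weights, delay-and-sum, range-angle maps, AoA estimation, phase-alignment check |
| `radarvitals.vitals` | clutter filter, target-bin selection, phase unwrapping, dual band-pass rate estimation |
| `radarvitals.evaluate` | 15-point distance x angle grid, MAE / improvement tables, noise calibration |
| `radarvitals.io` | HDF5 cube container, YAML run configs, CSV sidecars |

## CLI

```bash
radarvitals grid-config --out grid.yaml           # canonical 15-point run config
radarvitals simulate --config grid.yaml --out recs/
radarvitals scan recs/recording_000.h5 --out-csv map.csv --out-fig map.png
radarvitals extract recs/recording_000.h5 --out rates.csv --beamform --angle 20
radarvitals evaluate --out report/ --seeds 6 --noise-std 8
```

`evaluate` writes per-angle and per-distance MAE tables (columns: Angle,
Without Beamforming, With Beamforming, Improvement (%)), a bar chart of the
heart-rate improvement per angle, the raw per-recording records, and a run
manifest.

## Notes on defaults

* The device profile publishes no ADC rate or samples per chirp; the
  defaults (256 complex samples spanning the 50 us chirp) are chosen so the
  unambiguous range is ~10 m at the native c/(2B) bin spacing. Tests use a
  cheaper profile (64 samples, 4 chirps/frame), which leaves the range-bin
  spacing unchanged.
* Chest displacement amplitudes (2 mm breathing, 0.3 mm heartbeat) are
  physiological stand-ins, not measured values.
* Band edges: breathing 0.1-0.6 Hz, heart 0.8-2.2 Hz; 30 s windows with 1 s
  stride and a 5-window moving mean.
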