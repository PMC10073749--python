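# ivnirf

Blood-attenuation correction for intravascular NIRF–IVUS pullbacks using a
fluorophore-coated guidewire as an in-situ reference.

Intravascular near-infrared fluorescence (NIRF) signals are attenuated by the
blood between the catheter sheath and the vessel wall, and the attenuation
changes from frame to frame as distances and blood properties vary. This
package implements a frame-by-frame correction scheme: a fluorophore-coated
guidewire imaged alongside the tissue provides a reference signal from which a
fresh blood attenuation coefficient is estimated in *every* frame, using a
one-time water calibration of the same guidewire. Tissue signals are then
corrected for the two-media path (water inside the sheath, blood outside) and
converted to fluorophore concentrations.

Because no experimental pullback data are distributed, the package ships a
synthetic pullback simulator reproducing the three experiment geometries
(slanted-guidewire water calibration phantom, four-capillary target phantom,
blood-perfused artery with an injected fluorophore bolus), which drives the
test suite and the acceptance report end-to-end.

## Layout

| module               | contents                                                        |
|----------------------|-----------------------------------------------------------------|
| `ivnirf.model`       | two-media exponential forward model and its inverse operations  |
| `ivnirf.calibration` | water-phantom calibration fit and distance→reference look-up    |
| `ivnirf.pipeline`    | per-frame segmentation, coefficient estimation, correction, concentration conversion, ground truth |
| `ivnirf.simulate`    | phantom/artery scene descriptions and pullback rendering, noise |
| `ivnirf.evaluation`  | accuracy/variance, fold improvement, agreement, coefficient-fit validation, distance-error sensitivity analysis |
| `ivnirf.io`          | HDF5 (primary) / CSV (fallback) pullback containers, JSON calibration files |
| `ivnirf.cli`         | `simulate`, `calibrate`, `correct`, `evaluate`, `sensitivity` subcommands |

## CLI

A full noiseless demo (simulate → calibrate → correct → evaluate):

```sh
ivnirf simulate --scene calibration --seed 1 --out calib.h5
ivnirf calibrate --input calib.h5 --out calib.json
ivnirf simulate --scene artery --seed 1 --out blood.h5
ivnirf simulate --scene artery --seed 1 --medium water --out control.h5
ivnirf evaluate --blood blood.h5 --control control.h5 \
    --calib calib.json --out report.json
ivnirf sensitivity --scene artery --seed 0 --unit-scale 1000 \
    --cb-true 0.0034 --out sensitivity.json
```

On noiseless inputs the reported accuracy is 100% by construction (the
correction is the exact algebraic inverse of the simulator's forward model).
Output containers ending in `.h5`/`.hdf5` use HDF5; any other path is written
as a directory of CSV files with a YAML metadata file. All stochastic paths
are seeded and bit-reproducible.

A note on units: attenuation coefficients are carried in inverse millimetres
throughout, matching the printed coefficient magnitudes. A `--unit-scale`
factor (e.g. 1000) switches scenes to the per-micrometre reading of the same
numerals, which is what makes attenuation material over sub-millimetre paths;
noiseless identities hold at either scale.

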