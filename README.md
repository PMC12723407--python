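# opmcal

Simulation, calibration and quality-assurance toolkit for high-density
triaxial OPM-MEG arrays.

Optically pumped magnetometers (OPMs) make it possible to build wearable MEG
helmets with hundreds of channels — e.g. 128 triaxial sensors giving 384
field measurements close to the scalp. Accurate source localisation with
such an array requires knowing, for every channel, its sensitive
*orientation* (which deviates from the sensor casing by up to ~20°), its
*gain* (empirically 0.8–1.4 rather than the nominal 1) and its *position*.
`opmcal` implements, end to end and in closed loop:

* **Synthetic arrays** with ground-truth geometry: a spherical-cap helmet
  with ~163 evenly spaced slots, cell–scalp offsets of 6.2 ± 5.0 mm,
  per-axis orientation offsets (X: 18.7 ± 7.3°, Y: 4.5 ± 2.0°,
  Z: 9.3 ± 5.4°), gains uniform in 0.8–1.4, and white sensor noise
  (17 fT/√Hz).
* **Matrix-coil calibration.** Eight reference fields are applied
  simultaneously, frequency-multiplexed at 3–10 Hz: three 0.2-nT uniform
  fields $B_x,B_y,B_z$ and the five independent gradients
  $\partial B_x/\partial x,\ \partial B_x/\partial y,\ \partial
  B_x/\partial z,\ \partial B_z/\partial z,\ \partial B_y/\partial z$ at
  2 nT/m. Demodulating the signed in-phase response of a channel at the
  three uniform-field frequencies gives $\mathbf b = B_u\,\mathbf g$;
  solving $\mathbf g = B_u^{+}\mathbf b$ yields the orientation
  ($\mathbf g/\lVert\mathbf g\rVert$) and gain ($\lVert\mathbf g\rVert$).
  The five gradient responses then give
  $\mathbf b_g = B_G\,\mathbf r$ with row $k$ of $B_G$ equal to
  $\mathbf g^{\mathsf T}G_k$, solved for the channel position
  $\mathbf r = B_G^{+}\mathbf b_g$. One second of data suffices.
* **Phantom QA.** A PCB phantom with five spiral-coil magnetic dipoles on a
  7.5-cm circle at 30° spacing, driven at 27 Hz (1 V pp through 56 kΩ,
  50 trials of 2 s on / 1 s off per dipole). Sessions are simulated,
  trial-averaged, and a point magnetic dipole is fitted (separable
  nonlinear least squares) independently at each of 100 drive extrema.
  Accuracy is scored pose-free by the 10 inter-dipole distances against the
  manufactured ground truth and by the Pearson correlation between measured
  and modelled field patterns — with calibrated geometry versus CAD-only
  geometry (casing axes, unit gains).
* **Array metrics.** Lead-field Frobenius-norm sensitivity curves
  ($\lVert\mathbf l\rVert \propto \sqrt{N}$) under random subsets and
  greedy best/worst sensor placement, homogeneous field correction
  ($M = I - OO^{+}$), Hilbert-envelope SNR, and flat-top-window PSD
  estimates with dead/noisy channel flagging.

## Worked example

```python
import numpy as np
import opmcal as oc

array = oc.default_array(seed=1)                      # 128 triaxial sensors
results = oc.ArrayCalibrationModel.from_array(array, seed=2).fit()
report = results.compare_to_truth(array)
print(report.summary().round(4))

phantom = oc.make_phantom()
session = oc.simulate_phantom_session(array, phantom, dipole_index=3, seed=3)
avg = oc.average_trials(session)
idx = oc.select_extrema(avg, session.protocol)
fit = oc.DipoleFitModel(avg[:, idx[0]], results).fit()
err = np.linalg.norm(fit.position - phantom.positions[2]) * 1e3
print(f"first-extremum fit: position error {err:.3f} mm, "
      f"correlation {fit.model_correlation:.6f}")
```

prints

```
     angle_error_deg         gain_ratio         position_error_mm
                mean     std       mean     std              mean     std
axis
X             0.0061  0.0034        1.0  0.0001            0.0166  0.0080
Y             0.0058  0.0031        1.0  0.0001            0.0151  0.0081
Z             0.0058  0.0034        1.0  0.0001            0.0180  0.0078
first-extremum fit: position error 0.019 mm, correlation 0.999998
```

The table shows how well a 1-s calibration window recovers each channel's
true orientation (millidegrees), gain (0.01 %) and position (tens of
microns) under 17 fT/√Hz sensor noise, grouped by casing axis. The dipole
fit then uses that calibrated geometry to localise a phantom coil to within
tens of microns with a field-model correlation of essentially 1.

A command-line interface mirrors the workflows
(`opmcal simulate-array | calibrate | phantom-sim | phantom-qa |
sensitivity | qa-psd`); every command writes a run manifest with its seed
and config hash so outputs are exactly reproducible.

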