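# dcrmotion

Quantitative assessment of lung-tumor (and motion-phantom) respiratory
motion from **dynamic chest radiography (DCR)** sequences.

In stereotactic body radiotherapy the treatment strategy depends on how
far the tumor travels with breathing.  DCR — pulsed flat-panel
radiography at 15 frames/s over up to 20 s — captures that motion
directly, over several consecutive breathing cycles, without the motion
artifacts and single-cycle limitation of respiratory-gated 4D-CT.
`dcrmotion` implements the complete measurement chain for such
sequences, for medical physicists and researchers who want objective,
reproducible motion numbers rather than a visual estimate:

1. **Tracking.**  A feature window (template) around the target is
   matched in each frame against a larger candidate window by the
   zero-normalized cross-correlation coefficient

   NCC(u, v) = Σ (T − T̄)(I − Ī) / √( Σ(T − T̄)² · Σ(I − Ī)² ),

   with quadratic sub-pixel peak refinement, confidence gating,
   template update and manual re-seeding.
2. **Calibration.**  Pixel excursions are converted to object-plane
   millimetres by the pixel pitch and the geometric magnification
   M = SDD / (SDD − OID); the motion amplitude is the peak-to-peak
   distance (peak exhalation vs peak inhalation over the whole
   acquisition).
3. **3-D combination.**  Per-patient, the superior-inferior (SI)
   amplitude is the mean of the vertical amplitudes of the AP and
   lateral projections; left-right (LR) and anterior-posterior (AP)
   come from the respective horizontal axes, combined as
   SRSS = √(SI² + LR² + AP²).
4. **Breathing-cycle analysis.**  Trough-to-trough segmentation yields
   per-cycle periods and amplitudes, exposing breathing irregularity.
5. **Statistics.**  Spearman rank correlation and the exact Wilcoxon
   signed-rank test compare paired amplitude sets (e.g. DCR vs 4D-CT),
   plus median/IQR summaries.

Because real acquisitions need hospital hardware, the package ships a
**synthetic motion-phantom generator**: a programmable-platform
emulation moving a 2-mm high-attenuation sphere in sinusoidal, diagonal,
parallelogram-orbit or irregular-breathing patterns over a textured,
noisy 16-bit background — with exact ground truth, so the entire chain
is validated end to end.

## Worked example

```python
from dcrmotion import (AcquisitionGeometry, MotionPattern, ProjectionGeometry,
                       project_and_sample, render_video, track_sequence,
                       peak_to_peak_amplitude, segment_cycles)

geom = AcquisitionGeometry(matrix_px=512)          # 15 Hz, 20 s -> 300 frames
pattern = MotionPattern(amplitude_mm=20.0, period_s=4.0, magnification=1.20)

truth = project_and_sample(pattern, geom)
stack = render_video(truth, geom, noise_sd=240.0, seed=1)
traj = track_sequence(stack, (truth.x_px[0], truth.y_px[0]))

proj = ProjectionGeometry(projection="PHANTOM", magnification_override=1.20)
amp = peak_to_peak_amplitude(traj, "y", proj)
print(f"measured amplitude : {amp:.2f} mm (platform setting 20.00 mm)")
print(f"absolute error     : {abs(amp - 20.0):.2f} mm")
for c in segment_cycles(traj, "y", proj):
    print(f"cycle {c.cycle_index}: period {c.period_s:.2f} s, "
          f"amplitude {c.amplitude_mm:.2f} mm")
```

```
measured amplitude : 20.03 mm (platform setting 20.00 mm)
absolute error     : 0.03 mm
cycle 0: period 4.00 s, amplitude 20.00 mm
cycle 1: period 4.00 s, amplitude 20.02 mm
cycle 2: period 4.00 s, amplitude 20.03 mm
cycle 3: period 4.00 s, amplitude 20.01 mm
```

A 20 mm platform motion under 1.20× magnification spans 60 px on the
detector; the tracker recovers it to 0.03 mm, and every 4-s cycle is
segmented with its period and excursion.

The same stages are available from the shell:

```sh
dcrmotion simulate --amplitude 20 --period 4 --magnification 1.2 --out video/
dcrmotion track video/ --seed-x 255.5 --seed-y 255.5 --pitch 0.4 \
          --frame-rate 15 --out traj.csv
dcrmotion analyze --ap traj.csv --magnification 1.2 --out report.json
dcrmotion phantom-eval --seed 0 --out errors.csv
```

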