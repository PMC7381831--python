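"""Closed-loop visual servoing: center the probe on a displaced fiber tip.

The source starts 6 mm off the lateral center line.  Each laser pulse the
frame is beamformed with SLSC, the target is segmented, and a proportional
velocity command moves the probe toward the segmented centroid.  The
median tracking error over the analysis window should be well below the
0.3-mm element pitch.
"""

import paslsc as P

geometry = P.ArrayGeometry(num_elements=48, pitch_mm=0.3,
                           sampling_frequency_mhz=40.0)
trajectory = P.make_trajectory("centering", prf_hz=10.0, offset_mm=6.0,
                               duration_s=5.0)
record = P.run_servo_experiment(
    geometry, trajectory, P.SourceSpec(x_mm=0.0, depth_mm=22.0),
    depth_mm=30.0, method="slsc", noise_snr_db=-15.0, seed=3,
)
print("frame  probe(mm)  desired(mm)  |error|(mm)")
for i in range(0, len(record), 5):
    print(f"{i:5d}  {record.probe_mm[i]:9.3f}  {record.desired_mm[i]:11.3f}  "
          f"{record.errors_mm[i]:10.4f}")
print()
print(f"median error {record.median_error_mm:.4f} mm, "
      f"IQR {record.iqr_error_mm:.4f} mm, "
      f"failed segmentations: {100 * record.failure_fraction:.0f}%")
print("The probe converges onto the 6-mm-displaced source within a few "
      "frames and then holds it at the center line.")
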