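"""Simulate one drinking event and reconstruct it from the two camera views.

Generates a ground-truth flight (approach loops, plunge, water contact,
departure), films it with two synthetic cameras (pixel noise, unknown frame
offset, Gray-code LED counter), then runs synchronisation, DLT calibration
and triangulation — and reports how far the reconstruction is from the truth.
"""

import numpy as np

import stereoflight as sf

config = sf.FlightConfig()
flight = sf.generate_flight(config, rng_seed=1)
recording = sf.simulate_recording(flight, rng_seed=2)

result = sf.process_recording(recording, flight_id=1)

print(f"flight duration        : {flight.t[-1] - flight.t[0]:.2f} s "
      f"({len(flight)} frames at {flight.fs:.0f} fps)")
print(f"true inter-camera offset: {recording.true_offset} frames, "
      f"recovered: {result.sync.offset} (confidence {result.sync.confidence:.1f})")
print(f"checkerboard reprojection RMSE: "
      f"{result.qc['reprojection_rmse_px'][0]:.2f} px (camera A)")
print(f"median triangulation residual : {result.qc['triangulation_residual_px']:.2f} px")

# compare the aligned reconstruction with the generator's own frame: the
# aligned frame equals the generator frame rotated so the sun sits at +X
sa = np.radians(flight.sun_azimuth)
Rz = np.array([[np.cos(-sa), -np.sin(-sa), 0], [np.sin(-sa), np.cos(-sa), 0], [0, 0, 1.0]])
truth = flight.com @ Rz.T
delta = result.trajectory.com - truth
delta -= delta.mean(axis=0)  # a constant offset is a frame convention, not error
print(f"median 3D reconstruction error: "
      f"{np.median(np.linalg.norm(delta, axis=1)):.2f} mm "
      f"(pixel noise {config.noise_sd_pixels} px, cameras ~1.2 m away)")
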