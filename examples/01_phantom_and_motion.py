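"""Build a phantom, inject a transient head nod, and recover it by realignment.

Prints the injected versus estimated position parameters for the motion
volume: the six numbers are mm translations (tx, ty, tz) and degree
rotations (pitch, roll, yaw) relative to the first volume.
"""

import numpy as np

from interpmotion import (
    MotionEvent,
    NoiseSpec,
    PhantomSpec,
    RigidTransform,
    compute_brain_mask,
    estimate_motion,
    inject_motion,
    make_phantom,
    simulate_bold,
)

phantom, labels = make_phantom(PhantomSpec())
scan = simulate_bold(phantom, 20, tr_s=2.5, labels=labels, seed=0)

nod = MotionEvent(
    onset_volume=10,
    displacement=RigidTransform(ty=-1.0, tz=0.8, pitch=2.0),  # nose-up nod
    duration_volumes=2,
)
moved, truth = inject_motion(scan, [nod], labels=labels)

trace = estimate_motion(moved, mask=compute_brain_mask(moved))

print("injected position at volume 10:", np.round(truth.volume_params[10], 3))
print("estimated position at volume 10:", np.round(trace.params[10], 3))
err = trace.params[10] - truth.volume_params[10]
print(f"worst parameter error: {np.abs(err).max():.4f} (mm or deg)")
print("A well-behaved estimator recovers the injected nod to ~0.01 of a")
print("voxel; the residual is the realignment noise floor on this phantom.")
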