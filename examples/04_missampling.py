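"""Audit what a mid-volume motion does to an interleaved acquisition.

When the head moves between slice acquisitions, the assembled volume is
not a warped brain but an incorrectly sampled one: some tissue slabs are
never scanned and others are scanned in two different slices.  The audit
projects every tissue voxel into acquired-slice coordinates under the
pre- and post-motion positions and reports both sets.
"""

import numpy as np

from interpmotion import (
    MotionEvent,
    PhantomSpec,
    RigidTransform,
    Scan,
    inject_motion,
    make_phantom,
    missampling_audit,
)

phantom, labels = make_phantom(PhantomSpec())
data = np.repeat(phantom[..., None], 12, axis=3).astype(np.float32)
scan = Scan(data, tr_s=2.5, slice_order="alt+z2", voxel_mm=(3, 3, 3), n_ignore=0)

# a nod with a 1.4-slice through-plane component, striking after the 8th
# slice acquisition of volume 5
event = MotionEvent(
    onset_volume=5,
    displacement=RigidTransform(tz=4.2, pitch=2.5),
    duration_volumes=2,
    onset_slice_acq=8,
)
_, truth = inject_motion(scan, [event], labels=labels)
missing, duplicated = missampling_audit(truth, event)

print(f"slice order {scan.slice_order}, motion after acquisition rank "
      f"{event.onset_slice_acq} of volume {event.onset_volume}")
print(f"tissue slabs never scanned in that volume:   {sorted(missing)}")
print(f"tissue slabs scanned twice in that volume:   {sorted(duplicated)}")
print("\nNo realignment can recover the never-scanned tissue; the volume is")
print("an incomplete, partially duplicated sample of the head.")
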