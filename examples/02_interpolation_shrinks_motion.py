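"""Show that despiking and slice-time correction reduce estimated motion.

One synthetic subject is realigned four times: on raw data and after each
temporal-interpolation state (DS = despiked, TS = slice-time corrected,
DS+TS = both).  Printed: mean framewise displacement (FD, mm) under each
state and the percent reduction relative to raw.  The motions in the scan
never change — only the processing applied before motion estimation does.
"""

import numpy as np

from interpmotion import CohortSpec, compute_brain_mask
from interpmotion.pipeline import process_and_realign
from interpmotion.synthetic import make_subject

scan, truth, record = make_subject(CohortSpec(seed=1), 0)
print(f"subject with {record['n_events']} transient motions, "
      f"amplitude scale {record['amplitude_mm']:.2f} mm, "
      f"true mean FD {record['true_mean_fd']:.3f} mm\n")

mask = compute_brain_mask(scan)
_, fds, ds_traces, _ = process_and_realign(
    scan, ["raw", "DS", "TS", "DS+TS"], mask=mask
)

raw_mean = fds["raw"].mean
print(f"{'state':>6}  {'mean FD (mm)':>12}  {'vs raw':>8}")
for order in ("raw", "DS", "TS", "DS+TS"):
    m = fds[order].mean
    rel = 100.0 * (raw_mean - m) / raw_mean
    print(f"{order:>6}  {m:12.4f}  {rel:7.1f}%")

print("\nEvery interpolation state reports less motion than the raw data —")
print("the scan did not get quieter, the interpolation blurred the motion.")

pct = ds_traces["DS"].percent
fd = fds["raw"].fd
print(f"\ncorr(raw FD, percent voxels despiked) = "
      f"{np.corrcoef(fd, pct)[0, 1]:.2f}")
print("Despiking concentrates at times of motion, like a censoring mask.")
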