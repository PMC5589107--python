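"""Demonstrate the scrubbing false negative caused by reduced FD traces.

A small cohort carries a motion-coupled, distance-dependent artifact.
Scrubbing (censoring high-FD volumes and measuring the change in ROI-pair
correlations, delta-r, versus inter-ROI distance) detects it as a negative
slope: close ROI pairs lose more correlation than distant ones.  Using the
FD trace estimated after despiking + slice-time correction censors fewer
volumes and recovers a shallower slope — the same artifact, half hidden.
"""

import numpy as np

from interpmotion import CohortSpec, scrubbing_analysis
from interpmotion.pipeline import run_cohort

spec = CohortSpec(n_subjects=6, n_volumes=100, artifact_gain=20.0, seed=101)
results, rois = run_cohort(
    spec, orders=("raw", "DS+TS"), roi_spacing_mm=9.0, roi_radius_mm=4.0
)
print(f"{len(results)} subjects, {len(rois)} ROIs, "
      f"{len(rois) * (len(rois) - 1) // 2} edges\n")

ts = [r.roi_ts["raw"] for r in results]          # the data never changes
fd_raw = [r.fd["raw"] for r in results]
fd_dsts = [r.fd["DS+TS"] for r in results]

for name, fds in (("raw FD", fd_raw), ("DS+TS FD", fd_dsts)):
    censored = sum(int((f.fd > 0.5).sum()) for f in fds)
    res = scrubbing_analysis(ts, fds, rois, threshold_mm=0.5)
    print(f"censor by {name:9s}: {censored:3d} volumes censored, "
          f"delta-r slope {res.slope * 1e3:+.3f} x 1e-3 per mm")

print("\nThe artifact is identical in both rows; the interpolated FD trace")
print("misses motions that raw FD catches, so less artifact is detected.")
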