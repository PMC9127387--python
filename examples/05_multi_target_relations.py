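"""Detection-free multi-target tracking with inter-target geometry.

Two tissue targets (a moving chin, a fixed spine anchor) are registered
manually and tracked independently; the chin-anchor distance series is
compiled after tracking — the quantity a clinician reads off a
forward-lean swallow.
"""

import numpy as np

from fluorotrack import make_scene, render
from fluorotrack.multitarget import TargetRegistry, register_target, run_online

seq, truth = render(make_scene("forward_lean", seed=0))
reg = TargetRegistry()
register_target(reg, "chin", "organ", 0, truth["chin"].boxes[0])
register_target(reg, "anchor", "organ", 0, truth["anchor"].boxes[0])

trajs, relations = run_online(reg, seq, seed=0)
pair = relations.pair("chin", "anchor")
d = [r.distance for r in pair]
print(f"tracked {len(trajs)} targets over {len(seq)} frames")
print(f"chin-anchor distance: {d[0]:.1f} px at start, {d[-1]:.1f} px at end")
print(f"the distance shrinks by {d[0] - d[-1]:.1f} px as the chin leans "
      "toward the spine anchor")
true_d = [np.hypot(truth["chin"].centroids[i][0] - truth["anchor"].centroids[i][0],
                   truth["chin"].centroids[i][1] - truth["anchor"].centroids[i][1])
          for i in range(len(seq))]
err = [abs(r.distance - true_d[r.frame_index]) for r in pair]
print(f"mean distance error vs ground truth: {np.mean(err):.2f} px")
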