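"""Aggregate per-window softmax scores of a 5-s evaluation three ways.

The reference worked example has three overlapping 3-s windows whose
individual predictions disagree (8, 0, 7; true class 7).  Majority voting
treats windows equally and, after the tie-break, picks the wrong class;
max aggregation lets the very confident third window decide and recovers
the true class.
"""

import numpy as np

from predann.evaluation import aggregate_majority, aggregate_max, aggregate_mean
from predann.synthetic import worked_example_scores

wp = worked_example_scores()
print(f"score matrix: {wp.n_windows} windows x {wp.n_classes} classes, "
      f"true class {wp.true_label}")
print("per-window argmax predictions:", np.argmax(wp.scores, axis=1))

for agg in (aggregate_mean, aggregate_max, aggregate_majority):
    res = agg(wp)
    mark = "correct" if res.predicted_class == wp.true_label else "wrong"
    print(f"{res.method:>8}: class {res.predicted_class} ({mark}); "
          f"evidence for class 7 = {res.per_class_evidence[7]:.3g}")
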