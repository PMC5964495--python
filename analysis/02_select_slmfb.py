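"""Apply the three-rule slMFB selection to every subject.

Selection: visit the 3 mm VTA sphere at (±6, −12, −8), connect a
frontal terminal (y > 18) with a basal terminal (z < −8), and stay in
one hemisphere. Writes per-subject selected bundles and a rejection
audit; in the phantom the temporal distractors fail the frontal/basal
rule and the commissural arcs fail hemisphere exclusivity.
"""

import collections
import json
import os

import bundledissect as bd
from common import cohort, results_dir

out = results_dir("selection")
summary = []
for sub in cohort():
    res = bd.select_slmfb(sub.tractogram)
    for side in ("right", "left"):
        bundle = res.selected(side)
        if len(bundle):
            bd.write_tractogram(bundle, os.path.join(out, f"{sub.subject_id}_slmfb_{side}.tck"))
    reasons = collections.Counter(r["failed"] for r in res.records if not r["passed"])
    summary.append({"subject": sub.subject_id, "n_input": len(sub.tractogram),
                    "n_right": len(res.right), "n_left": len(res.left),
                    "rejections": dict(reasons)})
    print(f"{sub.subject_id}: right {len(res.right)}, left {len(res.left)}, "
          f"rejected {dict(reasons)}")
with open(os.path.join(out, "selection_summary.json"), "w") as fh:
    json.dump(summary, fh, indent=2)
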