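"""Generate the phantom cohort and write it to disk.

Five subjects, 2000 streamlines each: ~80% prefrontal streamlines
through the VTA sphere split over eight parcels (38/35/24% dominant
targets), ~17% temporal distractors, ~3% commissural arcs. Outputs
per-subject TCK tractograms, the parcellation and scalar NIfTIs, and a
ground-truth JSON sidecar under results/cohort/.
"""

import json
import os

import numpy as np

import bundledissect as bd
from common import cohort, results_dir

out = results_dir("cohort")
for sub in cohort():
    sdir = os.path.join(out, sub.subject_id)
    os.makedirs(sdir, exist_ok=True)
    bd.write_tractogram(sub.tractogram, os.path.join(sdir, "tracks.tck"))
    bd.write_volume(sub.labels.grid.astype(np.int16),
                    os.path.join(sdir, "parcels.nii.gz"), space=sub.labels.space)
    for name, vol in sub.scalars.items():
        bd.write_volume(vol, os.path.join(sdir, f"{name}.nii.gz"))
    with open(os.path.join(sdir, "ground_truth.json"), "w") as fh:
        json.dump({"classes": sub.ground_truth.classes,
                   "proportions": sub.ground_truth.proportions,
                   "label_names": {int(k): v for k, v in sub.labels.names.items()}},
                  fh, indent=2)
    n_pref = sum("temporal" not in c and c != "commissural"
                 for c in sub.ground_truth.classes)
    print(f"{sub.subject_id}: {len(sub.tractogram)} streamlines "
          f"({n_pref} prefrontal, {len(sub.tractogram) - n_pref} distractors)")
print(f"cohort written to {out}")
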