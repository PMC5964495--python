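"""Fiber-density, group-probability and relative sub-bundle maps.

Renders per-subject streamline-length density maps on the 3 mm grid,
thresholds them at 1 mm per voxel, averages the indicators into group
probability maps, and computes relative maps for the three dominant
sub-bundles — whose share at the trunk bottleneck sits near their
global proportions (the ~30% trunk signature).
"""

import os

import numpy as np

import bundledissect as bd
from common import SPEC, cohort, results_dir

out = results_dir("density")
indicators = {"right": [], "left": []}
subjects = cohort()
for sub in subjects:
    res = bd.select_slmfb(sub.tractogram)
    for side in ("right", "left"):
        d = bd.render_density(res.selected(side), SPEC.space)
        ind = bd.threshold_indicator(d, 1.0)
        indicators[side].append(ind)
        bd.write_volume(d.grid, os.path.join(out, f"{sub.subject_id}_density_{side}.nii.gz"),
                        space=SPEC.space)
for side, inds in indicators.items():
    g = bd.group_average(inds)
    bd.write_volume(g.grid, os.path.join(out, f"group_probability_{side}.nii.gz"),
                    space=SPEC.space)
    print(f"group probability map ({side}): "
          f"{np.count_nonzero(g.grid == 100.0)} voxels present in all "
          f"{g.n_subjects} subjects")

sub = subjects[0]
gt = sub.ground_truth
right_idx = [i for i, c in enumerate(gt.classes)
             if c.startswith("rh-") and "temporal" not in c]
t_right = sub.tractogram.subset(right_idx)
classes = [gt.classes[i] for i in right_idx]
vox = tuple(np.rint(SPEC.space.world_to_voxel([6, -12, -8])).astype(int))
print("\nrelative sub-bundle share at the VTA bottleneck (sub-01, right):")
for parcel in ("superiorfrontal", "rostralmiddlefrontal", "lateralorbitofrontal"):
    sub_t = t_right.subset([i for i, c in enumerate(classes) if c == f"rh-{parcel}"])
    rel = bd.relative_map(sub_t, t_right, SPEC.space)
    bd.write_volume(rel, os.path.join(out, f"sub-01_relative_{parcel}.nii.gz"),
                    space=SPEC.space)
    print(f"  {parcel}: {rel[vox]:.1f}%")
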