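"""Extract the gray-white junction surface of a folded phantom and compute
the three folding metrics: lobar surface area, local gyrification index
(LGI) and sulcal depth.

A folded phantom (radial perturbation of the white-matter core) is meshed,
each vertex is assigned its parcellation region, and the metrics are
computed against the convex hull: the whole-surface hull for LGI, one hull
per hemisphere for depth.
"""

import numpy as np

from fetalfold import (
    LGIParams,
    PhantomSpec,
    aggregate_features,
    assign_regions,
    convex_hull_mesh,
    extract_junction_mesh,
    local_gyrification_index,
    make_phantom,
    sulcal_depth,
)

spec = PhantomSpec.create(
    wm_radius=25.0, fold_amplitude=0.12, spacing=(1.25, 1.25, 1.25),
    with_accessories=False,
)
seg, parc = make_phantom(spec, seed=0)
mesh = extract_junction_mesh(seg, ("wm",))
assign_regions(mesh, parc)
print(f"junction mesh: {len(mesh.vertices)} vertices, area {mesh.area:.0f} mm^2")

hull = convex_hull_mesh(mesh, "both")
lgi = local_gyrification_index(mesh, hull, LGIParams(patch_radius=12.0))
depth = np.full(len(mesh.vertices), np.nan)
for hemi in ("left", "right"):
    d = sulcal_depth(mesh, convex_hull_mesh(mesh, hemi))
    depth = np.where(np.isnan(d), depth, d)

feats = aggregate_features(mesh, lgi, depth)
print(f"{'lobe':<10} {'area mm2':>9} {'mean LGI':>9} {'depth mm':>9}")
for lobe in ("frontal", "parietal", "temporal", "occipital", "global"):
    print(
        f"{lobe:<10} {feats.area[lobe]:>9.0f} {feats.mean_lgi[lobe]:>9.3f} "
        f"{feats.mean_depth[lobe]:>9.2f}"
    )
print(
    "\nLGI > 1 and positive depth reflect cortex buried in the synthetic "
    "folds; on an unfolded phantom LGI is ~1 and depth ~0."
)
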