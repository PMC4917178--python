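"""Inspect how a fused object is analysed and split.

Constructs three nuclei fused along z (the hard case for slice-wise
segmentation: no derivatives are taken along z), shows their voxel frequency
profiles and the mnp estimate, then splits with K-means and GMM+AIC.
"""

import numpy as np

from dsseg import REFERENCE_SPACING
from dsseg.core import SegmentedObject
from dsseg.postprocess import axis_profiles, estimate_mnp, gmm_aic_split, kmeans_split

spacing = REFERENCE_SPACING
zz, yy, xx = np.mgrid[0:40, 0:60, 0:60].astype(float)
x = (xx + 0.5) * spacing.dx
y = (yy + 0.5) * spacing.dy
z = (zz + 0.5) * spacing.dz
inside = np.zeros(zz.shape, dtype=bool)
for cz in (10.0, 16.0, 22.0):  # three nuclei stacked along z, 6 um apart
    inside |= ((z - cz) / 4) ** 2 + ((y - 15) / 2) ** 2 + ((x - 15) / 2) ** 2 <= 1
obj = SegmentedObject(1, np.argwhere(inside), spacing)

px, py, pz = axis_profiles(obj)
print(f"fused object: {obj.volume} voxels")
print("z-profile (voxels per slice):", pz.counts.tolist())
print(f"peaks per axis: x={len(px.peaks)} y={len(py.peaks)} z={len(pz.peaks)}")
print(f"mnp (max peaks over axes) = {estimate_mnp(obj)}  -> estimated number of fused nuclei")

for split in (kmeans_split, gmm_aic_split):
    sr = split(obj, seed=0)
    zs = sorted(round(float(c.centroid_um[2]), 1) for c in sr.children)
    print(f"{sr.method:7s}: {len(sr.children)} children, z-centroids {zs} (truth: 10, 16, 22)")
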