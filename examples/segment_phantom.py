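"""Measure fatty infiltration on a phantom with known composition.

Generates an ellipsoidal muscle phantom with 2.5% true fat-to-muscle
proportion (FTMP), runs threshold segmentation and label statistics, and
repeats with partial-volume mixing at the fat boundaries enabled to show
the gray-zone underestimation mechanism.
"""

import dataclasses

from fivol import PhantomSpec, compute_volumes, generate_phantom, segment_tissues

spec = PhantomSpec(target_ftmp=2.5, seed=7, shape=(48, 48, 12), fat_pattern="clustered")

for label, s in [("sharp boundaries", spec),
                 ("partial-volume mixing", dataclasses.replace(spec, partial_volume_width=1))]:
    volume, roi, truth = generate_phantom(s)
    result = compute_volumes(segment_tissues(volume, roi))
    print(f"{label}:")
    print(f"  true FTMP       : {truth.true_ftmp:.3f} %")
    print(f"  measured FTMP   : {result.ftmp:.3f} %")
    print(f"  muscle volume   : {result.muscle_volume:.1f} mm^3")
    print(f"  fat volume      : {result.fat_volume:.1f} mm^3")
    print(f"  gray-zone volume: {result.unclassified_volume:.1f} mm^3")

# With sharp boundaries the measured FTMP equals the generated truth
# exactly. With boundary mixing, interface voxels carry averaged signal
# below the fat floor, so fat is lost to the gray zone and the muscle
# window and the measured FTMP drops: thresholding underestimates fat
# where voxels straddle tissue boundaries.
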