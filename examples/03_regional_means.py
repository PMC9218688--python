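"""Recover regional tendon SWV from a reconstructed volume.

Masks the SWE volume to the tendon, splits it into proximal / mid-portion /
distal regions by cuts 10 mm from each insertion landmark, and compares the
regional means against the phantom's ground truth.
"""

import numpy as np

from tendonswe import (SweepConfig, TendonPhantom, VoxelGridSpec, apply_mask,
                       compound, partition_regions, pixel_world_positions,
                       rasterize_phantom_mask, regional_means, simulate_sweep)

phantom = TendonPhantom()
cfg = SweepConfig(n_frames=96, frame_rows=24, frame_cols=64,
                  pixel_spacing=0.5, swv_noise_sd=0.5,
                  pose_noise_rot_deg=0.5, pose_noise_trans_mm=0.5, seed=0)
frames = simulate_sweep(phantom, cfg)
pts = np.concatenate([pixel_world_positions(f).reshape(-1, 3) for f in frames])
spec = VoxelGridSpec.bounding(pts, 0.5)
swe, _ = compound(frames, spec)

for inset, label in ((0.0, "full mask"), (1.25, "interior (1.25 mm inset)")):
    mask = rasterize_phantom_mask(phantom, spec, inset=inset)
    labels = partition_regions(mask, cut_distance=10.0)
    rs = regional_means(apply_mask(swe, mask), labels, mask.tendon_length)
    print(f"\n{label}: {rs.counts['overall']} voxels")
    for region in ("proximal", "mid", "distal"):
        est = getattr(rs, region)
        true = phantom.swv_true[region]
        print(f"{region:>9}: estimated {est:.2f} m/s  (truth {true:.2f}, "
              f"bias {est - true:+.2f})")
# Full-mask means are biased low: voxels at the tendon surface blend the
# 2 m/s background through the compounding kernel (partial-volume effect,
# present in real masked reconstructions too).  One kernel-radius inside the
# surface the plateaus are recovered closely.
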