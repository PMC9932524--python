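"""Reconstruct an OCT volume of an implanted construct and find its cyst.

Renders swept-source interferograms of the in-vivo preset (shrunken construct
with a subsurface cyst), reconstructs the log-magnitude volume, and reports
every hypoechoic region the detector finds.
"""

import numpy as np

import flimoct as F

phantom = F.build_phantom(F.preset_spec("week4_invivo", seed=3))
stack = F.render_oct_fringes(phantom)
volume = F.reconstruct_volume(stack)

print(f"volume {volume.shape} voxels, axial pitch "
      f"{volume.axial_pitch_um:.2f} µm, lateral pitch "
      f"{volume.lateral_pitch_um:.0f} µm")
surf = volume.surface_map[volume.surface_map >= 0]
print(f"surface at depth index {int(np.median(surf))} "
      f"({np.median(surf) * volume.axial_pitch_um:.0f} µm optical path)")

regions = F.detect_hypoechoic_regions(volume)
print(f"\nhypoechoic regions found: {len(regions)}")
for i, r in enumerate(regions):
    z, fast, slow = r.centroid
    print(f"  region {i}: {r.volume_voxels} voxels, "
          f"contrast {r.mean_contrast_db:.1f} dB, centroid depth "
          f"{z * volume.axial_pitch_um:.0f} µm at lateral ({fast:.0f}, {slow:.0f})")

# Exactly one region should appear: the simulated cyst, ~15 dB darker than
# the surrounding scattering tissue, centered mid-slab -- the OCT counterpart
# of the histology finding that motivates nondestructive screening.
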