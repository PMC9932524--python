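"""Render a mature construct phantom and recover its FLIm parameter maps.

Builds the default week-4 in-vitro phantom (5 mm disk, collagen-rich rim,
central void), renders the raw time-multiplexed scan, deconvolves every pixel,
and prints the recovered channel lifetimes at the rim and the center.
"""

import numpy as np

import flimoct as F

phantom = F.build_phantom(F.preset_spec("week4_invitro", seed=1))
scan = F.render_flim_scan(phantom)
stack = F.snr_filter(F.process_scan(scan))

valid = stack.valid_mask()
H, W = stack.shape
rows, cols = np.mgrid[0:H, 0:W]
r_hat = np.hypot(rows - phantom.center_px[0], cols - phantom.center_px[1]) \
    / phantom.radius_px

print(f"foreground pixels: {int(phantom.foreground_mask.sum())}, "
      f"SNR-25 survivors: {stack.meta['snr_survivors']}")
for c in range(4):
    lt = stack.lt_maps[c]
    edge = np.nanmean(lt[valid & (r_hat > 0.88)])
    center = np.nanmean(lt[valid & (r_hat < 0.35)])
    print(f"CH{c + 1} lifetime: rim {edge:5.2f} ns   center {center:5.2f} ns")

err = stack.lt_maps[0][valid] - phantom.true_lifetime_maps[0][valid]
print(f"channel-1 recovery RMSE vs ground truth: "
      f"{np.sqrt(np.nanmean(err ** 2)) * 1000:.0f} ps")

# The rim reads ~0.2 ns longer than the center in channels 1-2 (collagen
# deposition at the periphery), while channels 3-4 stay nearly flat
# (cell-dominated emission); the RMSE line shows the deconvolution tracks
# the simulated truth to well under the +-5% tolerance band used for the
# homogeneity index.
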