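"""Variable-flip-angle T1 mapping on a digital phantom.

Simulates the two-phase SPGR acquisition (flips 1/7/14 deg, TR 5.79 ms) of
a liver phantom carrying one G1-like lesion under a smooth B1 field with
acquisition noise, fits T1 maps with B1 correction, and recovers the
lesion's reduction rate.
"""
import numpy as np

import hepquant as hq

spec = hq.PhantomSpec(
    grid_shape=(24, 24, 12),
    spacing_mm=(2.0, 2.0, 3.0),
    b1_range=(0.85, 1.15),
    noise_sd=0.8,  # SNR ~ 52 on the 14 deg volume
    lesions=(hq.LesionSpec(center_mm=(24.0, 24.0, 18.0), radius_mm=10.0),),
)
phantom = hq.simulate_phantom(spec, seed=1)

plain = hq.fit_t1_map(phantom.plain_volumes, phantom.b1, spec.acquisition)
hbp = hq.fit_t1_map(phantom.hbp_volumes, phantom.b1, spec.acquisition)
print(f"invalid voxels: plain {plain.n_invalid}, HBP {hbp.n_invalid}")

uptake = hq.lesion_uptake(plain, hbp, phantom.lesion_masks[0])
truth = hq.reduction_rate(spec.lesions[0].t1_plain_ms, spec.lesions[0].t1_hbp_ms)
print(f"lesion mean T1: plain {uptake.t1_plain_ms:.1f} ms, HBP {uptake.t1_hbp_ms:.1f} ms")
print(f"reduction rate: {uptake.reduction_rate:.4f} (ground truth {truth:.4f})")

err = np.nanmax(np.abs(plain.voxels - phantom.truth_plain.voxels))
print(f"max voxel T1 error (plain): {err:.1f} ms")
# At this noise level the volumetric mean averages voxel noise away, so the
# recovered reduction rate sits within ~0.01 of the generating value.
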