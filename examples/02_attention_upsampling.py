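"""Coarse cross-attention and mass-preserving upsampling, by hand.

Builds a toy attention problem (S=2 support images, 4x4 coarse grid),
computes the coarse attention map with registry tokens, then upsamples it
one stage with top-K refinement and verifies that per-row attention mass is
conserved.
"""

import numpy as np

from icseg.attention import (compute_coarse_attention, effective_top_k,
                             init_mapper_params, init_upsampler_params,
                             upsample_attention)

rng = np.random.default_rng(0)
S, H, W, d = 2, 4, 4, 16

mapper = init_mapper_params(d, n_registry=4, rng=rng)
query_feats = rng.standard_normal((H * W, d))
support_feats = rng.standard_normal((S * H * W, d))

cam = compute_coarse_attention(mapper, query_feats, support_feats, S, H, W)
print(f"coarse map: {cam.A.shape} (query locations x support locations)")
print(f"row sums + registry mass == 1:  max error "
      f"{np.abs(cam.A.sum(1) + cam.registry_mass - 1).max():.2e}")
print(f"mean registry mass: {cam.registry_mass.mean():.3f} "
      "(probability parked on 'nowhere in the support set')")

ups = init_upsampler_params(d, d, rng)
K = effective_top_k(base_k=8, upsampler_stage=1)
A2, mass2 = upsample_attention(
    cam.A, ups,
    rng.standard_normal((4 * H * W, d)), rng.standard_normal((S * 4 * H * W, d)),
    S, H, W, K, registry_mass=cam.registry_mass)
print(f"\nupsampled map: {np.asarray(A2).shape}, refined top-K={K} per row")
print(f"mass conservation after refinement: max |row sum - mass| = "
      f"{np.abs(np.asarray(A2).sum(1) - np.asarray(mass2)).max():.2e}")
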