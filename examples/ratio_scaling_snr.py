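"""Ratio scaling rescues horizontal integration from batch effects.

Simulates four batches of RNA profiling of the Quartet family (4 donors x 3
technical replicates), where per-feature batch offsets are twice as large as
the biological donor differences, then compares the SNR of the merged data
at the absolute level and after ratio scaling against the D6 reference.
"""

import numpy as np

from quartetqc import (
    SimulationConfig,
    compute_snr,
    merge_batches,
    ratio_scale,
    simulate_multiomics,
)

cfg = SimulationConfig(seed=1, layers={"rna": 300}, n_batches=4,
                       donor_effect_sd=0.5, batch_offset_sd=1.0, noise_sd=0.2,
                       n_planted_defs=0, n_planted_pairs=0)
res = simulate_multiomics(cfg)
batches = res.layers["rna"]

per_batch = [compute_snr(b) for b in batches]
snr_absolute = compute_snr(merge_batches(batches))
snr_ratio = compute_snr(merge_batches([ratio_scale(b, "D6") for b in batches]))

print(f"single-batch SNR (dB):      {np.round(per_batch, 1)}")
print(f"merged, absolute level:     {snr_absolute:6.2f} dB")
print(f"merged, ratio level (D6):   {snr_ratio:6.2f} dB")
print()
print("Each batch alone resolves the four donors (SNR >> 0), but merging at")
print("the absolute level collapses the signal to ~0 dB because batch offsets")
print("swamp donor differences.  Subtracting each batch's D6 replicate mean")
print("per feature cancels the offsets and restores the donor signal.")
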