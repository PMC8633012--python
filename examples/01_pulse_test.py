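"""Detect the frequency signature of two transient pulses.

Builds a 30 s signal containing a 30 Hz pulse and a 5 Hz pulse at different
times (plus noise), runs the full inter-scale power-correlation test at a
reduced Monte Carlo size, and reports what came out significant.
"""

import numpy as np

from ispc import RunConfig, SyntheticSpec, count_main_groupings, generate, run_ispc_test

spec = SyntheticSpec(kind="double_pulse", fs=500.0, duration=30.0, seed=7)
sig = generate(spec)

cfg = RunConfig(alpha=0.001, L=60, H=60, seed=11)
result = run_ispc_test(sig, cfg)

freqs = result.ispcm.freqs
mask = result.test.mask
iu = np.triu_indices(freqs.size, k=1)
sig_pairs = mask[iu]

print(f"scales tested     : {freqs.size} ({freqs.min():.2f}-{freqs.max():.1f} Hz)")
print(f"rejection threshold t_hat = {result.test.t_hat:.2f} "
      f"(fallback: {result.test.used_fallback})")
print(f"significant pairs : {int(sig_pairs.sum())}")
print(f"main groupings    : {count_main_groupings(mask)}")
if sig_pairs.any():
    fa, fb = freqs[iu[0][sig_pairs]], freqs[iu[1][sig_pairs]]
    print(f"significant pair frequencies span "
          f"{min(fa.min(), fb.min()):.1f}-{max(fa.max(), fb.max()):.1f} Hz")

# Each pulse correlates a band of scales around its carrier with itself
# (through the shared on/off envelope), so the expected picture is one main
# grouping hugging the diagonal near 30 Hz and one near 5 Hz; the two pulses
# happen at different times, so no significant cross-frequency cluster links
# them.
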