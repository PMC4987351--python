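"""Frequency bands of the wavelet decomposition for two fMRI protocols.

The repetition time (TR) of an acquisition fixes the Nyquist frequency
1/(2 TR); each wavelet scale then covers one dyadic band below it.  The
band of interest for resting-state fluctuations lies below 0.1 Hz, which
picks a different scale for a fast multiband protocol (TR = 0.72 s) than
for a conventional one (TR = 2.0 s).
"""

import numpy as np

from hubdisrupt import modwt_details, nyquist_frequency, scale_band, select_scale

for tr in (0.72, 2.0):
    f_n = nyquist_frequency(tr)
    j = select_scale(tr)
    lo, hi = scale_band(tr, j)
    print(f"TR = {tr:.2f} s: Nyquist {f_n:.2f} Hz -> scale {j} "
          f"covering {lo:.3f}-{hi:.3f} Hz")

# An undecimated (MODWT) decomposition returns one coefficient series per
# scale, each of the original length, and partitions the signal energy
# exactly across scales.
rng = np.random.default_rng(0)
x = rng.standard_normal(512)
res = modwt_details(x, max_scale=3)
energy = sum((d**2).sum() for d in res.details) + (res.smooth**2).sum()
print(f"energy identity: sum over scales / total = {energy / (x**2).sum():.12f}")
print("(1.0 means the decomposition loses nothing)")
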