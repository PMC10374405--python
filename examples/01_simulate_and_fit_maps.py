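"""Simulate weighted image stacks and recover T1/T2 maps per pixel.

A T1 map is built by sampling the inversion-recovery curve A - B*exp(-t/T1)
at 8 inversion times and refitting it pixelwise; a T2 map from 3 echoes of
the mono-exponential decay S0*exp(-TE/T2). With noise off the fits invert
the generators almost exactly; with noise they stay within a few percent.
"""

import numpy as np

from cardiomapseg import phantom as P

labels = np.zeros((64, 64), np.uint8)
labels[16:48, 16:48] = 2   # myocardium, T1=1000 ms / T2=50 ms
labels[24:40, 24:40] = 1   # blood pool,  T1=1600 ms / T2=250 ms

tissue = P.TissueParams()
t1_true = tissue.class_map(labels, "t1_ms")
t2_true = tissue.class_map(labels, "t2_ms")
amp = tissue.class_map(labels, "proton_amplitude")
times = P.DEFAULT_INVERSION_TIMES_MS

for sigma in (0.0, 20.0):
    rng = np.random.default_rng(0)
    t1w = P.simulate_t1_stack(t1_true, amp, 2 * amp, times)
    t2w = P.simulate_t2_stack(t2_true, amp, (0, 25, 55))
    t1w = t1w + rng.normal(0, sigma, t1w.shape)
    t2w = t2w + rng.normal(0, sigma, t2w.shape)
    t1_map = P.fit_t1_map(t1w, times)
    t2_map = P.fit_t2_map(t2w, (0, 25, 55))
    myo = labels == 2
    print(f"noise sigma {sigma:5.1f}:"
          f"  myocardial T1 median {np.nanmedian(t1_map.data[myo]):7.1f} ms"
          f"  (truth 1000), T2 median {np.nanmedian(t2_map.data[myo]):6.2f} ms"
          f"  (truth 50), failed pixels {int(t1_map.fit_failed.sum())}")
# Expected: noiseless medians sit at 1000.0 / 50.00; at sigma=20 (2% of the
# blood amplitude) they move by well under 2%.
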