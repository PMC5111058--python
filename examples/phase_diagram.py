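"""Phase diagrams in the (kappa_w, kappa_m) plane.

The crossover time to the asymptotic regime spans orders of magnitude:
it grows when restarts are rare (small kappa_m) and again when both
switching probabilities are large (rapid state oscillations).
"""

import numpy as np

import runpause as rp

kappas = np.linspace(0.05, 0.95, 10)

nc = rp.scan("n_c_single", kappas, kappas, n_max=8192)
print("crossover time n_c to ballistic motion (rows kappa_w, cols kappa_m):")
for i in (0, 4, 9):
    row = " ".join(f"{v:7.0f}" for v in nc.matrix[i, [0, 4, 9]])
    print(f"  kappa_w={kappas[i]:.2f}: {row}")
print("  (columns kappa_m = 0.05, 0.46, 0.95)")

dinf = rp.scan("D_inf", kappas, kappas, A=0.5)
print("\nasymptotic network diffusion D_inf (A=0.5, lambda=1, v=<l>=1):")
for i in (0, 4, 9):
    row = " ".join(f"{v:7.4f}" for v in dinf.matrix[i, [0, 4, 9]])
    print(f"  kappa_w={kappas[i]:.2f}: {row}")

print("\nconstrained slice kappa_m = 1 - kappa_w (inversely related rates):")
frame = rp.constrained_slice("D_inf", np.linspace(0.1, 0.9, 5), A=0.5)
for _, r in frame.iterrows():
    print(f"  kappa_w={r.kappa_w:.1f}: D_inf = {r.value:.4f}")
# D_inf falls monotonically along the slice: more pausing and rarer
# restarts both suppress transport.
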