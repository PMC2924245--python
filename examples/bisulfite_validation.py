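"""Compare predictions against five-point bisulfite scores, with and
without the tolerance-window adjustment.

Sanger bisulfite traces yield a coarse five-point unmethylation score per
CG. Because the underlying allele fraction is continuous, each score is
granted a feasible range (widest at mid-scale); the adjusted comparison
clamps a prediction into its site's range, asking whether disagreements
exceed what the score's precision can explain.
"""

import numpy as np

from metmap import adjusted_bisulfite, bisulfite_bin, pearson

rng = np.random.default_rng(0)
true_u = rng.random(46)  # a bisulfite-validated panel of sites
prediction = np.clip(true_u + rng.normal(0, 0.18, size=true_u.size), 0, 1)
bis = np.array([bisulfite_bin(u) for u in true_u])

adjusted = np.array([adjusted_bisulfite(b, p) for b, p in zip(bis, prediction)])
print("site  bisulfite  prediction  adjusted_bisulfite")
for k in range(6):
    print(f"{k:<6d}{bis[k]:<11.2f}{prediction[k]:<12.3f}{adjusted[k]:.3f}")
print("...")
print(f"r(prediction, bisulfite score)    = {pearson(prediction, bis):.3f}")
print(f"r(prediction, adjusted bisulfite) = {pearson(prediction, adjusted):.3f}")
print()
print("worked example: bisulfite 0.25 with prediction 0.40 adjusts to",
      adjusted_bisulfite(0.25, 0.4))
print("worked example: bisulfite 0.25 with prediction 0.00 adjusts to",
      adjusted_bisulfite(0.25, 0.0))
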