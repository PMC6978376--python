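"""Where do unreliable predictions concentrate as imbalance grows?

Averages the unreliability score over a uniform law on the relative
likelihood β for a balanced (π = 0.5) and a heavily imbalanced (π = 0.01)
population.  Under imbalance the expected unreliability rises steadily with
the predicted risk: with few positive examples to learn from, it is the
high-risk predictions that are most likely to be misleading.
"""

import numpy as np

from riskaudit import BetaLaw, expected_unreliability_curve

grid = np.array([0.1, 0.3, 0.5, 0.7, 0.9])

for pi, law in ((0.5, BetaLaw("uniform", 2.0)), (0.01, BetaLaw("uniform", 10.0))):
    curve = expected_unreliability_curve(pi, grid, law)
    print(f"prevalence {pi:4.2f}, beta ~ U(0, {law.upper:g}]:")
    for y, u in zip(curve.y_hat_grid, curve.expected_U):
        print(f"  E[U | score={y:.1f}] = {u:.3f}")

print("Balanced cohorts are least unreliable near the prevalence; imbalanced "
      "cohorts grow monotonically less reliable toward high predicted risk.")
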