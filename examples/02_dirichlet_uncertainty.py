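"""The Dirichlet evidence algebra that drives the decoder.

Shows how per-pixel logits become Dirichlet concentrations, and why two
pixels with the same expected probability can have opposite epistemic
status — the distinction a softmax head cannot express.
"""

import numpy as np

from espdnet import dirichlet_uncertainty, evidence_to_alpha, expected_probability

# logits from an evidence head -> concentrations alpha = 1 + softplus(logits)
logits = np.array([[0.0, 0.0],      # no evidence either way
                   [3.0, -3.0],     # moderate foreground evidence
                   [20.0, -20.0]])  # strong foreground evidence
alpha = evidence_to_alpha(logits, axis=1)
S, U = dirichlet_uncertainty(alpha, axis=1)
p = expected_probability(alpha, axis=1)
for i in range(3):
    print(f"logits {logits[i]} -> alpha {np.round(alpha[i], 3)}, "
          f"S={S[i]:.2f}, U={U[i]:.3f}, p_fg={p[i, 0]:.3f}")

# same expected probability, different evidence
weak = np.array([1.0, 1.0])      # S = 2   : total ignorance
strong = np.array([100.0, 100.0])  # S = 200 : confident boundary
print("\nboth pixels have p =", expected_probability(weak),
      "but U =", dirichlet_uncertainty(weak)[1],
      "vs", dirichlet_uncertainty(strong)[1])
print("high U marks an ambiguous region; low U a genuinely contested boundary")
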