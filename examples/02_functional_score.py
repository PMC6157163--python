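"""Score an edge functionally by class-conditional mutual information.

Draws a miRNA-gene pair whose dependence is the same bivariate normal
(correlation 0.6) in both phenotype classes, estimates the conditional
mutual information d with Gaussian kernel densities, and compares it to
the closed form -1/2 ln(1 - rho^2) available for this special case.  An
independent pair scores near zero.
"""

import math

import numpy as np

from miregnet import PhenotypeVector, conditional_mutual_information

rho = 0.6
n = 2000  # per class
rng = np.random.default_rng(0)
xs, ys = [], []
for _ in range(2):
    x = rng.standard_normal(n)
    ys.append(rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(n))
    xs.append(x)
ids = [f"s{i}" for i in range(2 * n)]
phen = PhenotypeVector(ids, {s: ("control" if i < n else "case")
                             for i, s in enumerate(ids)})

res = conditional_mutual_information(np.concatenate(xs), np.concatenate(ys),
                                     phen, sample_ids=ids)
print(f"estimated d:        {res.d:.4f} nats")
print(f"Gaussian closed form: {-0.5 * math.log(1 - rho**2):.4f} nats")
print("per-class contributions:",
      {c: round(v, 4) for c, v in res.per_class_terms.items()})

d0 = conditional_mutual_information(rng.standard_normal(2 * n),
                                    rng.standard_normal(2 * n),
                                    phen, sample_ids=ids).d
print(f"\nindependent pair:   {d0:.4f} nats (near zero, as it should be)")
print("d measures how much expression dependence the edge carries "
      "within each phenotype class")
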