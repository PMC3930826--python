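"""Compare smoothing model families by leave-one-out cross-validation.

Builds a 60-probe panel with curved (quadratic-like) age trends and ranks
linear, quadratic, cubic, quadratic-B-spline and LOESS fits by mean LOOCV
error, with pairwise Wilcoxon signed-rank tests on the per-probe errors.
"""

import numpy as np

from agebend import compare_models
from agebend.dataio import ExpressionDataset

rng = np.random.default_rng(0)
ages = np.sort(rng.uniform(25, 95, size=40))
rows = [
    rng.choice([-1, 1]) * rng.uniform(0.0008, 0.002)
    * (ages - rng.uniform(40, 80)) ** 2 + rng.normal(0, 0.5, size=40)
    for _ in range(60)
]
panel = ExpressionDataset(
    probe_ids=[f"p{i}" for i in range(60)],
    sample_ids=[f"s{j}" for j in range(40)],
    ages=ages, sex=np.array(["female", "male"] * 20),
    values=np.vstack(rows), normalized=True,
)

comp = compare_models(panel, ("linear", "quadratic", "cubic", "qbspline", "loess"))
for model in comp.models:
    print(f"{model:10s} mean LOOCV error {comp.mean_errors[model]:.4f}")
print(f"winner: {comp.winner}")
print(f"quadratic vs linear Wilcoxon p = "
      f"{comp.pairwise_p.loc['quadratic', 'linear']:.2e}")
print("A low p here says the linear family predicts held-out samples "
      "significantly worse than the quadratic on bending trends.")
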