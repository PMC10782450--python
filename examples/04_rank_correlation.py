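"""Kendall-tau BDE rank comparison between two BDE sets.

Computes reference BDEs for a 20-molecule battery, perturbs them with
Gaussian noise of growing amplitude (a stand-in for a cheaper, noisier
method), and reports the mean per-molecule rank correlation.
"""

import numpy as np

from bdekit import (
    ToyForceField,
    bde_pipeline,
    default_toy_params,
    make_fixture_battery,
    rank_report,
)

calc = ToyForceField(default_toy_params())
battery = make_fixture_battery(20, seed=0, perturbation=0.03)
ref = {m.tags["name"]: [r.bde for r in bde_pipeline(m, calc)] for m in battery}

rng = np.random.default_rng(0)
for sigma in (0.1, 1.0, 5.0):
    pred = {k: list(np.asarray(v) + sigma * rng.standard_normal(len(v)))
            for k, v in ref.items()}
    report = rank_report(ref, pred)
    print(f"noise sigma = {sigma:>4.1f} kcal/mol -> "
          f"mean tau = {report.mean_tau:.3f} over "
          f"{len(report.per_molecule)} molecules")
# Mean tau decays from ~0.6 toward ~0.2 as the noise overwhelms the
# few-kcal/mol within-molecule BDE spread: rank prediction quality is
# set by the method-error-to-spread ratio.
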