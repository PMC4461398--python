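"""Estimate the death threshold and classify cell fate three ways.

On a 300-cell cohort at the half-killing TRAIL dose we (1) estimate theta by
minimizing the live/dead misclassification count over fitted Max(C8), (2)
classify cells with the analytic fate boundary tau = theta/(2k) + t0, and
(3) benchmark against a linear max-margin (SVM) classifier in (log10 k, tau).
"""

import numpy as np
import pandas as pd

import c8fate as cf
from c8fate.experiments import fit_condition

fits = fit_condition(dose=25.0, n=300, seed=42)
ok = fits[~fits["discarded"]]
died = (ok["fate"] == cf.FATE_DIED).to_numpy()

res = cf.estimate_theta(ok["max_c8"], ok["fate"])
sem = cf.bootstrap_sem(
    lambda d: cf.estimate_theta(d["max_c8"], d["fate"]).accuracy,
    ok, n_boot=200, seed=0,
)
print(f"{len(ok)} fitted cells, {died.mean():.0%} died")
print(f"theta_hat = {res.theta_hat:.3g} a.u./min "
      f"(threshold accuracy {res.accuracy:.1%} +/- {sem:.1%})")

boundary = cf.BoundaryClassifier(theta=res.theta_hat, t0_bar=20.0)
pred_b = cf.classify_by_boundary(ok["k"], ok["tau"], boundary)
svm = cf.fit_linear_margin_classifier(ok["k"], ok["tau"], ok["fate"])
print(f"fate-boundary accuracy  = {np.mean(pred_b == died):.1%}")
print(f"linear SVM accuracy     = {svm['accuracy']:.1%}")
print("\nThe analytic boundary (one threshold + the mean lag) classifies as "
      "well as a\ndata-driven max-margin line: peak C8 activity is what decides fate.")
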