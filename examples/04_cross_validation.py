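"""Pair-holdout cross-validation (CV-p) of RCMF vs plain CMF.

Runs repeated 5-fold CV on the planted benchmark, recomputing GIP
similarities and WKNKN inside every training fold so no held-out label
leaks into the pipeline, and reports mean (sd) AUC for both variants.
"""

import warnings
from dataclasses import replace

from rcmf import CvPlan, RcmfConfig, WknknConfig, make_planted, run_cv

# tiny demo matrices: the default latent dimension exceeds the numerical
# rank inside some training folds, which is benign
warnings.filterwarnings("ignore", message="requested k")
warnings.filterwarnings("ignore", message="WKNKN")

inst = make_planted(40, 30, 2, 0.15, 0.01, 0.1, seed=0)
plan = CvPlan(n_folds=5, n_repeats=10, seed=42)
wk = WknknConfig(K=5, p=0.7)

for variant in ("rcmf", "cmf"):
    cfg = replace(RcmfConfig(), variant=variant)
    res = run_cv(inst.Y, inst.Sm, inst.Sd, cfg, wk, plan)
    print(f"{variant.upper():4}  AUC = {res.auc_mean:.4f} ({res.auc_sd:.4f}) "
          f"over {plan.n_repeats} repeats of {plan.n_folds}-fold CV-p")

print("""
AUC is the probability that a held-out true association outscores a random
never-known pair; 0.5 is chance.  Values well above 0.9 on this planted
rank-2 instance show the pipeline recovers the low-rank structure.
""")
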