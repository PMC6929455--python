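"""Evaluation: CV-p cross-validation, AUC, grid search, WKNKN sensitivity.

The protocol is pair-holdout ("CV-p"): the 1-entries of Y are partitioned
into folds; for each fold those entries are zeroed in a training copy, the
whole pipeline (GIP similarity, integration, WKNKN, factorization) is rerun
on the training matrix only, and the held-out positives are scored against
all never-known pairs.  Recomputing the similarity and imputation inside
each fold keeps test labels out of everything the model sees.
"""

from __future__ import annotations

import itertools
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .containers import (
    AssociationMatrix,
    CvPlan,
    CvResult,
    RcmfConfig,
    SimilarityMatrix,
    WknknConfig,
    check_alignment,
)
from .errors import DomainError, UndefinedAUCError
from .factorization import fit_matrix
from .preprocessing import wknkn
from .similarity import gip_kernel, integrate_similarity

__all__ = ["make_folds", "auc", "run_cv", "grid_search", "sensitivity_sweep"]


def make_folds(Y: AssociationMatrix, plan: CvPlan) -> list[list[np.ndarray]]:
    """Partition the known (1) pairs into folds, once per repeat.

    Returns ``folds[r][f]``: an integer array of shape (q, 2) holding the
    (row, column) indices held out in fold f of repeat r.  Fold sizes differ
    by at most one; the assignment is a pure function of ``plan.seed``.
    """
    pairs = np.argwhere(Y.values == 1)
    if len(pairs) < plan.n_folds:
        raise DomainError(
            f"{len(pairs)} known pairs cannot fill {plan.n_folds} folds"
        )
    children = np.random.SeedSequence(plan.seed).spawn(plan.n_repeats)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(pairs))
        out.append([pairs[idx] for idx in np.array_split(perm, plan.n_folds)])
    return out


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _fold_auc(Y: AssociationMatrix,
              Sm_primary: SimilarityMatrix | None,
              Sd_primary: SimilarityMatrix | None,
              held: np.ndarray,
              cfg: RcmfConfig,
              wk: WknknConfig | None,
              integration_mode: str) -> float:
    """Train with ``held`` pairs zeroed; score them against never-known pairs."""
    Ytr = Y.copy()
    Ytr.values[held[:, 0], held[:, 1]] = 0.0
    Sm = integrate_similarity(Sm_primary, gip_kernel(Ytr, "mirna"), integration_mode)
    Sd = integrate_similarity(Sd_primary, gip_kernel(Ytr, "disease"), integration_mode)
    train = wknkn(Ytr, Sm, Sd, wk) if wk is not None else Ytr
    result = fit_matrix(train.values, Sm.values, Sd.values, cfg)
    scores = result.factors.A @ result.factors.B.T
    neg = Y.values == 0  # never-known pairs in the full original matrix
    pos_scores = scores[held[:, 0], held[:, 1]]
    neg_scores = scores[neg]
    y_true = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    return auc(np.concatenate([pos_scores, neg_scores]), y_true)


def run_cv(Y: AssociationMatrix,
           Sm_primary: SimilarityMatrix | None,
           Sd_primary: SimilarityMatrix | None,
           cfg: RcmfConfig = RcmfConfig(),
           wk: WknknConfig | None = WknknConfig(),
           plan: CvPlan = CvPlan(),
           integration_mode: str = "mean") -> CvResult:
    """Repeated k-fold CV-p; returns mean/sd AUC over repeats.

    ``wk=None`` skips the WKNKN step.  Each repeat's AUC is the mean of its
    fold AUCs; the reported sd is the sample sd of the per-repeat values.
    """
    check_alignment(Y, Sm_primary, Sd_primary)
    folds = make_folds(Y, plan)
    per_repeat = np.array([
        np.mean([
            _fold_auc(Y, Sm_primary, Sd_primary, held, cfg, wk, integration_mode)
            for held in repeat
        ])
        for repeat in folds
    ])
    sd = float(per_repeat.std(ddof=1)) if len(per_repeat) > 1 else 0.0
    return CvResult(float(per_repeat.mean()), sd, per_repeat, plan, cfg)


def grid_search(Y: AssociationMatrix,
                Sm_primary: SimilarityMatrix | None,
                Sd_primary: SimilarityMatrix | None,
                lambda_l_grid: Sequence[float],
                lambda_d_grid: Sequence[float],
                lambda_t_grid: Sequence[float],
                plan: CvPlan,
                base_cfg: RcmfConfig = RcmfConfig(),
                wk: WknknConfig | None = WknknConfig(),
                integration_mode: str = "mean"
                ) -> tuple[RcmfConfig, pd.DataFrame]:
    """Exhaustive CV over the lambda grids; argmax AUC, ties to smaller lambdas.

    Returns the winning config and the full score table (one row per
    combination, iterated in ascending lambda order so the first maximum —
    the smallest lambdas — wins ties).
    """
    if not (len(lambda_l_grid) and len(lambda_d_grid) and len(lambda_t_grid)):
        raise DomainError("lambda grids must be non-empty")
    rows = []
    best_cfg, best_auc = None, -np.inf
    combos = itertools.product(sorted(lambda_l_grid), sorted(lambda_d_grid),
                               sorted(lambda_t_grid))
    for ll, ld, lt in combos:
        cfg = replace(base_cfg, lambda_l=ll, lambda_d=ld, lambda_t=lt)
        res = run_cv(Y, Sm_primary, Sd_primary, cfg, wk, plan, integration_mode)
        rows.append({"lambda_l": ll, "lambda_d": ld, "lambda_t": lt,
                     "auc_mean": res.auc_mean, "auc_sd": res.auc_sd})
        if res.auc_mean > best_auc:
            best_cfg, best_auc = cfg, res.auc_mean
    return best_cfg, pd.DataFrame(rows)


def sensitivity_sweep(Y: AssociationMatrix,
                      Sm_primary: SimilarityMatrix | None,
                      Sd_primary: SimilarityMatrix | None,
                      cfg: RcmfConfig,
                      K_values: Sequence[int],
                      p_values: Sequence[float],
                      plan: CvPlan,
                      integration_mode: str = "mean") -> pd.DataFrame:
    """CV AUC for every (K, p) WKNKN setting; long-format table for plotting."""
    if not (len(K_values) and len(p_values)):
        raise DomainError("K_values and p_values must be non-empty")
    rows = []
    for K in K_values:
        for p in p_values:
            res = run_cv(Y, Sm_primary, Sd_primary, cfg, WknknConfig(K=K, p=p),
                         plan, integration_mode)
            rows.append({"K": K, "p": p, "auc_mean": res.auc_mean,
                         "auc_sd": res.auc_sd})
    return pd.DataFrame(rows)
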