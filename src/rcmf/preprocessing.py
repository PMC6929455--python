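"""WKNKN: weighted K-nearest-known-neighbor imputation of the association matrix.

A 0 in the raw association matrix means "no evidence", not "no association".
Before factorization each unknown entry is replaced by a decay-weighted
average of the profiles of the K most similar miRNAs (row side) and the K
most similar diseases (column side) that have at least one known
association, the two sides averaged and combined with the original matrix
through an elementwise max.  Known 1-entries are therefore never altered.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import (
    AssociationMatrix,
    SimilarityMatrix,
    WknknConfig,
    check_alignment,
)

__all__ = ["wknkn"]


def _side_estimate(Y: np.ndarray, S: np.ndarray, K: int, p: float,
                   side: str) -> np.ndarray:
    """One-sided WKNKN estimate over rows of Y using row similarity S.

    For row i: take the K rows most similar to i (self excluded, ties broken
    by label order) among rows with at least one known association, and form
    sum_t p^(t-1) * S[i, i_t] * Y[i_t, :] / sum_t S[i, i_t].
    """
    n = Y.shape[0]
    known = np.flatnonzero(Y.sum(axis=1) > 0)
    est = np.zeros_like(Y, dtype=float)
    short = 0
    for i in range(n):
        cand = known[known != i]
        if cand.size == 0:
            continue  # no known neighbors: this side contributes 0
        order = cand[np.lexsort((cand, -S[i, cand]))]
        if order.size < K:
            short += 1
        nbrs = order[:K]
        sims = S[i, nbrs]
        denom = sims.sum()
        if denom <= 0:
            continue
        weights = p ** np.arange(nbrs.size) * sims
        est[i] = weights @ Y[nbrs] / denom
    if short:
        warnings.warn(
            f"WKNKN ({side} side): {short} profile(s) had fewer than K={K} "
            "known neighbors; used all available",
            stacklevel=3,
        )
    return est


def wknkn(Y: AssociationMatrix, Sm: SimilarityMatrix, Sd: SimilarityMatrix,
          cfg: WknknConfig = WknknConfig()) -> AssociationMatrix:
    """Impute likely-missing associations; returns a matrix with values in [0, 1].

    Both sides are computed from the *original* Y (order-independent), then
    averaged; the result is max-combined with Y so known entries survive.
    """
    check_alignment(Y, Sm, Sd)
    Yv = Y.values
    row_est = _side_estimate(Yv, Sm.values, cfg.K, cfg.p, "miRNA")
    col_est = _side_estimate(Yv.T, Sd.values, cfg.K, cfg.p, "disease").T
    imputed = np.maximum(Yv, (row_est + col_est) / 2.0)
    np.clip(imputed, 0.0, 1.0, out=imputed)
    return AssociationMatrix(Y.mirna_labels, Y.disease_labels, imputed, kind="imputed")
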