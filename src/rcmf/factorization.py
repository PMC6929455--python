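"""The RCMF solver: objective, SVD initialization, alternating updates.

The model approximates the association matrix Y (n x m) by A B^T with
A (n x k) the miRNA factors and B (m x k) the disease factors, minimizing

    ||Y - A B^T||_F^2 + lambda_l (||A||_F^2 + ||B||_F^2) + lambda_l ||B||_{2,1}
      + lambda_d ||S_m - A A^T||_F^2 + lambda_t ||S_d - B B^T||_F^2

where ||B||_{2,1} is the sum of row norms of B (dropped for the plain CMF
variant).  The two collaborative terms pull the factor Gramians toward the
similarity matrices; the L2,1 penalty drives whole rows of B to zero, which
both regularizes and suppresses outlying columns of Y.

Optimization alternates closed-form least-squares updates for A and for the
rows of B.  The non-smooth L2,1 term is handled by iteratively reweighted
least squares: each row i of B carries a weight d_ii = 1 / (2 ||B_i||_2)
(guarded below by ``epsilon``) that enters that row's k x k normal system.
The collaborative terms are linearized about the previous iterate, giving a
fixed-point/alternating scheme; A and B are initialized from the truncated
SVD of Y so the iteration starts at the best rank-k approximation.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import (
    AssociationMatrix,
    FactorPair,
    FitResult,
    RcmfConfig,
    SimilarityMatrix,
    check_alignment,
)
from .errors import DivergenceError, DomainError, NumericError

__all__ = [
    "svd_init",
    "objective",
    "reweight_D",
    "update_A",
    "update_B",
    "fit",
    "fit_matrix",
    "predict_scores",
    "rank_candidates",
]

_COND_LIMIT = 1e12


def _as_array(Y) -> np.ndarray:
    v = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(v)):
        raise NumericError("input matrix contains non-finite entries")
    return v


def svd_init(Y, k: int) -> FactorPair:
    """Initialize factors from the rank-k truncated SVD of Y.

    A = U_k S_k^{1/2}, B = V_k S_k^{1/2}, so A B^T is the best rank-k
    approximation of Y in Frobenius norm.  Requesting k beyond the numerical
    rank keeps the zero singular values (with a warning).
    """
    Yv = _as_array(Y)
    n, m = Yv.shape
    if not (1 <= k <= min(n, m)):
        raise DomainError(f"k must satisfy 1 <= k <= min(n, m)={min(n, m)}, got {k}")
    U, s, Vt = np.linalg.svd(Yv, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, m) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        warnings.warn(
            f"requested k={k} exceeds numerical rank {rank}; "
            "zero singular values retained",
            stacklevel=2,
        )
    root_s = np.sqrt(s[:k])
    return FactorPair(U[:, :k] * root_s, Vt[:k].T * root_s)


def _row_norms(B: np.ndarray) -> np.ndarray:
    return np.linalg.norm(B, axis=1)


def objective(Y, A: np.ndarray, B: np.ndarray,
              Sm: np.ndarray | SimilarityMatrix | None,
              Sd: np.ndarray | SimilarityMatrix | None,
              cfg: RcmfConfig) -> float:
    """Evaluate the (R)CMF objective at (A, B); CMF omits the L2,1 term."""
    Yv = _as_array(Y)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise NumericError("factors contain non-finite entries")
    val = np.sum((Yv - A @ B.T) ** 2)
    val += cfg.lambda_l * (np.sum(A**2) + np.sum(B**2))
    val += cfg.l21_weight * _row_norms(B).sum()
    if cfg.lambda_d > 0:
        if Sm is None:
            raise DomainError("lambda_d > 0 requires a miRNA similarity matrix")
        Smv = Sm.values if isinstance(Sm, SimilarityMatrix) else np.asarray(Sm, float)
        val += cfg.lambda_d * np.sum((Smv - A @ A.T) ** 2)
    if cfg.lambda_t > 0:
        if Sd is None:
            raise DomainError("lambda_t > 0 requires a disease similarity matrix")
        Sdv = Sd.values if isinstance(Sd, SimilarityMatrix) else np.asarray(Sd, float)
        val += cfg.lambda_t * np.sum((Sdv - B @ B.T) ** 2)
    return float(val)


def reweight_D(B: np.ndarray, epsilon: float) -> np.ndarray:
    """IRLS row weights d_ii = 1 / (2 max(||B_i||_2, epsilon)); strictly positive."""
    if epsilon <= 0:
        raise DomainError("epsilon must be > 0")
    return 1.0 / (2.0 * np.maximum(_row_norms(np.asarray(B, float)), epsilon))


def _solve_right(M: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Solve X G = M for X with a pseudoinverse fallback on ill-conditioning."""
    try:
        if np.linalg.cond(G) > _COND_LIMIT:
            raise np.linalg.LinAlgError("ill-conditioned")
        return np.linalg.solve(G.T, M.T).T
    except np.linalg.LinAlgError:
        warnings.warn("singular normal system; falling back to pseudoinverse",
                      stacklevel=3)
        return M @ np.linalg.pinv(G)


def update_A(Y, A_prev: np.ndarray, B: np.ndarray,
             Sm: np.ndarray | SimilarityMatrix | None,
             cfg: RcmfConfig) -> np.ndarray:
    """A <- (Y B + lambda_d S_m A) (B^T B + lambda_l I + lambda_d A^T A)^{-1}."""
    Yv = _as_array(Y)
    k = B.shape[1]
    M = Yv @ B
    G = B.T @ B + cfg.lambda_l * np.eye(k)
    if cfg.lambda_d > 0:
        Smv = Sm.values if isinstance(Sm, SimilarityMatrix) else np.asarray(Sm, float)
        M = M + cfg.lambda_d * Smv @ A_prev
        G = G + cfg.lambda_d * A_prev.T @ A_prev
    return _solve_right(M, G)


def update_B(Y, A: np.ndarray, B_prev: np.ndarray,
             Sd: np.ndarray | SimilarityMatrix | None,
             D: np.ndarray, cfg: RcmfConfig) -> np.ndarray:
    """Row-wise B update: B_i <- M_i (G + lambda_l d_ii I)^{-1}.

    M = Y^T A + lambda_t S_d B, G = A^T A + lambda_l I + lambda_t B^T B;
    the CMF variant passes d_ii = 0 for all rows, collapsing to one solve.
    """
    Yv = _as_array(Y)
    k = A.shape[1]
    M = Yv.T @ A
    G = A.T @ A + cfg.lambda_l * np.eye(k)
    if cfg.lambda_t > 0:
        Sdv = Sd.values if isinstance(Sd, SimilarityMatrix) else np.asarray(Sd, float)
        M = M + cfg.lambda_t * Sdv @ B_prev
        G = G + cfg.lambda_t * B_prev.T @ B_prev
    D = np.asarray(D, dtype=float)
    c = cfg.lambda_l * D  # scalar added to row i's diagonal
    if c.size == 0 or np.all(c == c[0]):  # uniform weights: one shared system
        shift = c[0] if c.size else 0.0
        return _solve_right(M, G + shift * np.eye(k))
    # rows share G and differ only by c_i on the diagonal: with G = Q L Q^T,
    # (G + c_i I)^{-1} = Q diag(1/(L + c_i)) Q^T, so all rows solve at once
    evals, Q = np.linalg.eigh((G + G.T) / 2.0)
    denom = evals[None, :] + c[:, None]
    tiny = np.abs(evals).max() / _COND_LIMIT + np.finfo(float).tiny
    if np.any(denom < tiny):
        warnings.warn("singular normal system; clamping small eigenvalues",
                      stacklevel=2)
        denom = np.maximum(denom, tiny)
    return ((M @ Q) / denom) @ Q.T


def _optimal_rescale(Yv, A, B, Sm, Sd, cfg: RcmfConfig) -> float:
    """Exact line search over the joint rescaling (A, B) -> (tA, tB), t >= 0.

    Alternating updates can stall at scaling saddles where shrinking (or
    growing) both factors together lowers the objective but neither
    coordinate update can.  Along the scaling direction the objective is an
    explicit quartic  c0 + c1 t + c2 t^2 + c4 t^4  (c1 from the L2,1 term,
    c2 from reconstruction/Tikhonov cross terms, c4 from the quartic
    collaborative and reconstruction terms), so the best t is a root of its
    cubic derivative; deterministic and never objective-increasing.
    """
    AB = A @ B.T
    c1 = cfg.l21_weight * _row_norms(B).sum()
    c2 = -2.0 * np.sum(Yv * AB) + cfg.lambda_l * (np.sum(A**2) + np.sum(B**2))
    c4 = np.sum(AB**2)
    if cfg.lambda_d > 0:
        Smv = Sm.values if isinstance(Sm, SimilarityMatrix) else np.asarray(Sm, float)
        AA = A @ A.T
        c2 += -2.0 * cfg.lambda_d * np.sum(Smv * AA)
        c4 += cfg.lambda_d * np.sum(AA**2)
    if cfg.lambda_t > 0:
        Sdv = Sd.values if isinstance(Sd, SimilarityMatrix) else np.asarray(Sd, float)
        BB = B @ B.T
        c2 += -2.0 * cfg.lambda_t * np.sum(Sdv * BB)
        c4 += cfg.lambda_t * np.sum(BB**2)

    def f(t: float) -> float:
        return c1 * t + c2 * t * t + c4 * t**4

    candidates = [0.0, 1.0]
    if c4 > 0:
        roots = np.roots([4.0 * c4, 0.0, 2.0 * c2, c1])
        candidates += [float(r.real) for r in roots
                       if abs(r.imag) < 1e-10 and r.real > 0]
    return min(candidates, key=f)


def fit_matrix(Y: np.ndarray,
               Sm: np.ndarray | None,
               Sd: np.ndarray | None,
               cfg: RcmfConfig) -> FitResult:
    """Run the alternating solver on plain arrays (no label bookkeeping).

    Iterates A-update, reweighting, B-update from the SVD start until the
    relative objective change falls below ``cfg.tol`` or ``cfg.max_iter`` is
    reached.  Deterministic: the solver uses no randomness.  Aborts with
    :class:`DivergenceError` if the objective ever rises by more than 10%.
    """
    Yv = _as_array(Y)
    n, m = Yv.shape
    k = cfg.resolve_k(n, m)
    pair = svd_init(Yv, k)
    A, B = pair.A, pair.B
    trace = [objective(Yv, A, B, Sm, Sd, cfg)]
    iterations = 0

    def damped(old, cand, other_is_A: bool, bound: float):
        # The closed-form updates linearize the quartic collaborative terms,
        # so a full step can raise the objective slightly; halve the step
        # toward the previous iterate until it does not.  step -> 0 recovers
        # the previous iterate, so the loop always terminates.
        step = 1.0
        for _ in range(40):
            new = old + step * (cand - old)
            obj = (objective(Yv, new, B, Sm, Sd, cfg) if other_is_A
                   else objective(Yv, A, new, Sm, Sd, cfg))
            if obj <= bound * (1.0 + 1e-13) + 1e-15:
                return new, obj
            step *= 0.5
        return old, bound

    for _ in range(cfg.max_iter):
        A_cand = update_A(Yv, A, B, Sm, cfg)
        A, obj_a = damped(A, A_cand, True, trace[-1])
        if cfg.variant == "rcmf":
            D = reweight_D(B, cfg.epsilon)
        else:
            D = np.zeros(m)
        B_cand = update_B(Yv, A, B, Sd, D, cfg)
        B, obj = damped(B, B_cand, False, obj_a)
        t = _optimal_rescale(Yv, A, B, Sm, Sd, cfg)
        if t != 1.0:
            A_t, B_t = t * A, t * B
            obj_t = objective(Yv, A_t, B_t, Sm, Sd, cfg)
            if obj_t < obj:  # guard float noise in the closed form
                A, B, obj = A_t, B_t, obj_t
        iterations += 1
        prev = trace[-1]
        trace.append(obj)
        if obj > prev * 1.10 and obj - prev > 1e-12:
            raise DivergenceError(
                f"objective rose from {prev:.6g} to {obj:.6g} at iteration "
                f"{iterations}; aborting"
            )
        if abs(prev - obj) <= cfg.tol * max(abs(prev), 1e-12):
            break
    return FitResult(
        factors=FactorPair(A, B),
        objective_trace=np.asarray(trace),
        iterations_run=iterations,
        config=cfg,
    )


def fit(Y: AssociationMatrix,
        Sm: SimilarityMatrix | None,
        Sd: SimilarityMatrix | None,
        cfg: RcmfConfig = RcmfConfig()) -> FitResult:
    """Fit (R)CMF to a labeled association matrix; see :func:`fit_matrix`."""
    check_alignment(Y, Sm, Sd)
    result = fit_matrix(
        Y.values,
        None if Sm is None else Sm.values,
        None if Sd is None else Sd.values,
        cfg,
    )
    result.mirna_labels = Y.mirna_labels
    result.disease_labels = Y.disease_labels
    return result


def predict_scores(result: FitResult) -> AssociationMatrix:
    """Score matrix Y* = A B^T with the labels of the fitted association matrix."""
    if result.mirna_labels is None or result.disease_labels is None:
        raise DomainError("fit result carries no labels; fit from an AssociationMatrix")
    scores = result.factors.A @ result.factors.B.T
    return AssociationMatrix(result.mirna_labels, result.disease_labels,
                             scores, kind="scores")


def rank_candidates(Ystar: AssociationMatrix, disease: str,
                    exclude_known: AssociationMatrix | None = None
                    ) -> list[tuple[str, float, bool]]:
    """Rank miRNAs for one disease by descending score, ties by label order.

    Returns (miRNA, score, known) triples; ``known`` flags pairs that are 1
    in ``exclude_known`` (all False when no known matrix is supplied).
    """
    j = Ystar.disease_index(disease)
    scores = Ystar.values[:, j]
    if exclude_known is not None:
        if exclude_known.mirna_labels != Ystar.mirna_labels:
            jk = exclude_known.disease_index(disease)  # raises if absent
            known_set = {
                exclude_known.mirna_labels[i]
                for i in np.flatnonzero(exclude_known.values[:, jk] == 1)
            }
        else:
            jk = exclude_known.disease_index(disease)
            known_set = {
                Ystar.mirna_labels[i]
                for i in np.flatnonzero(exclude_known.values[:, jk] == 1)
            }
    else:
        known_set = set()
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores[i], Ystar.mirna_labels[i]))
    return [
        (Ystar.mirna_labels[i], float(scores[i]), Ystar.mirna_labels[i] in known_set)
        for i in order
    ]
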