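"""Domain containers: labeled matrices, the disease DAG, factors and configs.

The matrices are thin dataclasses around a numpy array plus ordered label
tuples.  Invariants are validated at construction time so that downstream
numerical code can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import AlignmentError, DomainError, IdentifierError, NumericError

#: absolute tolerance for symmetry / unit-diagonal / range checks
SYMMETRY_TOL = 1e-9


def _check_labels(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise DomainError(f"duplicate {what} labels: {dupes[:5]}")
    return labels


@dataclass
class AssociationMatrix:
    """miRNA x disease association matrix Y.

    Raw inputs are binary (0/1); after WKNKN imputation entries live in
    [0, 1]; model score matrices are arbitrary reals (``kind='scores'``).
    """

    mirna_labels: tuple[str, ...]
    disease_labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "binary"  # binary | imputed | scores

    def __post_init__(self) -> None:
        self.mirna_labels = _check_labels(self.mirna_labels, "miRNA")
        self.disease_labels = _check_labels(self.disease_labels, "disease")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_labels), len(self.disease_labels)):
            raise DomainError(
                f"value shape {self.values.shape} does not match labels "
                f"({len(self.mirna_labels)}, {len(self.disease_labels)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise NumericError("association matrix contains non-finite entries")
        if self.kind == "binary":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                bad = np.argwhere(~np.isin(self.values, (0.0, 1.0)))[0]
                raise DomainError(
                    "binary association matrix has a non-0/1 entry at "
                    f"row {self.mirna_labels[bad[0]]!r}, "
                    f"column {self.disease_labels[bad[1]]!r}"
                )
        elif self.kind == "imputed":
            if self.values.min() < -SYMMETRY_TOL or self.values.max() > 1 + SYMMETRY_TOL:
                raise DomainError("imputed association values must lie in [0, 1]")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_labels)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "AssociationMatrix":
        return replace(self, values=self.values.copy())

    def mirna_index(self, label: str) -> int:
        try:
            return self.mirna_labels.index(label)
        except ValueError:
            raise IdentifierError(f"unknown miRNA {label!r}") from None

    def disease_index(self, label: str) -> int:
        try:
            return self.disease_labels.index(label)
        except ValueError:
            raise IdentifierError(f"unknown disease {label!r}") from None


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix with unit diagonal and entries in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels, "similarity")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DomainError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if np.any(np.isinf(self.values)):
            raise NumericError("similarity matrix contains infinite entries")
        # NaN marks an undefined entry (to be filled from another source);
        # the undefined pattern must itself be symmetric
        defined = ~np.isnan(self.values)
        if not np.array_equal(defined, defined.T):
            raise DomainError("undefined (NaN) entries must appear symmetrically")
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL, rtol=0.0,
                           equal_nan=True):
            raise DomainError("similarity matrix is not symmetric (tol 1e-9)")
        diag = np.diag(self.values)
        if not np.allclose(diag[~np.isnan(diag)], 1.0, atol=SYMMETRY_TOL, rtol=0.0):
            raise DomainError("similarity matrix diagonal must be 1")
        vals = self.values[defined]
        if vals.size and (vals.min() < -SYMMETRY_TOL or vals.max() > 1 + SYMMETRY_TOL):
            raise DomainError("similarity entries must lie in [0, 1]")
        # snap tiny violations so downstream code sees exact invariants
        np.clip(self.values, 0.0, 1.0, out=self.values)
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, np.where(np.isnan(diag), np.nan, 1.0))

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise IdentifierError(f"unknown label {label!r}") from None

    def reorder(self, labels: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy aligned to ``labels`` (must be a subset)."""
        idx = [self.index(l) for l in labels]
        return SimilarityMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class DiseaseDAG:
    """Directed acyclic graph of disease terms; edges point child -> parent."""

    terms: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(str(t) for t in self.terms))
        object.__setattr__(
            self, "edges", frozenset((str(c), str(p)) for c, p in self.edges)
        )
        for c, p in self.edges:
            if c not in self.terms or p not in self.terms:
                raise DomainError(f"edge ({c!r}, {p!r}) references an unknown term")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DomainError(f"disease graph contains a cycle: {cycle}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        return g

    def __contains__(self, term: str) -> bool:
        return term in self.terms


@dataclass(frozen=True)
class SemanticConfig:
    """Decay factor for DAG semantic contributions (default 0.5)."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.delta <= 1.0):
            raise DomainError(f"delta must be in (0, 1], got {self.delta}")


@dataclass(frozen=True)
class WknknConfig:
    """WKNKN parameters: K nearest known neighbors, decay p (defaults 5, 0.7)."""

    K: int = 5
    p: float = 0.7

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DomainError(f"K must be >= 1, got {self.K}")
        if not (0.0 < self.p <= 1.0):
            raise DomainError(f"p must be in (0, 1], got {self.p}")


#: standard search grid for the Tikhonov / L2,1 weight
LAMBDA_L_GRID: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)
#: standard search grid shared by the two collaborative weights
LAMBDA_DT_GRID: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)


@dataclass(frozen=True)
class RcmfConfig:
    """Hyperparameters for the factorization solver.

    ``lambda_l`` weights both the Tikhonov term and (for the RCMF variant)
    the L2,1 row-sparsity penalty on B; ``lambda_21`` may decouple the two.
    ``k=None`` resolves to min(n, m, 50) at fit time.
    """

    lambda_l: float = 1.0
    lambda_d: float = 0.01
    lambda_t: float = 0.01
    k: int | None = None
    max_iter: int = 200
    tol: float = 1e-6
    epsilon: float = 1e-8
    variant: str = "rcmf"  # rcmf | cmf
    lambda_21: float | None = None  # None -> use lambda_l (printed objective)

    def __post_init__(self) -> None:
        for name in ("lambda_l", "lambda_d", "lambda_t"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.k is not None and self.k < 1:
            raise DomainError("k must be >= 1")
        if self.max_iter < 1:
            raise DomainError("max_iter must be >= 1")
        if self.epsilon <= 0:
            raise DomainError("epsilon must be > 0")
        if self.variant not in ("rcmf", "cmf"):
            raise DomainError(f"variant must be 'rcmf' or 'cmf', got {self.variant!r}")

    @property
    def l21_weight(self) -> float:
        if self.variant == "cmf":
            return 0.0
        return self.lambda_l if self.lambda_21 is None else self.lambda_21

    def resolve_k(self, n: int, m: int) -> int:
        k = min(n, m, 50) if self.k is None else self.k
        if k > min(n, m):
            raise DomainError(f"k={k} exceeds min(n, m)={min(n, m)}")
        return k


@dataclass
class FactorPair:
    """Latent factors A (n x k, miRNAs) and B (m x k, diseases)."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.ndim != 2 or self.B.ndim != 2 or self.A.shape[1] != self.B.shape[1]:
            raise DomainError(
                f"incompatible factor shapes {self.A.shape} and {self.B.shape}"
            )
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise NumericError("factors contain non-finite entries")

    @property
    def k(self) -> int:
        return self.A.shape[1]


@dataclass
class FitResult:
    """Converged factors plus the per-iteration objective trace."""

    factors: FactorPair
    objective_trace: np.ndarray
    iterations_run: int
    config: RcmfConfig
    mirna_labels: tuple[str, ...] | None = None
    disease_labels: tuple[str, ...] | None = None


@dataclass(frozen=True)
class CvPlan:
    """Repeated k-fold plan over known association pairs (CV-p)."""

    n_folds: int = 5
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise DomainError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise DomainError("n_repeats must be >= 1")


@dataclass
class CvResult:
    """Mean/sd AUC over CV repeats, with the per-repeat values."""

    auc_mean: float
    auc_sd: float
    per_repeat_auc: np.ndarray
    plan: CvPlan
    config: RcmfConfig


def check_alignment(Y: AssociationMatrix, Sm: SimilarityMatrix | None,
                    Sd: SimilarityMatrix | None) -> None:
    """Raise AlignmentError unless Sm/Sd labels match Y's rows/columns exactly."""
    if Sm is not None and Sm.labels != Y.mirna_labels:
        missing = set(Y.mirna_labels) - set(Sm.labels)
        raise AlignmentError(
            f"miRNA similarity labels do not match association rows"
            + (f"; missing {sorted(missing)[:5]}" if missing else " (order differs)")
        )
    if Sd is not None and Sd.labels != Y.disease_labels:
        missing = set(Y.disease_labels) - set(Sd.labels)
        raise AlignmentError(
            f"disease similarity labels do not match association columns"
            + (f"; missing {sorted(missing)[:5]}" if missing else " (order differs)")
        )
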