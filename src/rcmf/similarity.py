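"""Similarity construction: DAG semantic similarity, GIP kernels, integration.

Disease semantic similarity follows the classic decaying-contribution scheme
on a disease-term DAG: each disease d has a sub-DAG T(d) consisting of d and
all of its ancestors; an ancestor t contributes Delta^depth (via a max over
paths) to d's semantic value, and two diseases are similar in proportion to
the contributions of their shared ancestors.

The Gaussian interaction profile (GIP) kernel measures how alike two
association profiles are: K(i, j) = exp(-gamma * ||y_i - y_j||^2) with the
bandwidth gamma normalized by the mean squared profile norm, so a dataset's
overall association density does not change the similarity scale.
"""

from __future__ import annotations

from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .containers import (
    AssociationMatrix,
    DiseaseDAG,
    SemanticConfig,
    SimilarityMatrix,
)
from .errors import (
    AlignmentError,
    DegenerateInputError,
    DomainError,
    IdentifierError,
)

__all__ = [
    "ancestor_set",
    "contribution",
    "semantic_value",
    "semantic_similarity",
    "gip_kernel",
    "integrate_similarity",
]


def ancestor_set(dag: DiseaseDAG, term: str) -> set[str]:
    """Return T(term): the term plus every ancestor reachable via parent edges."""
    if term not in dag:
        raise IdentifierError(f"unknown disease term {term!r}")
    g = dag.graph()  # edges point child -> parent, so ancestors are descendants
    return {term} | nx.descendants(g, term)


def _contributions(dag: DiseaseDAG, root: str, delta: float) -> dict[str, float]:
    """Semantic contribution D1_root(t) for every t in T(root).

    D1_root(root) = 1; for an ancestor t, D1_root(t) = delta * max over t's
    DAG children that lie inside T(root).  The recursion runs from the root
    outward and is well-founded because the graph is acyclic.
    """
    tset = ancestor_set(dag, root)
    children_in_t: dict[str, list[str]] = {t: [] for t in tset}
    for c, p in dag.edges:
        if p in tset and c in tset:
            children_in_t[p].append(c)

    out: dict[str, float] = {}

    def d1(node: str) -> float:
        if node in out:
            return out[node]
        if node == root:
            val = 1.0
        else:
            kids = children_in_t[node]
            # node != root and node in T(root) => it lies on a path from root,
            # so at least one child is in T(root)
            val = delta * max(d1(c) for c in kids)
        out[node] = val
        return val

    for t in tset:
        d1(t)
    return out


def contribution(dag: DiseaseDAG, root: str, node: str,
                 cfg: SemanticConfig = SemanticConfig()) -> float:
    """D1_root(node): the semantic contribution of ``node`` to disease ``root``."""
    contribs = _contributions(dag, root, cfg.delta)
    if node not in contribs:
        raise DomainError(f"{node!r} is not in the ancestor closure of {root!r}")
    return contribs[node]


def semantic_value(dag: DiseaseDAG, term: str,
                   cfg: SemanticConfig = SemanticConfig()) -> float:
    """DV1(term) = sum of semantic contributions over T(term); always >= 1."""
    return float(sum(_contributions(dag, term, cfg.delta).values()))


def semantic_similarity(dag: DiseaseDAG,
                        cfg: SemanticConfig = SemanticConfig(),
                        terms: Sequence[str] | None = None) -> SimilarityMatrix:
    """Pairwise disease semantic similarity over ``terms`` (default: all, sorted).

    S(i, j) = sum over shared ancestors t of (D1_i(t) + D1_j(t)) divided by
    (DV1(i) + DV1(j)); the diagonal is exactly 1.
    """
    if terms is None:
        terms = sorted(dag.terms)
    terms = list(terms)
    if not terms:
        raise DomainError("term list must be non-empty")
    for t in terms:
        if t not in dag:
            raise IdentifierError(f"unknown disease term {t!r}")

    contribs = {t: _contributions(dag, t, cfg.delta) for t in terms}
    dv = {t: sum(c.values()) for t, c in contribs.items()}

    n = len(terms)
    S = np.eye(n)
    for i in range(n):
        ci = contribs[terms[i]]
        for j in range(i + 1, n):
            cj = contribs[terms[j]]
            shared = ci.keys() & cj.keys()
            num = sum(ci[t] + cj[t] for t in shared)
            S[i, j] = S[j, i] = num / (dv[terms[i]] + dv[terms[j]])
    return SimilarityMatrix(tuple(terms), S)


def gip_kernel(Y: AssociationMatrix,
               axis: Literal["mirna", "disease"],
               bandwidth_scale: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over rows (miRNAs) or columns (diseases).

    gamma = bandwidth_scale / mean_i ||y_i||^2, K(i, j) = exp(-gamma ||y_i - y_j||^2).
    """
    if bandwidth_scale <= 0:
        raise DomainError("bandwidth_scale must be > 0")
    if axis == "mirna":
        profiles, labels = Y.values, Y.mirna_labels
    elif axis == "disease":
        profiles, labels = Y.values.T, Y.disease_labels
    else:
        raise DomainError(f"axis must be 'mirna' or 'disease', got {axis!r}")

    sq_norms = np.sum(profiles**2, axis=1)
    mean_norm = sq_norms.mean()
    if mean_norm == 0.0:
        raise DegenerateInputError(
            "all association profiles are zero; GIP bandwidth undefined"
        )
    gamma = bandwidth_scale / mean_norm
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(labels, (K + K.T) / 2.0)


def integrate_similarity(primary: SimilarityMatrix | None,
                         gip: SimilarityMatrix,
                         mode: Literal["mean", "gip_fill"] = "mean") -> SimilarityMatrix:
    """Combine a primary (functional/semantic) similarity with a GIP kernel.

    ``mean`` averages the two elementwise; ``gip_fill`` keeps the primary
    value and substitutes the GIP value only where the primary is undefined
    (NaN).  Undefined primary entries fall back to GIP in both modes; with
    ``primary=None`` the GIP matrix is returned unchanged.
    """
    if mode not in ("mean", "gip_fill"):
        raise DomainError(f"unknown integration mode {mode!r}")
    if primary is None:
        return gip
    if primary.labels != gip.labels:
        raise AlignmentError("primary and GIP similarity labels differ")
    P, G = primary.values, gip.values
    defined = np.isfinite(P)
    if mode == "mean":
        out = np.where(defined, (np.where(defined, P, 0.0) + G) / 2.0, G)
    else:
        out = np.where(defined, P, G)
    return SimilarityMatrix(gip.labels, out)
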