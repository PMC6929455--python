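"""Synthetic data: planted low-rank association instances and line clouds.

``make_planted`` emulates a miRNA-disease benchmark at desk scale: a binary
association matrix thresholded from a nonnegative rank-k_true score matrix,
with optional label noise and a set of planted-but-masked positives for
hold-out recovery experiments.  ``make_line_cloud`` builds the 2-D
robustness benchmark — points on the line y = x plus off-line noise points —
and ``robustness_experiment`` compares how far the RCMF and CMF rank-1
subspaces rotate away from the line.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import (
    AssociationMatrix,
    FactorPair,
    RcmfConfig,
    SimilarityMatrix,
)
from .errors import DomainError
from .factorization import fit_matrix
from .similarity import gip_kernel

__all__ = [
    "PlantedInstance",
    "LineCloud",
    "make_planted",
    "make_line_cloud",
    "robustness_experiment",
]


@dataclass
class PlantedInstance:
    """A generated benchmark: observed Y, similarities, truth and masked pairs."""

    Y: AssociationMatrix
    Sm: SimilarityMatrix
    Sd: SimilarityMatrix
    true_factors: FactorPair
    truth: np.ndarray  # binary matrix before noise/masking
    held_out: list[tuple[int, int]]  # planted 1s that are 0 in Y
    seed: int


@dataclass
class LineCloud:
    """2-D points: ``n_inliers`` exactly on y = x plus ``n_noise`` off-line."""

    points: np.ndarray  # (n_inliers + n_noise, 2)
    n_inliers: int
    n_noise: int
    seed: int


def make_planted(n: int, m: int, k_true: int, density: float,
                 noise_rate: float, mask_fraction: float,
                 seed: int) -> PlantedInstance:
    """Generate a planted low-rank association instance.

    Nonnegative factors are drawn, their product thresholded so exactly
    round(density * n * m) entries are 1, ``noise_rate`` of all entries are
    flipped, and ``mask_fraction`` of the *true* positives are zeroed out
    and recorded as ``held_out``.  S_m/S_d are GIP kernels of the noiseless
    truth, so the similarities are informative but not leaky about which
    specific entries were masked.
    """
    if not (1 <= k_true <= min(n, m)):
        raise DomainError(f"k_true must be in [1, min(n, m)]")
    for name, v in (("density", density), ("noise_rate", noise_rate),
                    ("mask_fraction", mask_fraction)):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"{name} must be in [0, 1], got {v}")
    n_ones = int(round(density * n * m))
    if n_ones < 1 or n_ones > n * m:
        raise DomainError(
            f"density {density} yields {n_ones} positives on a {n}x{m} matrix"
        )
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.0, 1.0, size=(n, k_true))
    B = rng.uniform(0.0, 1.0, size=(m, k_true))
    scores = A @ B.T
    flat_order = np.argsort(scores, axis=None)[::-1]
    truth = np.zeros(n * m)
    truth[flat_order[:n_ones]] = 1.0
    truth = truth.reshape(n, m)

    Y = truth.copy()
    n_flips = int(round(noise_rate * n * m))
    if n_flips:
        flip = rng.choice(n * m, size=n_flips, replace=False)
        Y.flat[flip] = 1.0 - Y.flat[flip]

    true_ones = np.argwhere(truth == 1)
    n_mask = int(round(mask_fraction * len(true_ones)))
    held: list[tuple[int, int]] = []
    if n_mask:
        pick = rng.choice(len(true_ones), size=n_mask, replace=False)
        for i, j in true_ones[pick]:
            Y[i, j] = 0.0
            held.append((int(i), int(j)))

    mirnas = tuple(f"mir-{i:03d}" for i in range(n))
    diseases = tuple(f"dis-{j:03d}" for j in range(m))
    truth_assoc = AssociationMatrix(mirnas, diseases, truth)
    return PlantedInstance(
        Y=AssociationMatrix(mirnas, diseases, Y),
        Sm=gip_kernel(truth_assoc, "mirna"),
        Sd=gip_kernel(truth_assoc, "disease"),
        true_factors=FactorPair(A, B),
        truth=truth,
        held_out=held,
        seed=seed,
    )


def make_line_cloud(n_inliers: int, n_noise: int,
                    noise_spread: float | None = None,
                    seed: int = 0) -> LineCloud:
    """Sample inliers uniformly on y = x over [-1, 1] plus an off-line cluster.

    Noise points form a one-sided cluster beside the line's midsection:
    along-line coordinate uniform in [0, 0.4 * spread], perpendicular offset
    uniform in [0.5 * spread, 1.5 * spread], all on the same side (default
    spread: half the inlier coordinate range, i.e. 1.0).  Sitting on one
    side, the cluster systematically rotates an unpenalized least-squares
    fit as it grows; sitting beside the line's center, its points have small
    along-subspace coordinates, so a row-sparse coefficient factor can
    discard them — the behavior the robustness experiment probes.
    """
    if n_inliers < 2:
        raise DomainError("need at least 2 inliers to define a line")
    if n_noise < 0:
        raise DomainError("n_noise must be >= 0")
    spread = 1.0 if noise_spread is None else float(noise_spread)
    if spread <= 0:
        raise DomainError("noise_spread must be > 0")
    rng = np.random.default_rng(seed)
    t = rng.uniform(-1.0, 1.0, size=n_inliers)
    inliers = np.column_stack([t, t])
    u = rng.uniform(0.0, 0.4 * spread, size=n_noise)  # along-line position
    o = rng.uniform(0.5 * spread, 1.5 * spread, size=n_noise)  # perp offset
    root2 = np.sqrt(2.0)
    noise = np.column_stack([u - o / root2, u + o / root2])
    pts = np.vstack([inliers, noise])
    return LineCloud(pts[rng.permutation(len(pts))], n_inliers, n_noise, seed)


def _subspace_angle_deg(direction: np.ndarray) -> float:
    """Angle (degrees) between a 2-D direction and the line y = x, sign-blind.

    A fully collapsed fit (zero direction: the row-sparsity penalty pruned
    every point) carries no subspace; reported as the maximal angle 90.
    """
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        warnings.warn("factorization collapsed to zero; no subspace learned",
                      stacklevel=3)
        return 90.0
    target = np.array([1.0, 1.0]) / np.sqrt(2.0)
    d = direction / norm
    return float(np.degrees(np.arccos(min(1.0, abs(float(d @ target))))))


def robustness_experiment(cloud: LineCloud,
                          cfg_rcmf: RcmfConfig | None = None,
                          cfg_cmf: RcmfConfig | None = None
                          ) -> tuple[float, float]:
    """Fit rank-1 RCMF and CMF to the cloud; return the two subspace angles.

    The cloud enters the solver as a 2 x N matrix so the N points are the
    rows of the penalized factor B: the L2,1 penalty can then shrink whole
    noise points out of the fit, which is the robustness mechanism under
    test.  Collaborative terms are disabled (lambda_d = lambda_t = 0); the
    learned direction is the column factor A (2 x 1), compared against
    (1, 1)/sqrt(2).
    """
    if len(cloud.points) == 0:
        raise DomainError("empty point cloud")
    if cfg_rcmf is None:
        cfg_rcmf = RcmfConfig(lambda_l=2.0, lambda_d=0.0, lambda_t=0.0,
                              k=1, variant="rcmf")
    if cfg_cmf is None:
        cfg_cmf = RcmfConfig(lambda_l=2.0, lambda_d=0.0, lambda_t=0.0,
                             k=1, variant="cmf")
    X = cloud.points.T  # 2 x N
    angles = []
    for cfg in (cfg_rcmf, cfg_cmf):
        if cfg.lambda_d != 0 or cfg.lambda_t != 0:
            raise DomainError("robustness experiment requires lambda_d = lambda_t = 0")
        res = fit_matrix(X, None, None, cfg)
        angles.append(_subspace_angle_deg(res.factors.A[:, 0]))
    return angles[0], angles[1]
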