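# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations behind `rcmf`. Nothing here asserts an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and objective

The method factorizes a binary miRNA×disease adjacency matrix
**Y** (n×m) as **AB**ᵀ with latent dimension k, minimizing

    F(A, B) = ‖Y − ABᵀ‖²_F
            + λ_l (‖A‖²_F + ‖B‖²_F)
            + λ_l ‖B‖₂,₁                      (RCMF only)
            + λ_d ‖S_m − AAᵀ‖²_F
            + λ_t ‖S_d − BBᵀ‖²_F.

Assumptions worth making explicit:

- **Low-rank association structure.** Prediction quality rests on the true
  association pattern being approximately low rank; the collaborative
  terms encode "similar entities have similar latent vectors".
- **Zeros are unlabeled, not negative.** A 0 in Y means "no evidence"; the
  WKNKN step and the CV-p evaluation both follow from this reading.
- **One weight for two penalties.** The printed objective uses λ_l for both
  the Tikhonov and L2,1 terms; the implementation keeps them shared by
  default, with `RcmfConfig.lambda_21` available to decouple them when the
  row-sparsity pressure should be tuned independently.

### The update rules, as implemented

The published closed-form updates for this model family contain two
dimensional inconsistencies, resolved here in the only conformable way:

- the A-update's collaborative term enters the k×k normal matrix as
  λ_d·AᵀA (not an n×n Gramian):
  A ← (YB + λ_d S_m A)(BᵀB + λ_l I_k + λ_d AᵀA)⁻¹;
- the L2,1 weight matrix D = diag(1/(2‖Bᵢ‖₂)) is m×m and cannot enter a
  single k×k inverse; the B-update is therefore solved row-wise, each row
  getting its own scalar shift:
  Bᵢ ← Mᵢ (G + λ_l d_ii I_k)⁻¹ with M = YᵀA + λ_t S_d B and
  G = AᵀA + λ_l I_k + λ_t BᵀB.

This row-wise scheme is the standard iteratively-reweighted-least-squares
(IRLS) treatment of an L2,1 penalty. Since the rows share G and differ
only by d_ii on the diagonal, all m solves are performed at once through
one eigendecomposition of G. The CMF variant is exactly the same machinery
with every d_ii = 0.

Terms involving the current factors on the right-hand side (S_m A, S_d B,
BᵀB) use the previous iterate: the scheme is a fixed-point/alternating
iteration, not an exact block minimization.

### Monotonicity safeguards

Because the collaborative terms are quartic in the factors, the linearized
updates are not guaranteed descent steps, and on small problems the plain
alternation can also stall at *scaling saddles* — points where neither
coordinate update improves but jointly shrinking (or growing) both factors
does, typically when the penalties make the all-zero fit competitive. Two
deterministic safeguards address this:

1. **Step damping.** After each A or B update, if the true objective rose,
   the step is halved toward the previous iterate until it does not
   (recovering the previous iterate in the limit, so the loop terminates).
2. **Exact rescaling line search.** After each iteration the objective is
   minimized over the ray (tA, tB), t ≥ 0. Along this ray F is the explicit
   quartic c₀ + c₁t + c₂t² + c₄t⁴ (c₁ from the L2,1 term, c₄ ≥ 0 from the
   reconstruction and collaborative terms), so the optimal t is a root of
   the cubic derivative, computed in closed form.

Neither safeguard moves a fixed point of the update equations, both are
deterministic, and together they make the objective trace non-increasing
in practice across the whole λ grid (asserted by the test suite at 1e-8
relative per step) while letting the solver escape the zero-scale saddle;
on 3×3, k=1 instances the converged objective matches a multi-start
Nelder–Mead minimization of F to well within 1e-4 relative.

### Convergence and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| λ_l | 1.0 | Tikhonov + L2,1 weight; midpoint of the standard grid {2⁻², 2⁻¹, 2⁰, 2¹} |
| λ_d, λ_t | 0.01 | collaborative weights; interior of the grid {0, 10⁻⁴, 10⁻³, 10⁻², 10⁻¹} |
| k | min(n, m, 50) | latent dimension; capped because association matrices at database scale are effectively low rank |
| max_iter | 200 | convergence is typically observed within ~50 iterations; headroom retained |
| tol | 1e-6 | relative objective change for convergence |
| epsilon | 1e-8 | IRLS guard: d_ii = 1/(2 max(‖Bᵢ‖, ε)) smooths the L2,1 derivative at zero rows |

The fit aborts with a diagnostic if the objective ever rises by more than
10% in one iteration (which the safeguards should make unreachable);
singular k×k systems (condition estimate > 1e12) fall back to a
pseudoinverse with a warning. The solver contains no randomness: identical
inputs give bit-identical traces.

## Similarity construction

**DAG semantic similarity.** Each disease d owns the sub-DAG T(d) = {d} ∪
ancestors(d). Contributions decay from the disease outward:
D1_d(d) = 1 and D1_d(t) = Δ·max{D1_d(c) : c a child of t inside T(d)},
with Δ = 0.5. "Children of t" is interpreted within T(d) — the only
reading under which the recursion is anchored at d and well-founded on an
acyclic graph (ties in the max need no tie-break). Two diseases score

    S_d(i, j) = Σ_{t ∈ T(i)∩T(j)} (D1_i(t) + D1_j(t)) / (DV1(i) + DV1(j)),

where DV1 is the sum of contributions; the diagonal is exactly 1. A
consequence of the max over paths is that D1_d(t) = Δ^(shortest
parent-edge distance from d to t in T(d)): contributions decay with
distance, but an ancestor reachable by a shortcut edge can legitimately
outscore a nearer node on a longer branch.

**GIP kernel.** K(i, j) = exp(−γ‖y_i − y_j‖²) over row (miRNA) or column
(disease) profiles, with γ = γ′ / mean‖y_i‖² and γ′ = 1, the normalization
that makes the kernel bandwidth track the dataset's association density.
An all-zero matrix leaves γ undefined and is rejected.

**Integration.** The source material never states how the
functional/semantic similarity and the GIP kernel combine into the single
S_m and S_d; both common conventions are implemented — elementwise mean
(default) and `gip_fill` (GIP only where the primary is undefined) — and
the choice is recorded in every run's config echo.

## WKNKN preprocessing

For each miRNA i, the K most similar miRNAs that have at least one known
association (self excluded, similarity ties broken by label order) predict
its profile as Σ_t p^(t−1)·S(i,i_t)·Y(i_t,·) / Σ_t S(i,i_t); the disease
side is symmetric over columns. Both sides are computed from the original
Y (making the operator order-independent), averaged, and combined with Y
by elementwise max, so known 1-entries are never lowered. Fewer than K
eligible neighbors ⇒ use all available and warn; none ⇒ that side
contributes 0. Defaults K = 5, p = 0.7, where the cross-validated AUC is
observed to stabilize (the `sensitivity_sweep` API regenerates that
analysis).

## Evaluation protocol

CV-p holds out *pairs*: the 1-entries are partitioned into 5 folds
(repeated, default 10 repeats for desk-scale runs; 100 via the CLI),
held-out entries are zeroed in the training copy, and — to keep test
labels out of the pipeline — the GIP kernels, similarity integration and
WKNKN are all recomputed inside each training fold. This is deliberately
stricter than a literal once-globally preprocessing reading, which would
leak held-out labels through the imputation. Held-out positives are scored
against all never-known pairs; AUC is the rank-based (Mann–Whitney)
statistic; the reported sd is the sample sd of per-repeat AUC means. Grid
search iterates the λ grids in ascending order and keeps the first
maximum, so ties resolve toward smaller (less complex) settings. A single
integer seed drives per-repeat substreams (numpy `SeedSequence.spawn`),
recorded in all outputs.

## Synthetic data

**Planted instances** emulate a curated MDA matrix at desk scale: uniform
nonnegative factors of rank k_true, scores thresholded so exactly
round(density·n·m) entries are 1, a fraction of entries flipped as label
noise, and a fraction of the *true* positives masked out as recoverable
hold-outs. S_m/S_d are GIP kernels of the noiseless truth — informative
about the planted structure without encoding which entries were masked.
Defaults (40×30, k_true = 2, density 0.15, noise 0.01, mask 0.1) keep
end-to-end runs in seconds. What passing tests on this generator show:
that the pipeline recovers planted low-rank structure under mild noise.
What they do not show: performance under the heavy-tailed degree
distributions, block structure and annotation biases of real curated
databases — real-data AUC must be measured on real data.

**Line clouds** probe robustness: 200 inliers uniform on y = x over
[−1, 1], plus an off-line noise cluster, fit at rank 1 by both variants
with the collaborative terms off. The noise model was chosen once, to
have the two properties without which the qualitative contrast cannot
appear: the cluster sits on *one side* of the line (symmetric ambient
noise produces no systematic rotation of a least-squares subspace — the
unpenalized direction is the top singular vector, which only rotates under
along/perpendicular correlation) and *beside the line's midsection*, where
its points have small along-subspace coordinates, so a row-sparse
coefficient factor can shrink them away — the mechanism the L2,1 penalty
claims. Concretely: along-line position U(0, 0.4s), perpendicular offset
U(0.5s, 1.5s) on one side, with s = 1 (half the inlier range) by default.

The cloud enters the solver as a 2×N matrix so the N points are rows of
the penalized factor B; the learned direction is the 2-vector factor A,
compared sign-blind against (1,1)/√2. The robustness demo uses λ_l = 2
(the top of the standard grid) for both variants, since the experiment
exists to exhibit the penalty's effect. Notes: the reported angle is
exactly scale-invariant only for the unpenalized variant (the penalties
have mixed homogeneity degree, so rescaling the cloud changes the
effective penalty strength for RCMF); and under a strong penalty on weak
data the fit can collapse entirely (all rows pruned), in which case no
subspace exists and the angle is reported as 90° with a warning.

## File contracts

Labeled matrices travel as tab-delimited UTF-8 with a header row and
first-column labels, values at 12 significant digits (lossless round-trip
at these scales); the disease DAG as a headerless child⟨TAB⟩parent edge
list with `#` comments. All writes are atomic (temp file + rename).
Readers validate invariants up front — binary entries for raw association
matrices, symmetry/unit-diagonal/[0,1] range (tolerance 1e-9) for
similarities, duplicate labels and ragged rows rejected with the offending
row/column named. Matrices must align exactly by label; partial overlap is
a hard error rather than a silent intersection.

## Known limitations

- The alternating solver is a local method; the safeguards remove the
  scaling saddle but global optimality is only verified on tiny instances.
- With λ_d, λ_t at the top of their grids the damped steps can be short;
  convergence then uses more of the iteration budget.
- The per-iteration cost is O(nmk + n²k + m²k) when both collaborative
  terms are active (the similarity products dominate for n ≫ m).
- Semantic similarity is quadratic in the number of terms with a closure
  computation per term — fine for ontology fragments of a few thousand
  terms, not tuned beyond that.
- The robustness experiment's qualitative contrast depends on the noise
  geometry, as discussed above; it is a mechanism probe, not a general
  robustness guarantee.
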