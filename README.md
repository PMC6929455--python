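# rcmf — robust collaborative matrix factorization for miRNA–disease association prediction

Experimentally confirming that a microRNA is involved in a disease is slow
and expensive, so computational ranking of candidate miRNA–disease
associations (MDAs) is used to prioritize lab work. `rcmf` implements a
link-prediction pipeline for this problem aimed at computational biologists
who have (a) a binary miRNA×disease adjacency matrix from a curated database
such as HMDD, (b) a precomputed miRNA functional similarity matrix (e.g.
MISIM scores), and (c) either a disease-term DAG or a precomputed disease
similarity matrix — or who want to study the method itself on synthetic
data, which the package generates.

## The model

Let **Y** ∈ {0,1}<sup>n×m</sup> be the association matrix over *n* miRNAs
and *m* diseases, **S**<sub>m</sub> ∈ ℝ<sup>n×n</sup> and
**S**<sub>d</sub> ∈ ℝ<sup>m×m</sup> similarity matrices. RCMF seeks latent
factors **A** (n×k) and **B** (m×k) minimizing

```
min   ‖Y − ABᵀ‖²_F  +  λ_l (‖A‖²_F + ‖B‖²_F)  +  λ_l ‖B‖_{2,1}
A,B    +  λ_d ‖S_m − AAᵀ‖²_F  +  λ_t ‖S_d − BBᵀ‖²_F
```

where ‖B‖₂,₁ = Σᵢ ‖Bᵢ‖₂ is the L2,1 norm (sum of row norms). The first
term reconstructs the observed network; the Tikhonov term controls scale;
the two *collaborative* terms ask similar miRNAs (diseases) to have similar
latent vectors; and the L2,1 penalty drives entire rows of **B** to zero,
which regularizes the disease factor and makes the fit robust to outliers.
Dropping the L2,1 term recovers classical collaborative matrix
factorization (CMF), included as the `cmf` variant.

The solver initializes **A**, **B** from the truncated SVD of **Y**
(**A** = U<sub>k</sub>S<sub>k</sub><sup>½</sup>,
**B** = V<sub>k</sub>S<sub>k</sub><sup>½</sup>) and alternates closed-form
least-squares updates, handling the non-smooth L2,1 term by iteratively
reweighted least squares with per-row weights d<sub>ii</sub> = 1/(2‖Bᵢ‖₂).
Two deterministic safeguards (step damping and an exact line search over a
joint factor rescaling) keep the objective trace monotone; see
`docs/methods.md`.

Around the factorization the package provides the full protocol:

- **similarity** — disease semantic similarity from a child→parent DAG
  (decaying-contribution scheme, Δ = 0.5), Gaussian interaction profile
  (GIP) kernels from association profiles, and mean/fill integration of the
  two sources;
- **preprocessing** — WKNKN (weighted K-nearest-known-neighbors, defaults
  K = 5, p = 0.7) imputation of likely-missing zeros;
- **evaluation** — repeated 5-fold pair-holdout cross-validation (CV-p)
  with rank-based AUC, λ grid search, and K/p sensitivity sweeps;
- **synthetic** — planted low-rank association benchmarks and the 2-D
  line-cloud robustness experiment comparing RCMF against CMF.

## Worked example

```python
from rcmf import (RcmfConfig, WknknConfig, fit, gip_kernel,
                  integrate_similarity, make_planted, predict_scores,
                  rank_candidates, wknkn)

inst = make_planted(n=40, m=30, k_true=2, density=0.15,
                    noise_rate=0.01, mask_fraction=0.1, seed=2)
Sm = integrate_similarity(inst.Sm, gip_kernel(inst.Y, "mirna"))
Sd = integrate_similarity(inst.Sd, gip_kernel(inst.Y, "disease"))
Yw = wknkn(inst.Y, Sm, Sd, WknknConfig(K=5, p=0.7))
result = fit(Yw, Sm, Sd, RcmfConfig(lambda_l=1.0, lambda_d=0.01, lambda_t=0.01))
ranking = rank_candidates(predict_scores(result), "dis-000", exclude_known=inst.Y)
```

Running this (`python examples/03_fit_and_rank.py`) prints:

```
converged in 19 iterations; objective 98.63 -> 70.93

top 10 miRNAs for dis-000:
rank  miRNA     score   status
   1  mir-036   0.076  candidate
   2  mir-019   0.075  known
   3  mir-021   0.073  candidate
   ...
```

The objective falls monotonically from the SVD start to the converged
value; the ranking for one disease lists miRNAs by predicted association
score, flagging pairs already known in the input. On this synthetic
instance the top "candidate" rows are dominated by planted-but-masked true
associations — the behavior that per-disease prediction tables rely on.
`examples/04_cross_validation.py` evaluates the same pipeline by CV-p (AUC
0.944 over 10×5-fold on the planted benchmark) and
`examples/05_robustness_line.py` reproduces the robustness contrast: with
80 off-line noise points the plain CMF subspace tilts by ~19° while RCMF
stays near ~9°.

The same workflow is scriptable via the `rcmf` CLI
(`simulate`, `similarity`, `wknkn`, `fit`, `predict`, `cv`, `grid`,
`sweep`, `robustness`); every run writes a JSON echo of its configuration
and seed next to its outputs.

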