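# thi — Taylor-based hypergraph inference from time series

`thi` reconstructs **directed pairwise and higher-order interactions**
(hyperedges) among the variables of a dynamical system from multivariate
time-series data, without knowing the node dynamics or the coupling
functions.  It is aimed at researchers in network inference and systems
biology / neuroscience who ask not "what are the equations?" but "**which
variables influence which, and in groups of what size?**" — effective
connectivity, including nonpairwise (triadic and higher) interactions that
ordinary network-inference methods cannot represent.

## The method

Consider coupled systems
ẋᵢ = fᵢ(xᵢ) + Σⱼ a⁽²⁾ᵢⱼ h⁽²⁾(xᵢ,xⱼ) + Σⱼₖ a⁽³⁾ᵢⱼₖ h⁽³⁾(xᵢ,xⱼ,xₖ) + …

Taylor-expanding the right-hand side around a base point x₀ turns the
question "is there a hyperedge {j,k} → i?" into "is some Taylor coefficient
of Fᵢ involving both xⱼ and xₖ nonzero?".  The package estimates these
coefficients by sparse regression: for each target variable i it solves

    ẋᵢ = D(X) vᵢ

where the columns of D are monomials of the deviations Δx = x − x₀ up to a
chosen degree, and vᵢ is made sparse by **sequential thresholded least
squares** (STLSQ, the SINDy solver): iterate {least-squares fit on the
current support; zero every coefficient below λ; refit} until the support is
stable.  Every surviving monomial whose distinct-variable set S (minus the
target) is nonempty witnesses a directed hyperedge S → i of order |S|+1,
scored by the largest contributing coefficient magnitude.  Sweeping an
existence threshold ε over the saved scores afterwards traces the full
ROC curve without re-running the regression.  Because the inference is
per-target, it parallelizes trivially and a subset of nodes can be inferred
without touching the rest.

Included batteries:

* **Simulators** — higher-order Kuramoto phases (pairwise `sin(θⱼ−θᵢ)`,
  triadic `sin(θⱼ+θₖ−2θᵢ)`) and Lorenz oscillators (σ=10, ρ=28, β=8/3)
  coupled through their x-components, on arbitrary hypergraphs; random-state
  or integrated-trajectory sampling with exact or finite-difference
  derivatives.
* **Random structures** — Erdős–Rényi-type random hypergraphs and random
  simplicial complexes (downward-closed).
* **Evaluation** — directed-truth expansion, candidate enumeration, ROC/AUC,
  and the order-ℓ contribution ratios ρ_ℓ (the fraction of the inferred
  derivative magnitude attributable to order-ℓ interactions, with
  ρ₂+ρ₃+ρ₄ = 1).
* **Preprocessing** — sensor grouping, zero-phase low-pass, unit-variance
  scaling, forward differences, near-median sample selection; plus a
  band-limited synthetic multichannel generator with plantable couplings.
* **Pearson pre-filtering** — keep only the ℓ_keep most correlated variable
  pairs and restrict the library accordingly, which is what makes 100+-node
  systems tractable.

## Worked example

Seven phase oscillators on a small simplicial complex (two triangles plus a
pairwise path), 150 random states from a side-0.1 hypercube at the origin
with exact derivatives — the saturated noiseless benchmark:

```python
import thi

sc = thi.build_preset("kuramoto7", seed=7)          # structure + data
scores, fits = thi.infer_all(sc.ts, sc.infer_cfg)   # THIS inference
truth = thi.directed_truth(sc.hypergraph)
cands = thi.candidate_set(7, max_order=3)
curve = thi.roc(scores, truth, cands)
print("AUC:", curve.auc)
for c, v in sorted(scores.items(), key=lambda kv: -kv[1])[:3]:
    print(f"  {sorted(c.sources)} -> {c.target}: {v:.3f}")
```

prints

```
AUC: 1.0
  [0] -> 2: 0.722
  [0] -> 1: 0.722
  [2] -> 1: 0.704
```

AUC = 1.0 means some threshold ε separates all 24 true directed hyperedges
from the other 123 candidates perfectly; the top scores are pairwise
couplings (a unit pairwise coupling plus the linear part of the triads each
member sits in), and the smallest true score (≈ 5.3e-4, a cubic triad
witness) still exceeds the largest spurious score (≈ 6.2e-7) by three orders
of magnitude.

The same pipeline from the shell:

```bash
this simulate --preset kuramoto7 --seed 7 --out-dir run/
this infer --input run/ts.npz --max-order 3 --degree 3 --lambda 0 --out run/scores.tsv
this eval  --scores run/scores.tsv --truth run/truth.tsv --out-prefix run/k7
```

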