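"""End-to-end benchmark runs: simulate → infer → evaluate, one call each.

These functions reproduce the package's headline experiments from a single
seed; they are what the acceptance script and the system-level tests call.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .evaluation import contribution_ratios, roc
from .hypergraphs import candidate_set, directed_truth
from .inference import infer_all
from .presets import build_preset

__all__ = [
    "lorenz_operating_point",
    "lorenz_replicates",
    "filtered_kuramoto_endpoint",
    "kuramoto7_auc",
    "contribution_sum_stats",
]


def lorenz_operating_point(seed: int) -> Tuple[float, float]:
    """One coupled-Lorenz replicate: (best TPR among FPR<0.2 points, AUC).

    Five-node random hypergraph (p=0.5 both orders), 10 trajectories of 150
    steps at dt=0.01 from a side-0.7 box, forward-difference derivatives,
    degree-3 library, node-level max aggregation, ε swept a posteriori.
    """
    sc = build_preset("lorenz5", seed)
    scores, _ = infer_all(sc.ts, sc.infer_cfg)
    truth = directed_truth(sc.hypergraph)
    cands = candidate_set(sc.n_nodes, sc.infer_cfg.max_order)
    curve = roc(scores, truth, cands)
    ok = curve.fpr < 0.2
    best = float(curve.tpr[ok].max()) if ok.any() else 0.0
    return best, curve.auc


def lorenz_replicates(seed: int, n_replicates: int = 10) -> List[float]:
    """Best-TPR-at-FPR<0.2 for ``n_replicates`` independent hypergraphs."""
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, n_replicates)
    return [lorenz_operating_point(int(s))[0] for s in sub]


def filtered_kuramoto_endpoint(seed: int, n: int = 100) -> Dict[str, float]:
    """Correlation-filtered simplicial-complex run; ε→0 end of the truncated
    ROC: returns endpoint TPR/FPR plus bookkeeping counts."""
    sc = build_preset("sc100_filtered", seed, n=n)
    scores, _ = infer_all(sc.ts, sc.infer_cfg)
    truth = directed_truth(sc.hypergraph)
    cands = candidate_set(sc.n_nodes, sc.infer_cfg.max_order)
    curve = roc(scores, truth, cands, filtered=True)
    tpr, fpr = curve.endpoint()
    return {"tpr": tpr, "fpr": fpr, "n_truth": len(truth),
            "n_candidates": len(cands), "n_scored": len(scores),
            "truncated": curve.truncated}


def kuramoto7_auc(seed: int, n_samples: int = 150) -> float:
    """Saturated noiseless benchmark: seven-node complex, exact derivatives."""
    sc = build_preset("kuramoto7", seed, n_samples=n_samples)
    scores, _ = infer_all(sc.ts, sc.infer_cfg)
    truth = directed_truth(sc.hypergraph)
    cands = candidate_set(sc.n_nodes, sc.infer_cfg.max_order)
    return roc(scores, truth, cands).auc


def contribution_sum_stats(seed: int,
                           epsilons=(0.0, 1e-4, 1e-2, 0.1)) -> Dict[str, float]:
    """Order-2..4 contribution ratios on an order-4 inference run; returns the
    extremes of ρ_2 + ρ_3 + ρ_4 over every retained time point and threshold
    (should equal 1 wherever the denominator is nonzero)."""
    from dataclasses import replace

    sc = build_preset("kuramoto7", seed)
    cfg = replace(sc.infer_cfg, max_order=4)
    scores, _ = infer_all(sc.ts, cfg)
    res = contribution_ratios(scores, sc.ts, o=4, epsilons=epsilons)
    sums = res.rho.sum(axis=2)
    valid = ~np.isnan(sums)
    return {
        "min_sum": float(np.min(sums[valid])),
        "max_sum": float(np.max(sums[valid])),
        "n_checked": int(valid.sum()),
    }
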