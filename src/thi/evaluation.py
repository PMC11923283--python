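"""Structure-recovery evaluation: ROC curves and order-ℓ contribution ratios.

ROC curves sweep the existence threshold ε from ∞ down to 0 over the distinct
score values.  At a swept threshold, a candidate is inferred when its score is
≥ that value; the true-positive rate is the fraction of existing directed
hyperedges inferred and the false-positive rate the fraction of nonexistent
ones.  Unscored candidates count as score 0.  When the library was restricted
(correlation filtering), candidates outside the scoreable set can never be
inferred and the curve truncates before (1, 1); a random-completion extension
(straight line to (1, 1)) is available as an option.

The order-ℓ contribution ratio measures how much of the inferred derivative
magnitude is attributable to order-ℓ interactions:

    ρ_ℓ(t) = Σ |â^(ℓ)_{i,S} Π_{j∈S} Δx_j(t)| / Σ_{k=2..o} (same for order k)

summed over all inferred candidates of each order; Σ_ℓ ρ_ℓ = 1 wherever the
denominator is nonzero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .dynamics import TimeSeries
from .hypergraphs import DirectedHyperedge
from .inference import DirectedScores

logger = logging.getLogger(__name__)

__all__ = ["ROCCurve", "ContributionResult", "roc", "contribution_ratios",
           "summarize_distribution"]


@dataclass
class ROCCurve:
    """Threshold sweep: ε values (descending, starting at ∞), TPR/FPR in
    [0, 1] (non-decreasing as ε decreases), and the trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    truncated: bool = False

    def endpoint(self) -> Tuple[float, float]:
        """(TPR, FPR) as ε → 0⁺: every positively scored candidate inferred.

        Unfiltered curves additionally close with a final (1, 1) tie-block
        point (all zero-score candidates inferred at once) so the trapezoidal
        AUC equals the standard ties-at-half-credit AUC; that closure point is
        not the ε → 0⁺ operating point reported here.
        """
        pos = np.nonzero(self.thresholds > 0)[0]
        k = pos[-1] if len(pos) else 0
        return float(self.tpr[k]), float(self.fpr[k])


def _restrict(edges: Iterable[DirectedHyperedge],
              orders: Optional[Sequence[int]]) -> Set[DirectedHyperedge]:
    s = set(edges)
    if orders is None:
        return s
    orders = set(orders)
    return {e for e in s if e.order in orders}


def roc(scores: DirectedScores, truth: Set[DirectedHyperedge],
        candidates: Set[DirectedHyperedge],
        orders: Optional[Sequence[int]] = None,
        filtered: bool = False,
        extend_random: bool = False) -> ROCCurve:
    """ROC curve of a score map against a directed ground truth.

    ``candidates`` is the full universe of possible directed hyperedges
    (truth must be a subset); ``orders`` restricts both truth and candidates
    to the given interaction orders.  ``filtered=True`` marks a run whose
    library was restricted (correlation pre-filtering): candidates outside
    the restricted library can never be inferred, so the curve ends at the
    ε → 0⁺ truncation point unless ``extend_random`` completes it with the
    straight random-completion segment to (1, 1).
    """
    cand = _restrict(candidates, orders)
    pos = _restrict(truth, orders)
    if not pos <= cand:
        raise ValueError("truth must be a subset of the candidate set")
    neg = cand - pos
    if not pos or not neg:
        raise ValueError("ROC undefined: empty truth or empty negative set")

    smap = {c: v for c, v in scores.items() if c in cand}
    pos_scores = np.sort(np.array([smap.get(c, 0.0) for c in pos]))
    neg_scores = np.sort(np.array([smap.get(c, 0.0) for c in neg]))
    values = np.unique(np.concatenate([
        [v for v in smap.values() if v > 0] or [np.inf]]))
    values = values[np.isfinite(values)][::-1]  # descending positive scores

    thresholds = [np.inf]
    tp = [0]
    fp = [0]
    for v in values:
        tp.append(len(pos_scores) - np.searchsorted(pos_scores, v, side="left"))
        fp.append(len(neg_scores) - np.searchsorted(neg_scores, v, side="left"))
    thresholds += list(values)
    truncated = False
    if not filtered:
        # zero-score candidates enter as one final tie block: the straight
        # segment to (1, 1) gives ties half credit in the trapezoidal AUC
        thresholds.append(0.0)
        tp.append(len(pos_scores))
        fp.append(len(neg_scores))
    else:
        # filtered run: pruned/unreachable candidates are never inferred at
        # any ε ≥ 0, so the curve ends at the ε → 0⁺ point and truncates
        thresholds.append(0.0)
        tp.append(tp[-1])
        fp.append(fp[-1])
        truncated = tp[-1] < len(pos_scores) or fp[-1] < len(neg_scores)
        if truncated and extend_random:
            thresholds.append(0.0)
            tp.append(len(pos_scores))
            fp.append(len(neg_scores))
            truncated = False

    tpr = np.array(tp, dtype=float) / len(pos_scores)
    fpr = np.array(fp, dtype=float) / len(neg_scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(np.array(thresholds), tpr, fpr, auc, truncated=bool(truncated))


@dataclass
class ContributionResult:
    """ρ_ℓ per (threshold ε, time point, order), plus per-series medians of
    the higher-order share ρ_3 + ρ_4 and the valid-denominator mask."""

    epsilons: np.ndarray
    orders: Tuple[int, ...]
    rho: np.ndarray        # (n_eps, K, n_orders); NaN where denominator == 0
    rho_bar: np.ndarray    # (n_eps, n_series) median_t of rho_3 (+ rho_4)
    series_lengths: List[int]

    def higher_order_share(self) -> np.ndarray:
        """ρ(s,t) = ρ_3 + ρ_4 per (ε, t)."""
        idx = [i for i, o in enumerate(self.orders) if o >= 3]
        return self.rho[:, :, idx].sum(axis=2)


def contribution_ratios(scores: DirectedScores, ts: TimeSeries, o: int = 4,
                        epsilons: Sequence[float] = (0.0,)) -> ContributionResult:
    """Order-ℓ contribution ratios of the inferred coefficient tensors.

    For each ε, only candidates with score > ε contribute.  Deviations from
    the series' base point are used, on the same samples used for fitting.
    Time points with zero denominator yield NaN ratios and are excluded from
    the per-series medians (logged).
    """
    if o < 2:
        raise ValueError("maximal order o must be >= 2")
    dev = ts.deviations()
    K = dev.shape[0]
    orders = tuple(range(2, o + 1))
    epsilons = np.asarray(list(epsilons), dtype=float)

    # per-candidate time profile |score * prod_j dev_j|
    cands = [(c, v) for c, v in scores.items() if c.order <= o]
    profiles = np.zeros((len(cands), K))
    for idx, (c, v) in enumerate(cands):
        prod = np.ones(K)
        for j in c.sources:
            prod *= dev[:, j]
        profiles[idx] = np.abs(v * prod)
    cand_scores = np.array([v for _, v in cands])
    cand_order = np.array([c.order for c, _ in cands])

    rho = np.full((len(epsilons), K, len(orders)), np.nan)
    n_series = len(ts.series_lengths)
    rho_bar = np.full((len(epsilons), n_series), np.nan)
    for ei, eps in enumerate(epsilons):
        act = cand_scores > eps
        nums = np.zeros((len(orders), K))
        for oi, order in enumerate(orders):
            sel = act & (cand_order == order)
            if sel.any():
                nums[oi] = profiles[sel].sum(axis=0)
        denom = nums.sum(axis=0)
        valid = denom > 0
        if not valid.all():
            logger.warning("ε=%g: %d time point(s) with zero denominator excluded",
                           eps, int((~valid).sum()))
        rho[ei, valid] = (nums[:, valid] / denom[valid]).T
        hi = [oi for oi, order in enumerate(orders) if order >= 3]
        share_t = rho[ei][:, hi].sum(axis=1) if hi else np.zeros(K)
        for si, sl in enumerate(ts.series_slices()):
            vals = share_t[sl]
            vals = vals[~np.isnan(rho[ei][sl][:, 0])] if len(vals) else vals
            if len(vals):
                rho_bar[ei, si] = float(np.median(vals))
    return ContributionResult(epsilons, orders, rho, rho_bar,
                              list(ts.series_lengths))


def summarize_distribution(values: np.ndarray) -> Dict[str, float]:
    """Median and the 10/25/75/90% quantiles of a sample (NaNs dropped)."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    qs = np.quantile(v, [0.10, 0.25, 0.50, 0.75, 0.90])
    return {"q10": float(qs[0]), "q25": float(qs[1]), "median": float(qs[2]),
            "q75": float(qs[3]), "q90": float(qs[4])}
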