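"""Taylor-based hypergraph inference via sparse regression (THIS).

Per target variable, the derivative is regressed on a monomial library of
state deviations; every support monomial whose distinct-variable set S
(excluding the target) is nonempty witnesses a directed hyperedge S → target
of order |S| + 1.  A candidate hyperedge's score is the maximum coefficient
magnitude over its contributing monomials.  Sweeping an existence threshold ε
over the saved scores yields ROC curves without re-running the regression.

The hyperedge order is read off the *distinct-variable set*, not the monomial
degree: for odd coupling functions (e.g. phase couplings expanded around 0)
the second-order cross derivative ∂_{jk} vanishes at the base point while
cubic monomials such as x_i x_j x_k still witness the triad {j,k} → i, so the
set rule strictly generalizes the degree-(p−1) ↔ order-p correspondence.

For multi-degree-of-freedom nodes (e.g. 3-D Lorenz oscillators) inference runs
at the variable level and node-level scores take the largest coefficient
between any degrees of freedom of the nodes involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .dynamics import TimeSeries, finite_difference
from .hypergraphs import DirectedHyperedge, Edge
from .sindy import (MonomialLibrary, SparseFit, build_library, design_matrix,
                    library_from_exponents, stlsq)

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "DirectedScores",
    "infer_node",
    "infer_all",
    "score_from_fit",
    "threshold_scores",
    "correlation_filter",
    "aggregate_multidof",
]


@dataclass
class InferenceConfig:
    """Knobs of the inference.

    max_order
        Highest interaction order sought (2–4); source sets have ≤ max_order−1
        nodes.
    library_degree
        Maximal monomial degree; defaults to max_order − 1.  Detecting odd
        couplings around a symmetric base point needs degree = max_order
        (cubic witnesses for triads), so the Kuramoto presets use 3.
    lam
        STLSQ sparsity threshold, applied on the unit-norm column scale when
        ``normalize_columns`` is on.
    epsilon
        Default existence threshold; usually swept a posteriori.
    base_point_rule
        'auto' (the series' own base point, else the data mean), 'zero',
        'data_mean', 'data_median', or 'user' (supply ``base_point``).
    l_keep
        Optional Pearson-correlation pair budget; restricts the library to
        monomials all of whose internal variable pairs are kept.
    dof_per_node
        Degrees of freedom per node; >1 triggers node-level aggregation.
    score_scale
        'normalized' scores by |v|·‖column‖ (comparable across monomial
        degrees; the default), 'original' by the raw coefficient magnitude.
    score_reduce
        'max' (default) or 'sum' over monomials contributing to one candidate.
    """

    max_order: int = 3
    library_degree: Optional[int] = None
    lam: float = 0.0
    epsilon: float = 0.0
    base_point_rule: str = "auto"
    base_point: Optional[np.ndarray] = None
    l_keep: Optional[int] = None
    dof_per_node: int = 1
    seed: int = 0
    normalize_columns: bool = True
    max_iter: int = 20
    score_scale: str = "normalized"
    score_reduce: str = "max"

    def __post_init__(self) -> None:
        if self.max_order not in (2, 3, 4):
            raise ValueError("max_order must be in {2, 3, 4}")
        if self.library_degree is None:
            self.library_degree = self.max_order - 1
        if self.library_degree < self.max_order - 1:
            raise ValueError("library_degree must be >= max_order - 1")
        if self.base_point_rule not in ("auto", "zero", "data_mean",
                                        "data_median", "user"):
            raise ValueError(f"unknown base_point_rule {self.base_point_rule!r}")
        if self.score_scale not in ("normalized", "original"):
            raise ValueError("score_scale must be 'normalized' or 'original'")
        if self.score_reduce not in ("max", "sum"):
            raise ValueError("score_reduce must be 'max' or 'sum'")


class DirectedScores:
    """Nonnegative scores on directed hyperedge candidates, with provenance."""

    def __init__(self) -> None:
        self.scores: Dict[DirectedHyperedge, float] = {}
        self.provenance: Dict[DirectedHyperedge, Tuple[int, ...]] = {}

    def add(self, cand: DirectedHyperedge, value: float,
            monomial: Optional[Tuple[int, ...]] = None,
            reduce: str = "max") -> None:
        if value < 0:
            raise ValueError("scores must be nonnegative")
        old = self.scores.get(cand)
        if old is None or (reduce == "max" and value > old):
            self.scores[cand] = value if old is None or reduce == "max" else old + value
            if reduce == "max" or old is None:
                self.provenance[cand] = monomial
        elif reduce == "sum":
            self.scores[cand] = old + value
        # reduce == "max" with value <= old: keep existing

    def merge(self, other: "DirectedScores") -> None:
        for cand, v in other.scores.items():
            self.add(cand, v, other.provenance.get(cand), reduce="max")

    def per_target(self, target: int) -> Dict[Edge, float]:
        return {c.sources: v for c, v in self.scores.items() if c.target == target}

    def by_order(self, order: int) -> Dict[DirectedHyperedge, float]:
        return {c: v for c, v in self.scores.items() if c.order == order}

    def items(self):
        return self.scores.items()

    def __len__(self) -> int:
        return len(self.scores)


def threshold_scores(scores: DirectedScores, epsilon: float) -> Set[DirectedHyperedge]:
    """Candidates with score strictly above ε; monotone in ε."""
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    return {c for c, v in scores.items() if v > epsilon}


def resolve_base_point(ts: TimeSeries, cfg: InferenceConfig) -> np.ndarray:
    rule = cfg.base_point_rule
    if rule == "auto":
        if ts.base_point is not None:
            return ts.base_point
        rule = "data_mean"
    if rule == "zero":
        return np.zeros(ts.n_vars)
    if rule == "data_mean":
        return ts.X.mean(axis=0)
    if rule == "data_median":
        return np.median(ts.X, axis=0)
    if cfg.base_point is None:
        raise ValueError("base_point_rule='user' requires cfg.base_point")
    return np.broadcast_to(np.asarray(cfg.base_point, float), (ts.n_vars,))


def correlation_filter(ts: TimeSeries, l_keep: int,
                       signal: str = "auto") -> Set[Edge]:
    """Keep the ``l_keep`` variable pairs of largest |Pearson correlation|.

    ``signal`` selects what is correlated: 'auto' uses the derivative signals
    when present (shared hyperedge terms appear in every member's equation, so
    coupled nodes have correlated derivatives even when the states themselves
    are sampled independently), falling back to the states; 'X' / 'Xdot'
    force one or the other.  Zero-variance signals get correlation 0 with a
    logged warning.  Ties are broken by lexicographic pair order.
    """
    if l_keep < 1:
        raise ValueError("l_keep must be >= 1")
    if signal == "auto":
        M = ts.Xdot if ts.Xdot is not None else ts.X
    elif signal == "X":
        M = ts.X
    elif signal == "Xdot":
        if ts.Xdot is None:
            raise ValueError("no derivatives available for signal='Xdot'")
        M = ts.Xdot
    else:
        raise ValueError(f"unknown signal {signal!r}")
    n = M.shape[1]
    stds = M.std(axis=0)
    if np.any(stds == 0):
        logger.warning("zero-variance signal(s) %s: correlations set to 0",
                       np.nonzero(stds == 0)[0].tolist())
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(M, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    pairs = [(abs(C[i, j]), (i, j)) for i, j in combinations(range(n), 2)]
    pairs.sort(key=lambda p: (-p[0], p[1]))
    return {frozenset(p) for _, p in pairs[:l_keep]}


def _filtered_exponent_rows(n_vars: int, degree: int, target: int,
                            kept: Set[Edge]) -> List[np.ndarray]:
    """Monomials whose every internal pair of distinct variables — target
    included — lies in the kept-pair set."""
    neighbors = sorted(v for v in range(n_vars)
                       if v != target and frozenset((target, v)) in kept)
    nb = set(neighbors)
    var_sets: List[Tuple[int, ...]] = [()]
    singles = sorted({target, *neighbors})
    var_sets += [(v,) for v in singles]
    if degree >= 2:
        for u, v in combinations(neighbors, 2):
            if frozenset((u, v)) in kept:
                var_sets.append((u, v))
        for v in neighbors:
            var_sets.append(tuple(sorted((target, v))))
    if degree >= 3:
        for u, v, w in combinations(neighbors, 3):
            if (frozenset((u, v)) in kept and frozenset((u, w)) in kept
                    and frozenset((v, w)) in kept):
                var_sets.append((u, v, w))
        for u, v in combinations(neighbors, 2):
            if frozenset((u, v)) in kept:
                var_sets.append(tuple(sorted((target, u, v))))
    # drop duplicates (target may equal a neighbor-pair member never happens,
    # but (target,v) could coincide with a neighbor pair ordering)
    var_sets = sorted(set(var_sets), key=lambda s: (len(s), s))
    rows: List[np.ndarray] = []
    for vs in var_sets:
        m = len(vs)
        if m == 0:
            rows.append(np.zeros(n_vars, dtype=int))
            continue
        # distribute degree: every member exponent >= 1, total <= degree
        for alloc in _allocations(m, degree):
            e = np.zeros(n_vars, dtype=int)
            for v, a in zip(vs, alloc):
                e[v] = a
            rows.append(e)
    return rows


def _allocations(m: int, degree: int) -> List[Tuple[int, ...]]:
    """All exponent tuples of length m, entries >= 1, sum <= degree,
    in graded order."""
    out: List[Tuple[int, ...]] = []

    def rec(prefix: Tuple[int, ...], remaining: int, left: int) -> None:
        if remaining == 0:
            out.append(prefix)
            return
        for a in range(1, left - (remaining - 1) + 1):
            rec(prefix + (a,), remaining - 1, left - a)

    rec((), m, degree)
    out.sort(key=lambda t: (sum(t), t))
    return out


def _ensure_derivatives(ts: TimeSeries) -> TimeSeries:
    if ts.Xdot is not None:
        return ts
    if ts.t is None:
        raise ValueError("TimeSeries has neither derivatives nor sample times")
    dts = np.diff(ts.t[: ts.series_lengths[0]])
    dt = float(dts[0])
    if not np.allclose(dts, dt):
        raise ValueError("finite differences require uniform sampling")
    X, Xdot, lengths = finite_difference(ts.X, dt, ts.series_lengths)
    t = np.concatenate([ts.t[s][:-1] for s in ts.series_slices()])
    return TimeSeries(X=X, t=t, Xdot=Xdot, base_point=ts.base_point,
                      series_lengths=lengths)


def _library_for_target(ts: TimeSeries, target: int, cfg: InferenceConfig,
                        kept: Optional[Set[Edge]]) -> MonomialLibrary:
    if kept is None:
        return build_library(ts.n_vars, cfg.library_degree)
    rows = _filtered_exponent_rows(ts.n_vars, cfg.library_degree, target, kept)
    return library_from_exponents(ts.n_vars, cfg.library_degree, rows)


def score_from_fit(fit: SparseFit, lib: MonomialLibrary, target: int,
                   cfg: InferenceConfig) -> DirectedScores:
    """Map support monomials to directed hyperedge scores.

    A monomial whose distinct-variable set minus the target is empty encodes
    intrinsic dynamics (no edge); larger sets witness an incoming hyperedge of
    order |S| + 1, capped at cfg.max_order.
    """
    coeffs = (fit.scaled_coefficients if cfg.score_scale == "normalized"
              else fit.coefficients)
    out = DirectedScores()
    for m in fit.support:
        S = lib.variables[m] - {target}
        if not S or len(S) > cfg.max_order - 1:
            continue
        cand = DirectedHyperedge(target, frozenset(S))
        out.add(cand, abs(float(coeffs[m])),
                monomial=tuple(lib.exponents[m]), reduce=cfg.score_reduce)
    return out


def infer_node(ts: TimeSeries, target: int, cfg: InferenceConfig,
               kept_pairs: Optional[Set[Edge]] = None,
               lib: Optional[MonomialLibrary] = None,
               ) -> Tuple[SparseFit, DirectedScores]:
    """Infer the hyperedges pointing into one target variable.

    Independent of every other target: results are identical regardless of
    the order in which targets are processed.
    """
    ts = _ensure_derivatives(ts)
    if not 0 <= target < ts.n_vars:
        raise IndexError(f"target {target} out of range for {ts.n_vars} variables")
    if ts.n_samples < 2:
        raise ValueError("need at least 2 samples for inference")
    if kept_pairs is None and cfg.l_keep is not None:
        kept_pairs = correlation_filter(ts, cfg.l_keep)
    if lib is None:
        lib = _library_for_target(ts, target, cfg, kept_pairs)
    x0 = resolve_base_point(ts, cfg)
    work = TimeSeries(X=ts.X, t=ts.t, Xdot=ts.Xdot, base_point=x0,
                      series_lengths=ts.series_lengths)
    D = design_matrix(lib, work)
    fit = stlsq(D, work.Xdot[:, target], cfg.lam, max_iter=cfg.max_iter,
                normalize_columns=cfg.normalize_columns)
    return fit, score_from_fit(fit, lib, target, cfg)


def infer_all(ts: TimeSeries, cfg: InferenceConfig,
              ) -> Tuple[DirectedScores, Dict[int, SparseFit]]:
    """Run inference for every variable and merge the scores.

    With ``cfg.dof_per_node > 1`` the variable-level scores are aggregated to
    node level (largest coefficient between any degrees of freedom).
    """
    ts = _ensure_derivatives(ts)
    if cfg.dof_per_node > 1 and ts.n_vars % cfg.dof_per_node:
        raise ValueError(
            f"{ts.n_vars} variables not divisible by dof_per_node={cfg.dof_per_node}")
    kept = correlation_filter(ts, cfg.l_keep) if cfg.l_keep is not None else None
    shared_lib = (build_library(ts.n_vars, cfg.library_degree)
                  if kept is None else None)
    merged = DirectedScores()
    fits: Dict[int, SparseFit] = {}
    for target in range(ts.n_vars):
        lib = shared_lib if shared_lib is not None else _library_for_target(
            ts, target, cfg, kept)
        fit, sc = infer_node(ts, target, cfg, kept_pairs=kept, lib=lib)
        fits[target] = fit
        merged.merge(sc)
    if cfg.dof_per_node > 1:
        merged = aggregate_multidof(merged, cfg.dof_per_node)
    return merged, fits


def aggregate_multidof(scores: DirectedScores, dof_per_node: int) -> DirectedScores:
    """Collapse variable-level scores to node level.

    Variable v belongs to node ⌊v/dof⌋.  A node-level candidate's score is the
    max over all variable-level candidates whose source variables map onto
    that node set (the target's own node excluded); candidates entirely within
    one node are dropped.
    """
    if dof_per_node < 1:
        raise ValueError("dof_per_node must be positive")
    out = DirectedScores()
    for cand, v in scores.items():
        t_node = cand.target // dof_per_node
        src_nodes = frozenset(s // dof_per_node for s in cand.sources) - {t_node}
        if not src_nodes:
            continue
        out.add(DirectedHyperedge(t_node, src_nodes), v,
                scores.provenance.get(cand), reduce="max")
    return out
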