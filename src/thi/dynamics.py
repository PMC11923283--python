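"""Benchmark dynamical systems on hypergraphs and synthetic sampling.

Two canonical systems are provided: a higher-order Kuramoto model (phase
oscillators with pairwise ``sin(θ_j − θ_i)`` and triadic
``sin(θ_j + θ_k − 2 θ_i)`` couplings) and Lorenz oscillators coupled through
their x-components by diffusive pairwise terms and cubic triadic terms.

Data can be sampled either as i.i.d. random states in a hypercube with exact
derivatives (the regime where a Taylor expansion around the box center is most
accurate), or as integrated trajectories with forward-finite-difference
derivatives.  Both samplers are deterministic given a seed.

Conventions
-----------
* Each unordered hyperedge contributes ONCE to each member node's equation.
  The triadic coupling functions are symmetrized in the two source nodes;
  ``ordered_pairs=True`` restores the sum-over-ordered-pairs convention (a
  factor of two, irrelevant for binary structure inference).
* Phases are not wrapped during simulation.
* Forward differences: ``ẋ(t_k) = (x(t_{k+1}) − x(t_k)) / Δt``, the last point
  of each series dropped; differences never span two series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy import sparse

from .hypergraphs import Hypergraph

__all__ = [
    "TimeSeries",
    "SamplingConfig",
    "KuramotoModel",
    "LorenzNetworkModel",
    "kuramoto_field",
    "lorenz_field",
    "sample_random_states",
    "integrate_trajectories",
    "finite_difference",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class TimeSeries:
    """Sample matrix ``X`` (K × n), optional sample times and derivatives.

    ``base_point`` is the Taylor-expansion base point x0: regression features
    are built from deviations ``X − x0``.  ``series_lengths`` partitions the
    rows into independent series (finite differences never cross a boundary).
    """

    X: np.ndarray
    t: Optional[np.ndarray] = None
    Xdot: Optional[np.ndarray] = None
    base_point: Optional[np.ndarray] = None
    series_lengths: Optional[List[int]] = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.Xdot is not None:
            self.Xdot = np.asarray(self.Xdot, dtype=float)
            if self.Xdot.shape != self.X.shape:
                raise ValueError(
                    f"X {self.X.shape} and Xdot {self.Xdot.shape} shapes disagree"
                )
        if self.base_point is not None:
            self.base_point = np.broadcast_to(
                np.asarray(self.base_point, dtype=float), (self.X.shape[1],)
            ).copy()
        if self.series_lengths is None:
            self.series_lengths = [self.X.shape[0]]
        if sum(self.series_lengths) != self.X.shape[0]:
            raise ValueError("series_lengths must sum to the number of rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    def deviations(self) -> np.ndarray:
        if self.base_point is None:
            raise ValueError("TimeSeries has no base point")
        return self.X - self.base_point

    def series_slices(self) -> List[slice]:
        out, start = [], 0
        for ln in self.series_lengths:
            out.append(slice(start, start + ln))
            start += ln
        return out


@dataclass
class SamplingConfig:
    """Where and how to sample a vector field.

    ``mode='random_states'`` draws ``n_samples`` i.i.d. uniform points from the
    hypercube of side ``box_side`` centered at ``base_point`` and evaluates
    derivatives exactly.  ``mode='trajectories'`` integrates ``n_series``
    trajectories of ``n_steps`` states at step ``dt`` (initial conditions drawn
    from the same hypercube) and computes derivatives exactly or by forward
    finite differences.
    """

    mode: str = "random_states"
    box_side: float = 0.1
    base_point: np.ndarray | float = 0.0
    n_samples: int = 150
    n_series: int = 10
    n_steps: int = 150
    dt: float = 0.01
    derivative_mode: str = "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random_states", "trajectories"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        if self.mode == "trajectories" and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.derivative_mode not in ("exact", "finite_difference"):
            raise ValueError(f"unknown derivative_mode {self.derivative_mode!r}")
        if self.mode == "random_states" and self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mode == "trajectories" and (self.n_series < 1 or self.n_steps < 2):
            raise ValueError("need n_series >= 1 and n_steps >= 2")


def _incidence(pairs: List[Tuple[int, int]], n_terms: int, n: int) -> sparse.csr_matrix:
    """Sparse (n_terms × n) matrix accumulating per-term contributions to nodes."""
    rows = [r for r, _ in pairs]
    cols = [c for _, c in pairs]
    return sparse.csr_matrix(
        (np.ones(len(pairs)), (rows, cols)), shape=(n_terms, n)
    )


class KuramotoModel:
    """Phase oscillators on a hypergraph.

    θ̇_i = ω_i + Σ_{pairs {i,j}} sin(θ_j − θ_i)
               + Σ_{triples {i,j,k}} sin(θ_j + θ_k − 2 θ_i)
    """

    def __init__(self, hypergraph: Hypergraph, omega: np.ndarray,
                 ordered_pairs: bool = False):
        self.hypergraph = hypergraph
        self.omega = np.asarray(omega, dtype=float)
        if self.omega.shape != (hypergraph.n,):
            raise ValueError("omega must have one entry per node")
        self.ordered_pairs = ordered_pairs
        n = hypergraph.n
        # pair terms: for {i,j} one term per member (target, other)
        p_tgt, p_src = [], []
        for e in sorted(hypergraph.edges2, key=sorted):
            i, j = sorted(e)
            p_tgt += [i, j]
            p_src += [j, i]
        self._p_tgt = np.array(p_tgt, dtype=int)
        self._p_src = np.array(p_src, dtype=int)
        self._p_acc = _incidence(list(zip(range(len(p_tgt)), p_tgt)), len(p_tgt), n)
        # triple terms: for {i,j,k} one term per member
        t_tgt, t_a, t_b = [], [], []
        for e in sorted(hypergraph.edges3, key=sorted):
            i, j, k = sorted(e)
            for tgt, (a, b) in ((i, (j, k)), (j, (i, k)), (k, (i, j))):
                t_tgt.append(tgt); t_a.append(a); t_b.append(b)
        self._t_tgt = np.array(t_tgt, dtype=int)
        self._t_a = np.array(t_a, dtype=int)
        self._t_b = np.array(t_b, dtype=int)
        self._t_acc = _incidence(list(zip(range(len(t_tgt)), t_tgt)), len(t_tgt), n)

    @classmethod
    def with_random_frequencies(cls, hypergraph: Hypergraph, seed: int,
                                low: float = -1.0, high: float = 1.0,
                                **kw) -> "KuramotoModel":
        rng = np.random.default_rng(seed)
        return cls(hypergraph, rng.uniform(low, high, hypergraph.n), **kw)

    @property
    def n_vars(self) -> int:
        return self.hypergraph.n

    def field(self, theta: np.ndarray) -> np.ndarray:
        """Vector field; accepts a single state ``(n,)`` or a batch ``(K, n)``."""
        th = np.asarray(theta, dtype=float)
        single = th.ndim == 1
        th2 = np.atleast_2d(th)
        if th2.shape[1] != self.n_vars:
            raise ValueError(f"state has {th2.shape[-1]} entries, expected {self.n_vars}")
        out = np.broadcast_to(self.omega, th2.shape).copy()
        w = 2.0 if self.ordered_pairs else 1.0
        if len(self._p_tgt):
            terms = np.sin(th2[:, self._p_src] - th2[:, self._p_tgt])
            out += terms @ self._p_acc
        if len(self._t_tgt):
            terms = w * np.sin(
                th2[:, self._t_a] + th2[:, self._t_b] - 2.0 * th2[:, self._t_tgt]
            )
            out += terms @ self._t_acc
        return out[0] if single else out


class LorenzNetworkModel:
    """Lorenz oscillators coupled through their x-components.

    ẋ_i = σ(y_i − x_i) + Σ_{pairs {i,j}} (x_j − x_i)
                        + Σ_{triples {i,j,k}} ((x_j x_k² + x_k x_j²)/2 − x_i³)
    ẏ_i = x_i(ρ − z_i) − y_i
    ż_i = x_i y_i − β z_i

    State layout: node i owns variables (x, y, z) at indices 3i, 3i+1, 3i+2.
    """

    def __init__(self, hypergraph: Hypergraph, sigma: float = 10.0,
                 rho: float = 28.0, beta: float = 8.0 / 3.0,
                 ordered_pairs: bool = False):
        if min(sigma, rho, beta) <= 0:
            raise ValueError("Lorenz parameters must be positive")
        self.hypergraph = hypergraph
        self.sigma, self.rho, self.beta = float(sigma), float(rho), float(beta)
        self.ordered_pairs = ordered_pairs
        n = hypergraph.n
        p_tgt, p_src = [], []
        for e in sorted(hypergraph.edges2, key=sorted):
            i, j = sorted(e)
            p_tgt += [i, j]
            p_src += [j, i]
        self._p_tgt = np.array(p_tgt, dtype=int)
        self._p_src = np.array(p_src, dtype=int)
        self._p_acc = _incidence(list(zip(range(len(p_tgt)), p_tgt)), len(p_tgt), n)
        t_tgt, t_a, t_b = [], [], []
        for e in sorted(hypergraph.edges3, key=sorted):
            i, j, k = sorted(e)
            for tgt, (a, b) in ((i, (j, k)), (j, (i, k)), (k, (i, j))):
                t_tgt.append(tgt); t_a.append(a); t_b.append(b)
        self._t_tgt = np.array(t_tgt, dtype=int)
        self._t_a = np.array(t_a, dtype=int)
        self._t_b = np.array(t_b, dtype=int)
        self._t_acc = _incidence(list(zip(range(len(t_tgt)), t_tgt)), len(t_tgt), n)

    @property
    def n_vars(self) -> int:
        return 3 * self.hypergraph.n

    def field(self, state: np.ndarray) -> np.ndarray:
        s = np.asarray(state, dtype=float)
        single = s.ndim == 1
        s2 = np.atleast_2d(s)
        if s2.shape[1] != self.n_vars:
            raise ValueError(f"state has {s2.shape[-1]} entries, expected {self.n_vars}")
        x, y, z = s2[:, 0::3], s2[:, 1::3], s2[:, 2::3]
        xdot = self.sigma * (y - x)
        w = 2.0 if self.ordered_pairs else 1.0
        if len(self._p_tgt):
            terms = x[:, self._p_src] - x[:, self._p_tgt]
            xdot = xdot + terms @ self._p_acc
        if len(self._t_tgt):
            xa, xb, xt = x[:, self._t_a], x[:, self._t_b], x[:, self._t_tgt]
            terms = w * (0.5 * (xa * xb**2 + xb * xa**2) - xt**3)
            xdot = xdot + terms @ self._t_acc
        ydot = x * (self.rho - z) - y
        zdot = x * y - self.beta * z
        out = np.empty_like(s2)
        out[:, 0::3], out[:, 1::3], out[:, 2::3] = xdot, ydot, zdot
        return out[0] if single else out


def kuramoto_field(model: KuramotoModel, theta: np.ndarray) -> np.ndarray:
    return model.field(theta)


def lorenz_field(model: LorenzNetworkModel, state: np.ndarray) -> np.ndarray:
    return model.field(state)


def _box_samples(rng: np.random.Generator, x0: np.ndarray, side: float,
                 shape: Tuple[int, ...]) -> np.ndarray:
    return x0 + rng.uniform(-side / 2.0, side / 2.0, shape)


def sample_random_states(field: Callable[[np.ndarray], np.ndarray],
                         cfg: SamplingConfig, n_vars: int) -> TimeSeries:
    """K i.i.d. uniform states from the hypercube ``x0 ± box_side/2`` with
    derivatives evaluated exactly from the field."""
    if cfg.mode != "random_states":
        raise ValueError("cfg.mode must be 'random_states'")
    if cfg.derivative_mode != "exact":
        raise ValueError("random-state sampling requires exact derivatives")
    rng = np.random.default_rng(cfg.seed)
    x0 = np.broadcast_to(np.asarray(cfg.base_point, dtype=float), (n_vars,))
    X = _box_samples(rng, x0, cfg.box_side, (cfg.n_samples, n_vars))
    return TimeSeries(X=X, Xdot=np.asarray(field(X)), base_point=x0)


def _rk4(field, y: np.ndarray, dt: float) -> np.ndarray:
    k1 = field(y)
    k2 = field(y + 0.5 * dt * k1)
    k3 = field(y + 0.5 * dt * k2)
    k4 = field(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate_trajectories(field: Callable[[np.ndarray], np.ndarray],
                           cfg: SamplingConfig, n_vars: int,
                           method: str = "adaptive") -> TimeSeries:
    """Integrate ``n_series`` independent trajectories sampled at step ``dt``.

    All series share the base point ``x0``; each initial condition is drawn
    uniformly from the hypercube of side ``box_side`` around it.  The default
    integrator is adaptive RK45 evaluated on the fixed dt grid (cubic coupling
    terms make the benchmark systems too stiff for a fixed step at the stated
    dt once trajectories reach the attractor); ``method='rk4'`` selects a
    fixed-step 4th-order scheme instead.  With
    ``derivative_mode='finite_difference'`` the forward difference is taken
    within each series and the final state of each series is dropped.
    """
    if cfg.mode != "trajectories":
        raise ValueError("cfg.mode must be 'trajectories'")
    if method not in ("adaptive", "rk4"):
        raise ValueError(f"unknown integration method {method!r}")
    rng = np.random.default_rng(cfg.seed)
    x0 = np.broadcast_to(np.asarray(cfg.base_point, dtype=float), (n_vars,))
    y = _box_samples(rng, x0, cfg.box_side, (cfg.n_series, n_vars))
    states = np.empty((cfg.n_series, cfg.n_steps, n_vars))
    states[:, 0] = y
    if method == "rk4":
        for k in range(1, cfg.n_steps):
            y = _rk4(field, y, cfg.dt)
            if not np.all(np.isfinite(y)):
                bad = int(np.argwhere(~np.isfinite(y).all(axis=1))[0][0])
                raise IntegrationError(
                    f"non-finite state in series {bad} at step {k}")
            states[:, k] = y
    else:
        from scipy.integrate import solve_ivp

        t_eval = np.arange(cfg.n_steps) * cfg.dt
        for s in range(cfg.n_series):
            sol = solve_ivp(lambda t, v: np.asarray(field(v)),
                            (0.0, t_eval[-1]), states[s, 0], t_eval=t_eval,
                            rtol=1e-9, atol=1e-9)
            if sol.status != 0 or not np.all(np.isfinite(sol.y)):
                raise IntegrationError(
                    f"integration failed in series {s}: {sol.message}")
            states[s] = sol.y.T
    t_one = np.arange(cfg.n_steps) * cfg.dt

    if cfg.derivative_mode == "exact":
        X = states.reshape(-1, n_vars)
        Xdot = np.asarray(field(X))
        t = np.tile(t_one, cfg.n_series)
        lengths = [cfg.n_steps] * cfg.n_series
    else:
        Xdot_full = np.diff(states, axis=1) / cfg.dt
        X = states[:, :-1].reshape(-1, n_vars)
        Xdot = Xdot_full.reshape(-1, n_vars)
        t = np.tile(t_one[:-1], cfg.n_series)
        lengths = [cfg.n_steps - 1] * cfg.n_series
    return TimeSeries(X=X, t=t, Xdot=Xdot, base_point=x0, series_lengths=lengths)


def finite_difference(X: np.ndarray, dt: float,
                      series_lengths: Optional[List[int]] = None
                      ) -> Tuple[np.ndarray, np.ndarray, List[int]]:
    """Forward differences per series; returns (X_trimmed, Xdot, lengths)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if series_lengths is None:
        series_lengths = [X.shape[0]]
    xs, ds, lens = [], [], []
    start = 0
    for ln in series_lengths:
        if ln < 2:
            raise ValueError("each series needs at least 2 samples for differencing")
        block = X[start:start + ln]
        xs.append(block[:-1])
        ds.append(np.diff(block, axis=0) / dt)
        lens.append(ln - 1)
        start += ln
    return np.vstack(xs), np.vstack(ds), lens
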