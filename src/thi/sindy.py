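"""Monomial feature libraries and sequential thresholded least squares (STLSQ).

The regression solved here is, per target variable i,

    ẋ_i = D(X) v_i

where the columns of the design matrix D are monomials of the *deviations*
Δx = x − x0 from a Taylor base point, and v_i is made sparse by iterating
{least-squares fit on the current support; zero every coefficient whose
magnitude falls below λ; refit on the survivors} until the support stabilizes.

Column normalization (on by default) rescales every design column to unit ℓ2
norm before fitting, so λ acts on comparable magnitudes regardless of monomial
degree; returned ``coefficients`` are on the original column scale and
``scaled_coefficients`` on the unit-norm scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb
from typing import FrozenSet, List, Sequence

import numpy as np

__all__ = ["MonomialLibrary", "SparseFit", "build_library", "design_matrix", "stlsq"]


@dataclass
class MonomialLibrary:
    """Ordered list of monomials over ``n_vars`` variables.

    Each monomial is an exponent vector e ∈ ℕ^n with Σe ≤ max_degree; the
    first monomial is always the constant.  ``variables[m]`` is the set of
    distinct variables appearing in monomial m (empty for the constant) —
    hyperedge inference keys off this set, not the degree.
    """

    n_vars: int
    max_degree: int
    exponents: np.ndarray  # (N, n_vars) int array
    variables: List[FrozenSet[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=int)
        if self.exponents.ndim != 2 or self.exponents.shape[1] != self.n_vars:
            raise ValueError("exponents must be (N, n_vars)")
        if not self.variables:
            self.variables = [
                frozenset(np.nonzero(e)[0].tolist()) for e in self.exponents
            ]
        seen = {tuple(e) for e in self.exponents}
        if len(seen) != len(self.exponents):
            raise ValueError("duplicate exponent vectors in library")

    def __len__(self) -> int:
        return self.exponents.shape[0]

    def names(self, prefix: str = "x") -> List[str]:
        out = []
        for e in self.exponents:
            if not e.any():
                out.append("1")
                continue
            parts = []
            for v in np.nonzero(e)[0]:
                parts.append(f"{prefix}{v}" + (f"^{e[v]}" if e[v] > 1 else ""))
            out.append("*".join(parts))
        return out


def build_library(n_vars: int, max_degree: int) -> MonomialLibrary:
    """All monomials of total degree ≤ ``max_degree`` in graded
    lexicographic order; count = C(n_vars + max_degree, max_degree)."""
    if n_vars < 1 or max_degree < 1:
        raise ValueError("n_vars and max_degree must be positive")
    rows = [np.zeros(n_vars, dtype=int)]
    for deg in range(1, max_degree + 1):
        for combo in combinations_with_replacement(range(n_vars), deg):
            e = np.zeros(n_vars, dtype=int)
            for v in combo:
                e[v] += 1
            rows.append(e)
    lib = MonomialLibrary(n_vars, max_degree, np.array(rows))
    assert len(lib) == comb(n_vars + max_degree, max_degree)
    return lib


def library_from_exponents(n_vars: int, max_degree: int,
                           rows: Sequence[np.ndarray]) -> MonomialLibrary:
    """Library restricted to an explicit monomial list (used by filtering)."""
    return MonomialLibrary(n_vars, max_degree, np.array(list(rows), dtype=int))


def design_matrix(lib: MonomialLibrary, ts) -> np.ndarray:
    """K × N matrix with entry (k, m) = Π_i (X_{k,i} − x0_i)^{e_{m,i}}."""
    if ts.base_point is None:
        raise ValueError("TimeSeries must carry a base point for the design matrix")
    if lib.n_vars != ts.n_vars:
        raise ValueError(
            f"library over {lib.n_vars} variables, data has {ts.n_vars}"
        )
    dev = ts.deviations()
    K = dev.shape[0]
    D = np.ones((K, len(lib)))
    for m, e in enumerate(lib.exponents):
        for v in np.nonzero(e)[0]:
            D[:, m] *= dev[:, v] ** e[v]
    return D


@dataclass
class SparseFit:
    """Result of one STLSQ regression.

    ``coefficients`` are on the original column scale; entries outside
    ``support`` are exactly zero.  ``scaled_coefficients`` are the unit-norm
    column coefficients that thresholding (and default hyperedge scoring)
    operates on; they coincide with ``coefficients`` when normalization is off.
    """

    coefficients: np.ndarray
    support: np.ndarray
    residual: float
    n_iterations: int
    scaled_coefficients: np.ndarray

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "support": self.support.tolist(),
            "residual": self.residual,
            "n_iterations": self.n_iterations,
            "scaled_coefficients": self.scaled_coefficients.tolist(),
        }


def _rms(v: np.ndarray) -> float:
    return float(np.sqrt(np.mean(v**2))) if v.size else 0.0


def stlsq(D: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 20,
          normalize_columns: bool = True) -> SparseFit:
    """Sequential thresholded least squares.

    Iterates minimum-norm least squares on the active support, then zeroes
    coefficients with magnitude strictly below ``lam`` (ties at exactly
    ``lam`` are kept), until the support stabilizes or ``max_iter`` is hit.
    An empty final support is returned with residual RMS(y), not an error.
    """
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if D.ndim != 2 or D.shape[0] != y.shape[0]:
        raise ValueError("D must be (K, N) with K matching y")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    K, N = D.shape
    norms = np.linalg.norm(D, axis=0)
    unit_norms = np.where(norms > 0, norms, 1.0)
    Dw = D / unit_norms if normalize_columns else D

    active = np.ones(N, dtype=bool)
    active &= norms > 0  # all-zero columns can never contribute
    w_active = np.zeros(0)
    n_it = 0
    for n_it in range(1, max_iter + 1):
        if not active.any():
            break
        w_active, *_ = np.linalg.lstsq(Dw[:, active], y, rcond=None)
        keep = np.abs(w_active) >= lam
        if keep.all():
            break
        idx = np.nonzero(active)[0]
        active[idx[~keep]] = False
        w_active = w_active[keep]

    scaled = np.zeros(N)
    if active.any():
        scaled[active] = w_active
    coeffs = scaled / unit_norms if normalize_columns else scaled.copy()
    resid = _rms(y - D @ coeffs) if active.any() else _rms(y)
    return SparseFit(
        coefficients=coeffs,
        support=np.nonzero(active)[0],
        residual=resid,
        n_iterations=n_it,
        scaled_coefficients=scaled,
    )
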