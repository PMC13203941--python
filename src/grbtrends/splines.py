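"""Penalized B-spline building blocks for the trend model.

Cubic B-spline bases over calendar time with second-order difference
penalties (P-splines).  The penalty is reparametrized to identity form so
that every penalized coefficient block in the trend model carries a plain
ridge penalty, which keeps the restricted-marginal-likelihood determinants
cheap and separable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


def bspline_basis(x, n_basis: int, lo: float, hi: float, degree: int = 3) -> np.ndarray:
    """Evaluate a cubic B-spline basis with ``n_basis`` functions on [lo, hi].

    Knots are equally spaced with full multiplicity at the boundaries.
    """
    if n_basis < degree + 1:
        raise ValueError(f"n_basis must be >= {degree + 1}")
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    x = np.asarray(x, dtype=float)
    # clip guards floating-point spill just past the boundary knot
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, t, degree).toarray()
    return B


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """P-spline penalty matrix D'D for ``order``-th coefficient differences."""
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


@dataclass(frozen=True)
class SmoothReparam:
    """Natural parametrization of one penalized smooth.

    ``range_transform`` maps basis columns onto wiggly columns with identity
    penalty; ``null_transform`` spans the penalty null space (for a
    second-order difference penalty: constant and linear trend).
    """

    range_transform: np.ndarray  # (n_basis, n_basis - order)
    null_transform: np.ndarray  # (n_basis, order)

    @property
    def rank(self) -> int:
        return self.range_transform.shape[1]


def reparametrize_penalty(S: np.ndarray, order: int = 2) -> SmoothReparam:
    """Eigen-reparametrize penalty S so the wiggly part has identity penalty."""
    vals, vecs = np.linalg.eigh(S)
    # eigh returns ascending order: first `order` eigenvalues are ~0
    null = vecs[:, :order]
    pos_vals = vals[order:]
    pos_vecs = vecs[:, order:]
    if np.any(pos_vals <= 0):
        raise ValueError("penalty rank deficiency beyond the expected null space")
    rng = pos_vecs / np.sqrt(pos_vals)
    return SmoothReparam(range_transform=rng, null_transform=null)


def sum_to_zero_contrasts(n_levels: int) -> np.ndarray:
    """Orthonormal (n_levels, n_levels-1) basis of the sum-to-zero subspace.

    Effects reconstructed as ``Q @ beta`` sum to zero exactly for any beta.
    """
    from scipy.linalg import null_space

    Q = null_space(np.ones((1, n_levels)))
    if Q.shape != (n_levels, n_levels - 1):
        raise RuntimeError("contrast construction failed")
    return Q
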