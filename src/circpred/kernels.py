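"""The seven kernel functions and their Gram matrices.

All kernels operate on (standardized) 62-dimensional feature rows:

=============  ==========================================================
name           K(x, y)
=============  ==========================================================
linear         <x, y>
polynomial     (gamma * <x, y> + r)^d
rbf            exp(-gamma * ||x - y||^2)
hyperbolic     tanh(gamma * <x, y> + r)
laplace        exp(-gamma * ||x - y||)
sigmoid        (<x, y> + r)^d
bessel         J_order(gamma*||x-y||) / (gamma*||x-y||)^order, normalized
               to K(x, x) = 1 and raised to the power d
=============  ==========================================================

The "sigmoid" and "hyperbolic" names follow the nomenclature of the source
method: "hyperbolic" is the conventional sigmoid/tanh kernel, while
"sigmoid" here is an inhomogeneous polynomial form.  The Bessel kernel is
the kernlab-style construction (the first-kind Bessel function of the given
order applied to the scaled distance, normalized by its value at zero
distance).  Only the Laplace, linear and rbf kernels are positive
semi-definite and used for final models; the others are comparison
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn
from scipy.special import jv

KERNEL_NAMES = (
    "linear",
    "polynomial",
    "rbf",
    "sigmoid",
    "hyperbolic",
    "laplace",
    "bessel",
)

_NEEDS_GAMMA = {"polynomial", "rbf", "hyperbolic", "laplace", "bessel"}


@dataclass(frozen=True)
class KernelSpec:
    """A kernel name plus its parameters.

    ``gamma=None`` means "1 / n_features", resolved when a Gram matrix is
    computed (the usual scale-free default for distance kernels).
    """

    name: str
    gamma: float | None = None
    degree: int = 3
    offset: float = 0.0  # the "r" parameter
    order: int = 1  # Bessel-function order

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}")
        if self.gamma is not None and self.gamma <= 0 and self.name in _NEEDS_GAMMA:
            raise ValueError("gamma must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def resolve_gamma(self, n_features: int) -> float:
        if self.gamma is not None:
            return self.gamma
        return 1.0 / n_features


@dataclass(frozen=True)
class GramMatrix:
    """Pairwise kernel values with optional row/column identities."""

    values: np.ndarray
    row_ids: tuple[str, ...] | None = None
    col_ids: tuple[str, ...] | None = None


def gram(X: np.ndarray, Y: np.ndarray | None = None, spec: KernelSpec | None = None) -> np.ndarray:
    """Kernel matrix K[i, j] = K(X[i], Y[j]); Y defaults to X.

    Raises on dimensionality mismatch or non-finite output.
    """
    if spec is None:
        raise ValueError("a KernelSpec is required")
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D arrays")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    g = spec.resolve_gamma(X.shape[1])
    r, d = spec.offset, spec.degree

    if spec.name == "linear":
        K = X @ Y.T
    elif spec.name == "polynomial":
        K = (g * (X @ Y.T) + r) ** d
    elif spec.name == "sigmoid":
        K = ((X @ Y.T) + r) ** d
    elif spec.name == "hyperbolic":
        K = np.tanh(g * (X @ Y.T) + r)
    elif spec.name == "rbf":
        K = np.exp(-g * cdist(X, Y, metric="sqeuclidean"))
    elif spec.name == "laplace":
        K = np.exp(-g * cdist(X, Y, metric="euclidean"))
    elif spec.name == "bessel":
        nu = spec.order
        t = g * cdist(X, Y, metric="euclidean")
        # J_nu(t)/t^nu -> 1/(2^nu * Gamma(nu+1)) as t -> 0; normalize so K(x,x)=1
        lim = 1.0 / (2.0**nu * gamma_fn(nu + 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            base = jv(nu, t) / np.power(t, nu)
        base = np.where(t < 1e-8, lim, base)
        K = (base / lim) ** d
    else:  # pragma: no cover - guarded by KernelSpec
        raise ValueError(spec.name)

    if not np.all(np.isfinite(K)):
        raise FloatingPointError(f"non-finite entries in {spec.name} Gram matrix")
    return K


def gram_matrix(
    X: np.ndarray,
    Y: np.ndarray | None = None,
    spec: KernelSpec | None = None,
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
) -> GramMatrix:
    """Like :func:`gram` but wrapped with row/column identities."""
    values = gram(X, Y, spec)
    return GramMatrix(
        values=values,
        row_ids=tuple(row_ids) if row_ids is not None else None,
        col_ids=tuple(col_ids) if col_ids is not None else None,
    )


def default_spec(name: str, n_features: int = 62) -> KernelSpec:
    """Default parameterization for a kernel by name (gamma = 1/n_features)."""
    return KernelSpec(name=name, gamma=1.0 / n_features)
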