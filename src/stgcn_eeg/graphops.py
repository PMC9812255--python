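"""Spectral graph-convolution machinery.

For a nonnegative symmetric adjacency W with degree matrix D, the
normalised Laplacian ``L = I - D^{-1/2} W D^{-1/2}`` has spectrum in
[0, 2].  Chebyshev polynomials of the rescaled Laplacian
``L~ = 2 L / lambda_max - I`` give K-hop-localised filters without an
eigendecomposition, and the first-order renormalised form
``S = D~^{-1/2} (W + I) D~^{-1/2}`` (with ``D~`` the degree of ``W + I``)
is the single-parameter propagation operator used by the network layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ChebCoeffs:
    """Chebyshev polynomial coefficients theta_0 .. theta_{K-1}."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.theta.size < 1:
            raise ValueError("need at least one coefficient (K >= 1)")

    @property
    def K(self) -> int:
        return self.theta.size


def _check_adjacency(W: np.ndarray, *, nonnegative: bool = True) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if nonnegative and np.any(W < 0):
        raise ValueError("adjacency must be nonnegative (rectify upstream)")
    return W


@dataclass
class GraphOperator:
    """Derived Laplacian / propagation matrices of one adjacency."""

    W: np.ndarray
    L: np.ndarray
    lambda_max: float
    L_scaled: np.ndarray
    S: np.ndarray
    U: np.ndarray | None = None
    Lambda: np.ndarray | None = None

    @classmethod
    def from_adjacency(cls, W: np.ndarray, *, exact_lambda_max: bool = False,
                       eig: bool = False) -> "GraphOperator":
        """Build all derived operators.

        ``exact_lambda_max=False`` uses the customary assumption
        lambda_max ~ 2 for the rescaled Laplacian; the exact largest
        eigenvalue is available for oracle comparisons.
        """
        W = _check_adjacency(W)
        n = W.shape[0]
        L = normalized_laplacian(W)
        U = Lam = None
        if exact_lambda_max or eig:
            Lam, U = np.linalg.eigh(L)
            lmax = float(Lam[-1])
        else:
            lmax = 2.0
        if lmax <= 0:  # edgeless graph: L = I, spectrum {1}
            lmax = 2.0
        L_scaled = 2.0 * L / lmax - np.eye(n)
        S = renormalized_propagation(W)
        return cls(W=W, L=L, lambda_max=lmax, L_scaled=L_scaled, S=S,
                   U=U, Lambda=Lam)


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """``I - D^{-1/2} W D^{-1/2}``; isolated nodes use the zero convention."""
    W = _check_adjacency(W)
    deg = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, deg ** -0.5, 0.0)
    L = np.eye(W.shape[0]) - d_inv_sqrt[:, None] * W * d_inv_sqrt[None, :]
    return 0.5 * (L + L.T)


def renormalized_propagation(W: np.ndarray) -> np.ndarray:
    """``S = D~^{-1/2} (W + I) D~^{-1/2}`` with ``D~`` the degree of W + I.

    Self-loops guarantee positive degrees, so S is well defined for any
    nonnegative symmetric W and has spectral radius <= 1.
    """
    W = _check_adjacency(W)
    n = W.shape[0]
    W_tilde = W + np.eye(n)
    d = W_tilde.sum(axis=1) ** -0.5
    S = d[:, None] * W_tilde * d[None, :]
    return 0.5 * (S + S.T)


def chebyshev_filter(x: np.ndarray, gop: GraphOperator,
                     coeffs: ChebCoeffs | np.ndarray) -> np.ndarray:
    """Filter a graph signal with a Chebyshev polynomial of the scaled
    Laplacian, via the recurrence T0 = I, T1 = L~, Tk = 2 L~ T_{k-1} - T_{k-2}.
    """
    if not isinstance(coeffs, ChebCoeffs):
        coeffs = ChebCoeffs(coeffs)
    x = np.asarray(x, dtype=float)
    Lt = gop.L_scaled
    Tk_prev = x
    out = coeffs.theta[0] * x
    if coeffs.K == 1:
        return out
    Tk = Lt @ x
    out = out + coeffs.theta[1] * Tk
    for k in range(2, coeffs.K):
        Tk, Tk_prev = 2 * Lt @ Tk - Tk_prev, Tk
        out = out + coeffs.theta[k] * Tk
    return out


def spectral_filter(x: np.ndarray, gop: GraphOperator,
                    coeffs: ChebCoeffs | np.ndarray) -> np.ndarray:
    """Same filter evaluated explicitly in the spectral domain,
    ``U (sum_k theta_k T_k(Lambda~)) U^T x`` — the eigendecomposition route
    the Chebyshev recurrence approximates (here: matches exactly)."""
    if not isinstance(coeffs, ChebCoeffs):
        coeffs = ChebCoeffs(coeffs)
    if gop.U is None or gop.Lambda is None:
        Lam, U = np.linalg.eigh(gop.L)
    else:
        Lam, U = gop.Lambda, gop.U
    lam_scaled = 2.0 * Lam / gop.lambda_max - 1.0
    tk_prev = np.ones_like(lam_scaled)
    g = coeffs.theta[0] * tk_prev
    if coeffs.K > 1:
        tk = lam_scaled.copy()
        g = g + coeffs.theta[1] * tk
        for k in range(2, coeffs.K):
            tk, tk_prev = 2 * lam_scaled * tk - tk_prev, tk
            g = g + coeffs.theta[k] * tk
    xh = U.T @ np.asarray(x, dtype=float)
    gx = g * xh if xh.ndim == 1 else g[:, None] * xh
    return U @ gx


def graph_conv(X: np.ndarray, S: np.ndarray, Theta: np.ndarray) -> np.ndarray:
    """First-order graph convolution of a frame stack.

    ``X`` has shape [M, n, Ci]; the identical kernel ``Theta`` [Ci, Co] is
    applied to every frame: ``Y[t] = S @ X[t] @ Theta``.
    """
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    Theta = np.atleast_2d(np.asarray(Theta, dtype=float))
    if X.ndim != 3:
        raise ValueError("X must be [M, n, Ci]")
    if S.shape != (X.shape[1], X.shape[1]):
        raise ValueError("S must be [n, n] matching X's node axis")
    if Theta.shape[0] != X.shape[2]:
        raise ValueError("Theta rows must match X's channel axis")
    return np.einsum("uv,tvi,io->tuo", S, X, Theta)
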