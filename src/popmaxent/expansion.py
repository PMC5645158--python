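"""The inhibition term G and its exact higher-order expansion.

The reference-measure exponent ``N G(s̄ − θ)`` with ``G(x) = x H(x)``,
``H(0) = 1``, can be rewritten on the activity grid as a linear combination
of sums of K-tuple products of activities,

    N G(s̄ − θ) = Σ_{K=Θ+1}^{N} f_K(Θ) Σ_{i1<...<iK} s_{i1}...s_{iK},

with Θ = Nθ.  Because Σ_{i1<...<iK} s_{i1}...s_{iK} = C(S, K) when the total
activity is S, the coefficient vector solves v = f P with the
(N+1)-dimensional Pascal matrix P[K,S] = C(S,K), and equals the generalized
binomial coefficients f_K = C(−Θ, K−Θ−1) for K > Θ, 0 otherwise.

Everything here is exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

__all__ = [
    "ExpansionTable",
    "g_term",
    "pascal_matrices",
    "expansion_coefficients",
    "grid_identity_holds",
]


def g_term(sbar: float, theta: float, N: int) -> int:
    """N·G(s̄ − θ) on the activity grid, with the convention H(0) = 1.

    ``sbar`` must be a grid value S/N and ``N*theta`` an integer; the result
    is the integer max(S − Θ, 0).  The discrete difference identity
    N G(x + 1/N) − N G(x) = H(x) holds on this grid.
    """
    S = sbar * N
    if abs(S - round(S)) > 1e-9:
        raise ValueError("sbar must be a multiple of 1/N")
    Th = theta * N
    if abs(Th - round(Th)) > 1e-9:
        raise ValueError("N*theta must be an integer")
    S, Th = int(round(S)), int(round(Th))
    if not 0 <= S <= N:
        raise ValueError("sbar must lie in [0, 1]")
    return max(S - Th, 0)


def pascal_matrices(N: int) -> tuple[np.ndarray, np.ndarray]:
    """The (N+1)-dimensional Pascal matrix and its exact inverse.

    P[K, S] = C(S, K);  P⁻¹[S, K] = (−1)^{K−S} C(K, S).  Object arrays of
    Python integers so that P·P⁻¹ = I holds exactly at any size.
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    size = N + 1
    P = np.empty((size, size), dtype=object)
    Pinv = np.empty((size, size), dtype=object)
    for a in range(size):
        for b in range(size):
            P[a, b] = comb(b, a)
            Pinv[a, b] = (-1) ** (b - a) * comb(b, a) if b >= a else 0
    return P, Pinv


def _gen_binom_neg(Theta: int, j: int) -> int:
    """Generalised binomial coefficient C(−Θ, j) as an exact integer."""
    if j < 0:
        return 0
    if j == 0:
        return 1
    return (-1) ** j * comb(Theta + j - 1, j)


@dataclass
class ExpansionTable:
    """Coefficients f_K(Θ) with the target vector v_S = G(S − Θ)."""

    N: int
    Theta: int
    f: np.ndarray  # length N+1, object (exact ints)
    v: np.ndarray  # length N+1, object (exact ints)


def expansion_coefficients(N: int, Theta: int) -> ExpansionTable:
    """Exact expansion coefficients computed two ways and cross-checked.

    The matrix route f = v·P⁻¹ and the closed form
    f_K = C(−Θ, K−Θ−1) (K > Θ) must agree entry by entry; the
    reconstruction Σ_K f_K C(S,K) = max(0, S−Θ) is verified for every S.
    """
    if not 0 <= Theta <= N:
        raise ValueError("Theta must be in {0,...,N}")
    v = np.array([max(S - Theta, 0) for S in range(N + 1)], dtype=object)
    _, Pinv = pascal_matrices(N)
    f_matrix = v @ Pinv
    f_closed = np.array(
        [_gen_binom_neg(Theta, K - Theta - 1) if K > Theta else 0
         for K in range(N + 1)],
        dtype=object,
    )
    if not all(int(a) == int(b) for a, b in zip(f_matrix, f_closed)):
        raise AssertionError("matrix and closed-form coefficient routes disagree")
    P, _ = pascal_matrices(N)
    recon = f_closed @ P
    if not all(int(r) == int(t) for r, t in zip(recon, v)):
        raise AssertionError("reconstruction invariant violated")
    return ExpansionTable(N=N, Theta=Theta, f=f_closed, v=v)


def grid_identity_holds(N: int, Theta: int) -> bool:
    """Check N G(x + 1/N) − N G(x) = H(x) at every grid point x = S/N − θ."""
    theta = Theta / N
    for S in range(N):
        x = S / N - theta
        lhs = g_term((S + 1) / N, theta, N) - g_term(S / N, theta, N)
        rhs = 1 if x >= -1e-12 else 0  # H with H(0)=1; grid x is (S-Θ)/N
        if lhs != rhs:
            return False
    return True
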