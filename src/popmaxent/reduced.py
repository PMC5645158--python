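"""Fitting the reduced model and characterising uni/bimodality.

The reduced (homogeneous) pairwise maximum-entropy model constrains only the
population-level first and second factorial moments,

    E[S] = N m̄,      E[S(S−1)] = N(N−1) ḡ,      S = N s̄,

and its two multipliers (h_r, J_r) are found by minimising the convex dual

    f(h_r, J_r) = ln Z_r − h_r N m̄ − ½ J_r N(N−1) ḡ

with damped Newton iteration: the gradient is the moment mismatch and the
Hessian the covariance of the sufficient statistics (S, S(S−1)/2).

Bimodality is analysed on the continuous extension of ln P_r(s̄) obtained by
replacing the binomial coefficient with its log-gamma form; its stationary
points satisfy

    h_r + J_r (N s̄ − ½) − Ψ(N s̄ + 1) + Ψ(N(1−s̄) + 1) = 0,

with Ψ the digamma function, and a stationary point is a minimum iff
J_r > Ψ′(N s̄ + 1) + Ψ′(N(1−s̄) + 1) (trigamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp, polygamma, psi

from .models import ReducedModel, reduced_distribution

__all__ = [
    "ReducedConstraints",
    "ModeAnalysis",
    "BimodalityBoundary",
    "FitDivergedError",
    "fit_reduced",
    "stationary_points",
    "find_modes",
    "bimodality_region",
    "bimodality_threshold_N",
    "gbar_from_rhobar",
]

_MULTIPLIER_LIMIT = 1e3  # |h_r| or |J_r| beyond this signals boundary constraints


class FitDivergedError(RuntimeError):
    """Raised when constraints sit on (or beyond) the attainable boundary."""


def gbar_from_rhobar(mbar: float, rhobar: float) -> float:
    """Convert (m̄, ρ̄) to ḡ under homogeneity: ḡ = m̄² + ρ̄ m̄(1−m̄)."""
    return mbar * mbar + rhobar * (mbar - mbar * mbar)


@dataclass
class ReducedConstraints:
    """Population-level constraints (m̄, ḡ) for ``N`` units.

    Alternatively construct from (m̄, ρ̄) with :func:`gbar_from_rhobar`.
    """

    N: int
    mbar: float
    gbar: float

    def __post_init__(self) -> None:
        if not 0 < self.mbar < 1:
            raise ValueError("mbar must be in (0, 1)")
        lo = max(0.0, 2 * self.mbar - 1)
        if not lo < self.gbar < self.mbar:
            raise ValueError(
                f"gbar={self.gbar} outside the strictly attainable pair "
                f"bounds ({lo}, {self.mbar}); boundary values need "
                "diverging multipliers"
            )
        if self.N < 2:
            raise ValueError("N must be >= 2")

    @classmethod
    def from_rho(cls, N: int, mbar: float, rhobar: float) -> "ReducedConstraints":
        return cls(N=N, mbar=mbar, gbar=gbar_from_rhobar(mbar, rhobar))


@dataclass
class ModeAnalysis:
    """Stationary-point structure of the continuous extension plus discrete modes."""

    N: int
    stationary: list[tuple[float, str]]  # (s̄ location, 'max' | 'min')
    discrete_modes: list[int]  # indices S of strict local maxima of the pmf
    peak_ratio: float | None  # pmf(low mode)/pmf(high mode); None if unimodal
    peak_ratio_continuous: float | None
    bimodal: bool

    @property
    def maxima(self) -> list[float]:
        return [x for x, kind in self.stationary if kind == "max"]

    @property
    def minima(self) -> list[float]:
        return [x for x, kind in self.stationary if kind == "min"]


def _moments_and_cov(N: int, h: float, J: float):
    S = np.arange(N + 1, dtype=np.float64)
    base = gammaln(N + 1) - gammaln(S + 1) - gammaln(N - S + 1)
    t1 = S
    t2 = S * (S - 1) / 2.0
    logw = base + h * t1 + J * t2
    lz = logsumexp(logw)
    p = np.exp(logw - lz)
    E1 = float(p @ t1)
    E2 = float(p @ t2)
    cov = np.array(
        [
            [p @ (t1 * t1) - E1 * E1, p @ (t1 * t2) - E1 * E2],
            [p @ (t1 * t2) - E1 * E2, p @ (t2 * t2) - E2 * E2],
        ]
    )
    return E1, E2, cov, float(lz)


def fit_reduced(constraints: ReducedConstraints,
                tol: float = 1e-10, max_iter: int = 200) -> tuple[float, float]:
    """Newton solve of the two-parameter convex dual; returns (h_r, J_r).

    Converged when both relative moment mismatches drop below ``tol``.
    Divergence (multiplier magnitude above 1e3) raises
    :class:`FitDivergedError`, signalling boundary constraints.
    """
    N = constraints.N
    a = N * constraints.mbar  # target E[S]
    b = N * (N - 1) * constraints.gbar / 2.0  # target E[S(S-1)/2]
    h = float(np.log(constraints.mbar / (1 - constraints.mbar)))
    J = 0.0

    def dual(hh, JJ):
        return _moments_and_cov(N, hh, JJ)[3] - hh * a - JJ * b

    f = dual(h, J)
    for _ in range(max_iter):
        E1, E2, cov, lz = _moments_and_cov(N, h, J)
        grad = np.array([E1 - a, E2 - b])
        rel = max(abs(grad[0]) / a, abs(grad[1]) / max(abs(b), 1e-300))
        if rel < tol:
            return h, J
        try:
            step = np.linalg.solve(cov, grad)
        except np.linalg.LinAlgError as exc:
            raise FitDivergedError("singular Hessian; boundary constraints") from exc
        t = 1.0
        while t > 1e-14:
            f_new = dual(h - t * step[0], J - t * step[1])
            if f_new < f - 1e-4 * t * float(grad @ step):
                break
            t *= 0.5
        else:
            # decrease below float resolution of the dual: in the Newton
            # basin, take the full step (quadratic convergence regime)
            t = 1.0
        h -= t * step[0]
        J -= t * step[1]
        f = dual(h, J)
        if abs(h) > _MULTIPLIER_LIMIT or abs(J) > _MULTIPLIER_LIMIT:
            raise FitDivergedError(
                f"multipliers diverged (h_r={h:.3g}, J_r={J:.3g}); "
                "constraints at or beyond the attainable boundary"
            )
    raise FitDivergedError("Newton iteration did not converge")


def _dlog(N: int, h: float, J: float):
    """Derivative in s̄ of the continuous extension of ln P_r, divided by N."""

    def d1(x: float) -> float:
        return h + J * (N * x - 0.5) - psi(N * x + 1) + psi(N * (1 - x) + 1)

    return d1


def stationary_points(N: int, h_r: float, J_r: float,
                      grid_points: int | None = None) -> ModeAnalysis:
    """All interior stationary points of the continuous extension of ln P_r.

    Roots are bracketed by sign changes on a grid of ``10 N`` points (default)
    and refined by bisection to 1e−12; classification is by the sign of the
    second derivative (trigamma terms).  Discrete modes and peak ratios are
    computed from the exact pmf alongside.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    d1 = _dlog(N, h_r, J_r)
    npts = grid_points or 10 * N
    xs = np.linspace(1e-9, 1 - 1e-9, npts)
    vals = np.array([d1(x) for x in xs])
    stationary: list[tuple[float, str]] = []
    for i in range(npts - 1):
        if vals[i] == 0.0 or (vals[i] > 0) != (vals[i + 1] > 0):
            root = brentq(d1, xs[i], xs[i + 1], xtol=1e-12)
            curv = J_r - polygamma(1, N * root + 1) - polygamma(1, N * (1 - root) + 1)
            stationary.append((float(root), "max" if curv < 0 else "min"))
    model = reduced_distribution(N, h_r, J_r)
    discrete, ratio = _discrete_modes(model.log_pmf)
    maxima = [x for x, k in stationary if k == "max"]
    ratio_cont = None
    if len(maxima) >= 2:
        ratio_cont = float(
            np.exp(_log_cont(N, h_r, J_r, maxima[0]) - _log_cont(N, h_r, J_r, maxima[-1]))
        )
    return ModeAnalysis(
        N=N,
        stationary=stationary,
        discrete_modes=discrete,
        peak_ratio=ratio,
        peak_ratio_continuous=ratio_cont,
        bimodal=len(maxima) >= 2,
    )


def _log_cont(N: int, h: float, J: float, x: float) -> float:
    return (
        gammaln(N + 1) - gammaln(N * x + 1) - gammaln(N * (1 - x) + 1)
        + h * N * x + 0.5 * J * N * x * (N * x - 1)
    )


def _discrete_modes(log_pmf: np.ndarray) -> tuple[list[int], float | None]:
    """Strict local maxima of a pmf; plateaus collapse to their leftmost index."""
    n = log_pmf.shape[0]
    modes: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and log_pmf[j + 1] == log_pmf[i]:
            j += 1
        left_ok = i == 0 or log_pmf[i - 1] < log_pmf[i]
        right_ok = j == n - 1 or log_pmf[j + 1] < log_pmf[i]
        if left_ok and right_ok:
            modes.append(i)
        i = j + 1
    ratio = None
    if len(modes) >= 2:
        ratio = float(np.exp(log_pmf[modes[0]] - log_pmf[modes[-1]]))
    return modes, ratio


def find_modes(model: ReducedModel) -> tuple[list[int], float | None]:
    """Discrete modes of the reduced pmf and the low/high peak-probability ratio.

    The ratio pmf(lowest-S mode)/pmf(highest-S mode) is ``None`` when the pmf
    is unimodal.
    """
    return _discrete_modes(model.log_pmf)


@dataclass
class BimodalityBoundary:
    """Critical curve in the (E_r(s̄), ρ̄) plane separating uni- from bimodal.

    Points with ρ̄ above the curve (at the same activity) yield a bimodal
    reduced model for this N.
    """

    N: int
    E: np.ndarray
    rho: np.ndarray
    h_r: np.ndarray = field(repr=False, default=None)
    J_r: np.ndarray = field(repr=False, default=None)

    def rho_critical(self, E: float) -> float:
        order = np.argsort(self.E)
        return float(np.interp(E, self.E[order], self.rho[order]))

    def classify(self, E: float, rho: float) -> str:
        return "bimodal" if rho > self.rho_critical(E) else "unimodal"


def bimodality_region(N: int, n_points: int = 2000) -> BimodalityBoundary:
    """Sweep the analytic bimodality boundary and map it to moment space.

    On the boundary a stationary point at s̄_m is degenerate:
    J_r = Ψ′(1 + (1−s̄_m)N) + Ψ′(1 + s̄_m N), with
    h_r = J_r/2 − s̄_m N J_r − Ψ(1 + (1−s̄_m)N) + Ψ(1 + s̄_m N).
    Each boundary (h_r, J_r) is mapped to (E_r(s̄), ρ̄) through the exact
    reduced pmf.  The sweep is geometrically refined near s̄_m = 0 and 1.
    """
    half = n_points // 2
    lo = np.geomspace(1.0 / (4 * N), 0.5, half)
    xs = np.unique(np.concatenate([lo, 1 - lo]))
    E = np.empty(xs.size)
    rho = np.empty(xs.size)
    hs = np.empty(xs.size)
    Js = np.empty(xs.size)
    for k, x in enumerate(xs):
        J = float(polygamma(1, 1 + (1 - x) * N) + polygamma(1, 1 + x * N))
        h = float(J / 2 - x * N * J - psi(1 + (1 - x) * N) + psi(1 + x * N))
        model = reduced_distribution(N, h, J)
        E[k] = model.E_sbar
        rho[k] = model.rhobar
        hs[k] = h
        Js[k] = J
    ok = np.isfinite(E) & np.isfinite(rho)  # extreme sweep points degenerate
    return BimodalityBoundary(N=N, E=E[ok], rho=rho[ok], h_r=hs[ok], J_r=Js[ok])


def bimodality_threshold_N(mbar: float, gbar: float,
                           N_range: range | list[int]
                           ) -> tuple[int | None, ModeAnalysis | None]:
    """Smallest N in ``N_range`` whose fitted reduced model is bimodal.

    Returns ``(None, None)`` when no N in the range yields two continuous
    maxima (e.g. ḡ = m̄², independent units).
    """
    for N in N_range:
        h, J = fit_reduced(ReducedConstraints(N=N, mbar=mbar, gbar=gbar))
        analysis = stationary_points(N, h, J)
        if analysis.bimodal:
            return N, analysis
    return None, None
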