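"""Fitting inhomogeneous pairwise and inhibited models.

Small populations (N ≤ 15) are fitted exactly by Newton iteration on the
convex dual with full state enumeration.  Larger populations use Boltzmann
learning: sample the current model with (inhibited) Glauber dynamics,
measure the empirical moments, and nudge the multipliers along the moment
mismatch,

    h_i ← h_i + η_h (m_i − m̂_i),     J_ij ← J_ij + η_J (g_ij − ĝ_ij).

The weak-correlation linear inversion J_ij ≈ c_ij/[m_i(1−m_i) m_j(1−m_j)]
provides the starting point.  Inhibition parameters (J_I, θ) are fixed a
priori, never learned; a very negative multiplier is a symptom that a
constraint sits at its attainable boundary, where the maximum-entropy method
itself breaks down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .glauber import SamplerConfig, Variant, _run
from .models import PairwiseModel, exact_distribution
from .raster import EmpiricalStats

__all__ = [
    "LearningConfig",
    "LearningReport",
    "FixedPointSet",
    "exact_fit_pairwise",
    "boltzmann_learning",
    "naive_inversion",
    "mean_field_fixed_points",
    "mean_field_fixed_points_homogeneous",
]

logger = logging.getLogger(__name__)


def _check_targets(m: np.ndarray, g: np.ndarray) -> None:
    n = m.shape[0]
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("all target means must lie strictly in (0, 1)")
    iu = np.triu_indices(n, k=1)
    lo = np.maximum(0.0, m[iu[0]] + m[iu[1]] - 1)
    hi = np.minimum(m[iu[0]], m[iu[1]])
    if np.any(g[iu] <= lo) or np.any(g[iu] >= hi):
        raise ValueError(
            "boundary targets: each g_ij must lie strictly inside "
            "(max(0, m_i+m_j-1), min(m_i, m_j)); multipliers would diverge"
        )


def _pack(h: np.ndarray, J: np.ndarray, iu) -> np.ndarray:
    return np.concatenate([h, J[iu]])


def exact_fit_pairwise(m: np.ndarray, g: np.ndarray,
                       tol: float = 1e-10, max_iter: int = 200,
                       cap: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """Exact moment matching by Newton iteration with full enumeration.

    Targets: E(s_i) = m_i and E(s_i s_j) = g_ij.  Returns (h, J) such that
    the refitted moments match the targets to ``tol`` (max absolute
    mismatch).  Strictly interior targets required.
    """
    m = np.asarray(m, dtype=float)
    g = np.asarray(g, dtype=float)
    n = m.shape[0]
    if n > cap:
        raise ValueError(f"N={n} exceeds the exact-fit cap {cap}")
    _check_targets(m, g)
    iu = np.triu_indices(n, k=1)
    target = _pack(m, g, iu)
    from .models import state_table

    states = state_table(n).astype(np.float64)
    # feature matrix: [s_i ... , s_i s_j ...]
    pair_feats = states[:, iu[0]] * states[:, iu[1]]
    phi = np.hstack([states, pair_feats])
    theta = np.concatenate([np.log(m / (1 - m)), np.zeros(iu[0].size)])

    def moments_cov(th):
        logw = phi @ th
        logw -= logw.max()
        p = np.exp(logw)
        p /= p.sum()
        mu = p @ phi
        cov = (phi * p[:, None]).T @ phi - np.outer(mu, mu)
        return p, mu, cov

    def dual(th):
        logw = phi @ th
        c = logw.max()
        return c + np.log(np.exp(logw - c).sum()) - th @ target

    f = dual(theta)
    for _ in range(max_iter):
        _, mu, cov = moments_cov(theta)
        grad = mu - target
        if np.abs(grad).max() < tol:
            break
        step = np.linalg.solve(cov + 1e-12 * np.eye(cov.shape[0]), grad)
        t = 1.0
        while t > 1e-14:
            if dual(theta - t * step) < f - 1e-4 * t * float(grad @ step):
                break
            t *= 0.5
        theta = theta - t * step
        f = dual(theta)
    else:
        raise RuntimeError("exact fit did not converge")
    h = theta[:n]
    J = np.zeros((n, n))
    J[iu] = theta[n:]
    J = J + J.T
    return h, J


@dataclass
class LearningConfig:
    sampling_steps: int = 1_000_000
    eta_h: float = 0.1
    eta_J: float = 0.1
    decay: float = 0.99  # geometric per-iteration decay of both rates
    max_iter: int = 200
    tol: float = 1e-3  # on max |m̂−m|, |ĝ−g|
    variant: Variant = "standard"
    seed: int = 0
    record_every: int = 1
    burn_in: int | None = None
    exact: bool = False  # replace sampling by enumeration-exact moments
    verification_steps: int = 0  # e.g. 5e7 to probe ergodicity after learning

    def __post_init__(self) -> None:
        if self.eta_h <= 0 or self.eta_J <= 0:
            raise ValueError("learning rates must be positive")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class LearningReport:
    converged: bool
    n_iter: int
    mismatch_history: list[float]
    final_mismatch: float
    ergodicity_flag: bool
    ergodicity_detail: str = ""


def _model_with(template: PairwiseModel, h, J) -> PairwiseModel:
    if template is not None and template.has_inhibition:
        return PairwiseModel(h=h, J=J, J_I=template.J_I, Theta=template.Theta)
    return PairwiseModel(h=h, J=J)


def _sampled_moments(model: PairwiseModel, steps: int, seed: int,
                     variant: Variant, record_every: int,
                     burn_in: int | None):
    config = SamplerConfig(
        steps=steps, seed=seed, variant=variant,
        record_every=record_every, burn_in=burn_in,
    )
    trace = _run(model, config)
    return trace.m_hat, trace.g_hat, trace


def _exact_moments(model: PairwiseModel):
    dist = exact_distribution(model)
    return dist.E_s, dist.E_ss


def boltzmann_learning(m: np.ndarray, g: np.ndarray,
                       template: PairwiseModel | None = None,
                       config: LearningConfig | None = None,
                       h0: np.ndarray | None = None,
                       J0: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray, LearningReport]:
    """Iterative moment matching with sampled (or enumeration-exact) gradients.

    ``template`` carries optional inhibition parameters (kept fixed).  When
    no starting point is given the weak-correlation inversion is used.
    Non-convergence returns the last parameters with ``converged=False``.
    """
    m = np.asarray(m, dtype=float)
    g = np.asarray(g, dtype=float)
    n = m.shape[0]
    config = config or LearningConfig()
    _check_targets(m, g)
    iu = np.triu_indices(n, k=1)
    if h0 is None or J0 is None:
        c = g - np.outer(m, m)
        h, J = _naive_from_mc(m, c)
    else:
        h, J = np.array(h0, dtype=float), np.array(J0, dtype=float)
    eta_h, eta_J = config.eta_h, config.eta_J
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        model = _model_with(template, h, J)
        if config.exact:
            m_hat, g_hat = _exact_moments(model)
        else:
            m_hat, g_hat, _ = _sampled_moments(
                model, config.sampling_steps, config.seed + it,
                config.variant, config.record_every, config.burn_in,
            )
        mismatch = max(
            float(np.abs(m_hat - m).max()),
            float(np.abs(g_hat[iu] - g[iu]).max()),
        )
        history.append(mismatch)
        if mismatch < config.tol:
            converged = True
            break
        h = h + eta_h * (m - m_hat)
        dJ = np.zeros_like(J)
        dJ[iu] = eta_J * (g[iu] - g_hat[iu])
        J = J + dJ + dJ.T
        eta_h *= config.decay
        eta_J *= config.decay
    flag, detail = False, ""
    if config.verification_steps > 0:
        model = _model_with(template, h, J)
        flag, detail = _ergodicity_probe(model, config)
    if not converged:
        logger.warning("Boltzmann learning unconverged after %d iterations", it)
    report = LearningReport(
        converged=converged, n_iter=it, mismatch_history=history,
        final_mismatch=history[-1] if history else float("nan"),
        ergodicity_flag=flag, ergodicity_detail=detail,
    )
    return h, J, report


def _ergodicity_probe(model: PairwiseModel, config: LearningConfig
                      ) -> tuple[bool, str]:
    """Long verification run; flag if the chain leaves its sampled regime.

    The trace is cut into windows; a spread of window-mean activities larger
    than 0.3 (fraction of the population) indicates a jump between metastable
    regimes, i.e. the sampling used during learning was not ergodic.
    """
    trace = _run(model, SamplerConfig(
        steps=config.verification_steps, seed=config.seed + 10_000,
        variant=config.variant, record_every=model.N, burn_in=0,
    ))
    n_windows = 100
    w = max(1, trace.n_recorded // n_windows)
    usable = trace.total_activity[: w * n_windows] if trace.n_recorded >= n_windows \
        else trace.total_activity
    means = usable[: (usable.size // w) * w].reshape(-1, w).mean(axis=1) / model.N
    spread = float(means.max() - means.min())
    flagged = spread > 0.3
    detail = (f"window s̄ range [{means.min():.3f}, {means.max():.3f}], "
              f"spread {spread:.3f}")
    return flagged, detail


def _naive_from_mc(m: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    var = m * (1 - m)
    silent = var <= 0
    safe = np.where(silent, 1.0, var)
    J = c / np.outer(safe, safe)
    np.fill_diagonal(J, 0.0)
    if silent.any():
        logger.warning("%d silent/saturated unit(s); their couplings zeroed",
                       int(silent.sum()))
        J[silent, :] = 0.0
        J[:, silent] = 0.0
    with np.errstate(divide="ignore"):
        h = np.where(silent, 0.0, np.log(m / (1 - m))) - J @ m
    return h, J


def naive_inversion(stats: EmpiricalStats) -> tuple[np.ndarray, np.ndarray]:
    """Weak-correlation (linear-order) inversion of empirical statistics.

    J_ij = c_ij / [m_i(1−m_i) m_j(1−m_j)] and the mean-field-consistent bias
    h_i = logit(m_i) − Σ_j J_ij m_j.  Intended as a Boltzmann-learning start.
    """
    return _naive_from_mc(stats.m, stats.c)


@dataclass
class FixedPointSet:
    """Solutions of the naive mean-field self-consistency equations."""

    solutions: list[tuple[np.ndarray, bool]]  # (m vector, stable?)

    @property
    def homogeneous(self) -> list[tuple[float, bool]]:
        return [(float(m.mean()), s) for m, s in self.solutions]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def mean_field_fixed_points_homogeneous(N: int, h_r: float, J_r: float,
                                        grid: int = 1000) -> FixedPointSet:
    """All roots of m̄ = σ((N−1) J_r m̄ + h_r), with stability by map slope."""
    from scipy.optimize import brentq

    def resid(mm):
        return _sigmoid((N - 1) * J_r * mm + h_r) - mm

    xs = np.linspace(0.0, 1.0, grid)
    vals = resid(xs)
    roots: list[float] = []
    for i in range(grid - 1):
        if vals[i] == 0.0 or (vals[i] > 0) != (vals[i + 1] > 0):
            roots.append(float(brentq(resid, xs[i], xs[i + 1], xtol=1e-13)))
    sols = []
    for r in roots:
        sig = _sigmoid((N - 1) * J_r * r + h_r)
        slope = sig * (1 - sig) * (N - 1) * J_r
        sols.append((np.full(N, r), bool(abs(slope) < 1)))
    return FixedPointSet(solutions=sols)


def mean_field_fixed_points(model: PairwiseModel, n_starts: int = 20,
                            damping: float = 0.5, seed: int = 0,
                            max_iter: int = 10_000,
                            tol: float = 1e-12) -> FixedPointSet:
    """Fixed points of m_i = σ(Σ_{j≠i} J_ij m_j + h_i) by damped iteration.

    Multiple random starts, solutions deduplicated at 1e−8.  Stability is the
    spectral radius of the linearised map σ′ ∘ J at the fixed point.
    """
    rng = np.random.default_rng(seed)
    found: list[np.ndarray] = []
    for k in range(n_starts):
        m = rng.random(model.N) if k > 0 else _sigmoid(model.h)
        for _ in range(max_iter):
            new = (1 - damping) * m + damping * _sigmoid(model.J @ m + model.h)
            if np.abs(new - m).max() < tol:
                m = new
                break
            m = new
        resid = np.abs(_sigmoid(model.J @ m + model.h) - m).max()
        if resid < 1e-10 and not any(np.abs(m - f).max() < 1e-8 for f in found):
            found.append(m)
    sols = []
    for m in found:
        sig = _sigmoid(model.J @ m + model.h)
        jac = (sig * (1 - sig))[:, None] * model.J
        rad = float(np.abs(np.linalg.eigvals(jac)).max())
        sols.append((m, bool(rad < 1)))
    return FixedPointSet(solutions=sols)
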