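"""Asynchronous Glauber dynamics, standard and inhibited.

One step = one single-unit update attempt: a unit i is chosen uniformly at
random and set to 1 with probability σ(F_i), where σ is the logistic function
and F_i the local field.  Variants differ only in F_i:

``standard``
    F_i = h_i + Σ_{k≠i} J_ik s_k.  Stationary law: the pairwise model P_p.
``inhibited_single``
    one extra inhibitory unit s_I = H(Σ_k s_k / N − θ) updated
    deterministically after every step; F_i gains J_I s_I.  Only
    approximately stationary for P_i (exact in the large-N limit).
``inhibited_excluded``
    per-unit exclusion of i from the inhibitor's input:
    F_i gains J_I H(Σ_{k≠i} s_k / N − θ).  Satisfies detailed balance with
    the inhibited model P_i exactly (H(0) = 1 throughout).

All variants consume exactly two pseudo-random values per step (unit choice,
acceptance draw), so with J_I = 0 every variant reproduces the standard
trajectory bit-for-bit under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix, identity
from scipy.sparse.linalg import spsolve

from .models import (
    PairwiseModel,
    exact_distribution,
    ng_term,
    state_table,
)
from .reduced import stationary_points

__all__ = [
    "SamplerConfig",
    "SamplerTrace",
    "glauber_run",
    "inhibited_glauber_run",
    "transition_matrix",
    "detailed_balance_check",
    "multistart_probe",
]

Variant = Literal["standard", "inhibited_single", "inhibited_excluded"]
_VARIANT_CODE = {"standard": 0, "inhibited_single": 1, "inhibited_excluded": 2}


@dataclass
class SamplerConfig:
    steps: int
    seed: int
    variant: Variant = "standard"
    initial_state: np.ndarray | None = None
    initial_activity: int | None = None  # random placement of this many 1s
    record_every: int = 1
    record_states: bool = False
    burn_in: int | None = None  # default 100*N update attempts

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.variant not in _VARIANT_CODE:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class SamplerTrace:
    """Recorded output of a Glauber run."""

    total_activity: np.ndarray  # S = N s̄ at each recorded step
    m_hat: np.ndarray  # empirical single-unit means over recorded steps
    g_hat: np.ndarray  # empirical coupled activities over recorded steps
    states: np.ndarray | None  # (n_rec, N) uint8 if recorded
    seed: int
    config: SamplerConfig = field(repr=False, default=None)

    @property
    def n_recorded(self) -> int:
        return self.total_activity.shape[0]


@njit(cache=True)
def _glauber_kernel(J, h, J_I, Theta, variant, s0, burn_in, steps,
                    record_every, seed, record_states):  # pragma: no cover
    np.random.seed(seed)
    N = h.shape[0]
    s = s0.copy()
    field = J @ s.astype(np.float64)
    S = int(s.sum())
    n_rec = steps // record_every
    tot = np.empty(n_rec, np.int64)
    if record_states:
        states = np.empty((n_rec, N), np.uint8)
    else:
        states = np.empty((0, N), np.uint8)
    msum = np.zeros(N, np.float64)
    gsum = np.zeros((N, N), np.float64)
    active = np.empty(N, np.int64)
    k = 0
    total = burn_in + steps
    for t in range(total):
        i = np.random.randint(0, N)
        F = h[i] + field[i]
        if variant == 1:
            if S >= Theta:  # H(0)=1: inhibitor on when s̄ >= θ
                F += J_I
        elif variant == 2:
            if S - s[i] >= Theta:
                F += J_I
        u = np.random.random()
        new = 1 if u < 1.0 / (1.0 + np.exp(-F)) else 0
        if new != s[i]:
            d = new - s[i]
            S += d
            s[i] = new
            for q in range(N):
                field[q] += J[q, i] * d
        if t >= burn_in and (t - burn_in + 1) % record_every == 0:
            tot[k] = S
            na = 0
            for q in range(N):
                if s[q] == 1:
                    active[na] = q
                    na += 1
            for a in range(na):
                qa = active[a]
                msum[qa] += 1.0
                for b in range(na):
                    gsum[qa, active[b]] += 1.0
            if record_states:
                states[k, :] = s
            k += 1
    return tot, msum, gsum, states, k


def _initial_state(model: PairwiseModel, config: SamplerConfig,
                   rng: np.random.Generator) -> np.ndarray:
    if config.initial_state is not None:
        s0 = np.asarray(config.initial_state, dtype=np.int8)
        if s0.shape != (model.N,) or not np.isin(s0, (0, 1)).all():
            raise ValueError("initial_state must be a binary vector of length N")
        return s0
    if config.initial_activity is not None:
        if not 0 <= config.initial_activity <= model.N:
            raise ValueError("initial_activity must be in {0,...,N}")
        s0 = np.zeros(model.N, dtype=np.int8)
        idx = rng.choice(model.N, size=config.initial_activity, replace=False)
        s0[idx] = 1
        return s0
    return np.zeros(model.N, dtype=np.int8)


def _run(model: PairwiseModel, config: SamplerConfig) -> SamplerTrace:
    variant = _VARIANT_CODE[config.variant]
    if variant > 0 and not model.has_inhibition:
        raise ValueError("inhibited variants need inhibition parameters")
    J_I = model.J_I if model.has_inhibition else 0.0
    Theta = model.Theta if model.has_inhibition else 0
    burn_in = config.burn_in if config.burn_in is not None else 100 * model.N
    rng = np.random.default_rng(config.seed)
    s0 = _initial_state(model, config, rng)
    kernel_seed = int(config.seed) % (2**32 - 1)
    tot, msum, gsum, states, k = _glauber_kernel(
        np.ascontiguousarray(model.J, dtype=np.float64),
        np.ascontiguousarray(model.h, dtype=np.float64),
        float(J_I), int(Theta), variant, s0,
        int(burn_in), int(config.steps), int(config.record_every),
        kernel_seed, config.record_states,
    )
    n_rec = max(k, 1)
    m_hat = msum / n_rec
    g_hat = gsum / n_rec
    np.fill_diagonal(g_hat, m_hat)
    return SamplerTrace(
        total_activity=tot[:k],
        m_hat=m_hat,
        g_hat=g_hat,
        states=states[:k] if config.record_states else None,
        seed=config.seed,
        config=config,
    )


def glauber_run(model: PairwiseModel, config: SamplerConfig) -> SamplerTrace:
    """Standard asynchronous Glauber dynamics sampling P_p."""
    if config.variant != "standard":
        raise ValueError("use inhibited_glauber_run for inhibited variants")
    return _run(model, config)


def inhibited_glauber_run(model: PairwiseModel, config: SamplerConfig) -> SamplerTrace:
    """Inhibited Glauber dynamics (single-inhibitor or per-unit exclusion)."""
    if config.variant == "standard":
        raise ValueError("use glauber_run for the standard variant")
    return _run(model, config)


def _local_fields(model: PairwiseModel, states: np.ndarray,
                  variant: int) -> np.ndarray:
    """F_i(s) for every enumerated state; (2^N, N)."""
    fs = states.astype(np.float64)
    F = fs @ model.J + model.h  # J symmetric, zero diagonal: excludes i itself
    if variant == 0:
        return F
    S = states.sum(axis=1).astype(np.int64)
    if variant == 1:
        on = (S >= model.Theta).astype(np.float64)
        return F + model.J_I * on[:, None]
    S_excl = S[:, None] - states  # population excluding unit i
    return F + model.J_I * (S_excl >= model.Theta)


def transition_matrix(model: PairwiseModel, variant: Variant = "standard",
                      cap: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Single-flip transition matrix over all 2^N states + stationary vector.

    Row s, column s': probability of moving to s' in one update attempt.
    The stationary distribution is obtained by solving the sparse linear
    system (Pᵀ − I)π = 0 with Σπ = 1.
    """
    N = model.N
    if N > cap:
        raise ValueError(f"N={N} exceeds transition-matrix cap {cap}")
    code = _VARIANT_CODE[variant]
    if code > 0 and not model.has_inhibition:
        raise ValueError("inhibited variants need inhibition parameters")
    n_states = 2 ** N
    states = state_table(N)
    F = _local_fields(model, states, code)
    p_on = 1.0 / (1.0 + np.exp(-F))
    rows, cols, vals = [], [], []
    idx = np.arange(n_states, dtype=np.int64)
    diag = np.zeros(n_states)
    for i in range(N):
        bit = 1 << i
        target_on = idx | bit
        target_off = idx & ~bit
        pi_on = p_on[:, i] / N
        pi_off = (1.0 - p_on[:, i]) / N
        for tgt, pr in ((target_on, pi_on), (target_off, pi_off)):
            same = tgt == idx
            diag += np.where(same, pr, 0.0)
            rows.append(idx[~same])
            cols.append(tgt[~same])
            vals.append(pr[~same])
    rows.append(idx)
    cols.append(idx)
    vals.append(diag)
    P = csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_states, n_states),
    )
    A = (P.T - identity(n_states, format="csr")).tolil()
    A[0, :] = 1.0  # replace one equation by the normalisation Σπ = 1
    b = np.zeros(n_states)
    b[0] = 1.0
    pi = spsolve(A.tocsr(), b)
    pi = np.maximum(pi, 0)
    pi /= pi.sum()
    return P.toarray(), pi


def detailed_balance_check(model: PairwiseModel, variant: Variant,
                           cap: int = 10) -> float:
    """Max |p(s'|s)π(s) − p(s|s')π(s')| over single-flip pairs.

    π is the exact model distribution: P_p for ``standard``, P_i for the
    inhibited variants.  For ``standard`` and ``inhibited_excluded`` the
    result is at machine precision; ``inhibited_single`` violates detailed
    balance with respect to P_i (strictly positive result).
    """
    N = model.N
    if N > cap:
        raise ValueError(f"N={N} exceeds detailed-balance cap {cap}")
    code = _VARIANT_CODE[variant]
    target = exact_distribution(model if code > 0 else
                                PairwiseModel(h=model.h, J=model.J), cap=cap)
    states = state_table(N)
    F = _local_fields(model, states, code)
    p_on = 1.0 / (1.0 + np.exp(-F))
    idx = np.arange(2 ** N, dtype=np.int64)
    worst = 0.0
    for i in range(N):
        bit = 1 << i
        s_off = idx & ~bit
        s_on = idx | bit
        # flow off -> on and back, per unordered pair (enumerate via off states)
        off_states = idx[(idx & bit) == 0]
        on_states = off_states | bit
        fwd = (p_on[off_states, i] / N) * target.p[off_states]
        bwd = ((1.0 - p_on[on_states, i]) / N) * target.p[on_states]
        worst = max(worst, float(np.abs(fwd - bwd).max()))
    return worst


@dataclass
class BasinSummary:
    threshold: float | None  # continuous minimum s̄ of the reduced proxy
    labels: list[str]  # 'low' / 'high' per start
    n_basins: int
    final_means: list[float]


def multistart_probe(model: PairwiseModel, initial_activities: list[int],
                     steps: int, seed: int = 0,
                     variant: Variant = "standard",
                     record_every: int | None = None
                     ) -> tuple[list[SamplerTrace], BasinSummary]:
    """Run one trace per initial total activity and classify the basins.

    Basin classification thresholds the final-window mean activity at the
    continuous minimum of the homogeneous (population-averaged) reduced proxy
    of the model: below -> 'low' basin, at/above -> 'high'.  A unimodal proxy
    yields a single basin by construction.
    """
    N = model.N
    h_r = float(model.h.mean())
    iu = np.triu_indices(N, k=1)
    J_r = float(model.J[iu].mean())
    analysis = stationary_points(N, h_r, J_r)
    threshold = analysis.minima[0] if analysis.bimodal else None
    traces: list[SamplerTrace] = []
    labels: list[str] = []
    finals: list[float] = []
    rec = record_every or N
    for k, a0 in enumerate(initial_activities):
        config = SamplerConfig(
            steps=steps, seed=seed + 1000 * k + a0, variant=variant,
            initial_activity=int(a0), record_every=rec, burn_in=0,
        )
        trace = _run(model, config)
        traces.append(trace)
        window = trace.total_activity[-max(1, trace.n_recorded // 4):]
        sbar = float(window.mean()) / N
        finals.append(sbar)
        if threshold is None:
            labels.append("low")
        else:
            labels.append("low" if sbar < threshold else "high")
    return traces, BasinSummary(
        threshold=threshold,
        labels=labels,
        n_basins=len(set(labels)),
        final_means=finals,
    )
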