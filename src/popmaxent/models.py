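"""Model distributions: pairwise, inhibited, truncated and reduced.

All distributions are defined through log-weights and normalised in the log
domain (log-sum-exp); the reduced model uses log-binomials via ``gammaln`` so
it is overflow-free for population sizes in the thousands.

The pairwise (Ising) model over binary states ``s`` in {0,1}^N is

    P_p(s) ∝ exp( Σ_i h_i s_i + Σ_{i<j} J_ij s_i s_j ).

The inhibited model multiplies this by the reference measure
``exp[J_I N G(s̄ − θ)]`` with ``G(x) = x H(x)`` and the convention
``H(0) = 1``: a single asymmetric inhibitory feedback that drains probability
from states whose population-averaged activity s̄ reaches the threshold θ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "PairwiseModel",
    "ReducedModel",
    "ExactDistribution",
    "DEFAULT_ENUM_CAP",
    "state_table",
    "pairwise_log_weight",
    "inhibited_log_weight",
    "exact_distribution",
    "reduced_distribution",
    "truncated_distribution",
    "relative_entropy",
]

DEFAULT_ENUM_CAP = 20


@dataclass
class PairwiseModel:
    """Multipliers (h, J) with optional inhibition parameters (J_I, θ).

    ``J`` is symmetric with zero diagonal.  The threshold is stored as the
    integer ``Theta = N*θ`` so grid identities hold exactly.
    """

    h: np.ndarray
    J: np.ndarray
    J_I: float | None = None
    Theta: int | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.shape[0]
        if self.J.shape != (n, n):
            raise ValueError("J must be N x N")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have zero diagonal")
        if (self.J_I is None) != (self.Theta is None):
            raise ValueError("J_I and Theta must be given together")
        if self.Theta is not None:
            if not (isinstance(self.Theta, (int, np.integer)) and 0 <= self.Theta <= n):
                raise ValueError("Theta must be an integer in {0,...,N}")
            self.Theta = int(self.Theta)

    @property
    def N(self) -> int:
        return self.h.shape[0]

    @property
    def has_inhibition(self) -> bool:
        return self.J_I is not None

    @property
    def theta(self) -> float | None:
        return None if self.Theta is None else self.Theta / self.N

    @classmethod
    def with_theta(cls, h, J, J_I: float, theta: float) -> "PairwiseModel":
        """Build from a fractional threshold.

        The inhibitor switches on when S = N s̄ reaches N*theta, so only the
        grid point Θ = ceil(N*theta) matters (H(0) = 1): any theta in
        ((Θ−1)/N, Θ/N] defines the same model.  Θ is stored exactly.
        """
        if not 0 <= theta <= 1:
            raise ValueError("theta must be in [0, 1]")
        h = np.asarray(h, dtype=float)
        n_theta = theta * h.shape[0]
        Theta = int(round(n_theta)) if abs(n_theta - round(n_theta)) < 1e-9 \
            else int(np.ceil(n_theta))
        return cls(h=h, J=J, J_I=J_I, Theta=Theta)

    @classmethod
    def homogeneous(cls, N: int, h_r: float, J_r: float,
                    J_I: float | None = None, theta: float | None = None
                    ) -> "PairwiseModel":
        h = np.full(N, h_r)
        J = np.full((N, N), J_r)
        np.fill_diagonal(J, 0.0)
        if J_I is None:
            return cls(h=h, J=J)
        return cls.with_theta(h, J, J_I, theta)

    def to_json(self, path: str | Path) -> None:
        obj = {"N": self.N, "h": self.h.tolist(), "J": self.J.tolist()}
        if self.has_inhibition:
            obj["J_I"] = self.J_I
            obj["theta"] = self.theta
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "PairwiseModel":
        obj = json.loads(Path(path).read_text())
        n = int(obj["N"])
        h = np.asarray(obj["h"], dtype=float)
        rows = obj["J"]
        J = np.zeros((n, n))
        for i, row in enumerate(rows):
            J[i, : len(row)] = row
        # accept a full symmetric matrix or either triangle; symmetrise
        L, U = np.tril(J, -1), np.triu(J, 1)
        if np.allclose(L, U.T):
            full = L + U
        else:
            tri = L if np.abs(L).sum() >= np.abs(U).sum() else U
            full = tri + tri.T
        np.fill_diagonal(full, 0.0)
        if "J_I" in obj:
            return cls.with_theta(h, full, float(obj["J_I"]), float(obj["theta"]))
        return cls(h=h, J=full)


@dataclass
class ReducedModel:
    """Homogeneous two-parameter model; exact pmf over total activity S=N*s̄.

    ``log_pmf[S]`` is the normalised log-probability of observing exactly S
    active units, S in {0,...,N}.
    """

    N: int
    h_r: float
    J_r: float
    log_pmf: np.ndarray

    @property
    def pmf(self) -> np.ndarray:
        return np.exp(self.log_pmf)

    @property
    def E_sbar(self) -> float:
        S = np.arange(self.N + 1)
        return float((self.pmf * S).sum() / self.N)

    @property
    def E_factorial(self) -> float:
        """E[ N s̄ (N s̄ − 1) ], the second factorial moment of S."""
        S = np.arange(self.N + 1)
        return float((self.pmf * S * (S - 1)).sum())

    @property
    def cbar(self) -> float:
        m = self.E_sbar
        return self.E_factorial / (self.N * (self.N - 1)) - m * m

    @property
    def rhobar(self) -> float:
        m = self.E_sbar
        var = m - m * m
        if var <= 0:
            return float("nan")
        return self.cbar / var

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"N": self.N, "h_r": self.h_r, "J_r": self.J_r})
        )


@dataclass
class ExactDistribution:
    """Probability table over all 2^N states with model expectations."""

    p: np.ndarray  # (2^N,)
    log_p: np.ndarray
    E_s: np.ndarray  # (N,) single-unit expectations
    E_ss: np.ndarray  # (N, N), diagonal equals E_s

    @property
    def N(self) -> int:
        return self.E_s.shape[0]


def state_table(N: int) -> np.ndarray:
    """All 2^N binary states as an (2^N, N) uint8 matrix; bit i of the row index."""
    idx = np.arange(2 ** N, dtype=np.int64)
    return ((idx[:, None] >> np.arange(N)) & 1).astype(np.uint8)


def _check_binary(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s)
    if not np.isin(s, (0, 1)).all():
        raise ValueError("state entries must be 0 or 1")
    return s.astype(np.float64)


def pairwise_log_weight(s: np.ndarray, model: PairwiseModel) -> float:
    """Unnormalised log-probability Σ h_i s_i + Σ_{i<j} J_ij s_i s_j."""
    s = _check_binary(s)
    if s.shape[0] != model.N:
        raise ValueError("state length must equal N")
    return float(model.h @ s + 0.5 * s @ model.J @ s)


def ng_term(S: int | np.ndarray, Theta: int) -> np.ndarray:
    """N G(s̄ − θ) on the activity grid: (S − Θ) H((S − Θ)/N) with H(0)=1."""
    return np.maximum(np.asarray(S) - Theta, 0)


def inhibited_log_weight(s: np.ndarray, model: PairwiseModel) -> float:
    """Pairwise log-weight plus the inhibition term J_I N G(s̄ − θ)."""
    if not model.has_inhibition:
        raise ValueError("model has no inhibition parameters")
    s = _check_binary(s)
    base = pairwise_log_weight(s, model)
    return base + model.J_I * float(ng_term(int(s.sum()), model.Theta))


def _log_weights_all(model: PairwiseModel, cap: int) -> np.ndarray:
    if model.N > cap:
        raise ValueError(
            f"N={model.N} exceeds the enumeration cap {cap}; "
            "raise `cap` explicitly if you really want 2^N states"
        )
    states = state_table(model.N).astype(np.float64)
    logw = states @ model.h + 0.5 * np.einsum("si,ij,sj->s", states, model.J, states)
    if model.has_inhibition:
        S = states.sum(axis=1).astype(int)
        logw = logw + model.J_I * ng_term(S, model.Theta)
    return logw


def exact_distribution(model: PairwiseModel,
                       cap: int = DEFAULT_ENUM_CAP) -> ExactDistribution:
    """Exhaustive normalisation over all 2^N states (oracle for small N)."""
    logw = _log_weights_all(model, cap)
    log_p = logw - logsumexp(logw)
    p = np.exp(log_p)
    states = state_table(model.N).astype(np.float64)
    E_s = p @ states
    E_ss = (states * p[:, None]).T @ states
    np.fill_diagonal(E_ss, E_s)
    return ExactDistribution(p=p, log_p=log_p, E_s=E_s, E_ss=E_ss)


def reduced_distribution(N: int, h_r: float, J_r: float) -> ReducedModel:
    """Exact reduced-model pmf over the total activity S ∈ {0,...,N}.

    P_r(S) ∝ C(N,S) exp[h_r S + ½ J_r S(S−1)], computed with log-binomials.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    S = np.arange(N + 1, dtype=np.float64)
    logw = (
        gammaln(N + 1) - gammaln(S + 1) - gammaln(N - S + 1)
        + h_r * S + 0.5 * J_r * S * (S - 1)
    )
    return ReducedModel(N=N, h_r=h_r, J_r=J_r, log_pmf=logw - logsumexp(logw))


def truncated_distribution(model: PairwiseModel, theta: float,
                           cap: int = DEFAULT_ENUM_CAP) -> ExactDistribution:
    """Pairwise weights restricted to s̄ ≤ θ, renormalised (zero above)."""
    base = PairwiseModel(h=model.h, J=model.J)
    logw = _log_weights_all(base, cap)
    states = state_table(model.N)
    keep = states.sum(axis=1) <= theta * model.N + 1e-12
    if not keep.any():
        raise ValueError("empty support: no state has s̄ <= theta")
    logw = np.where(keep, logw, -np.inf)
    log_p = logw - logsumexp(logw[keep])
    p = np.exp(log_p)
    fs = states.astype(np.float64)
    E_s = p @ fs
    E_ss = (fs * p[:, None]).T @ fs
    np.fill_diagonal(E_ss, E_s)
    return ExactDistribution(p=p, log_p=log_p, E_s=E_s, E_ss=E_ss)


def relative_entropy(p: np.ndarray, p0: np.ndarray) -> float:
    """Discrimination information Σ p ln(p/p0) in nats, with 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if p.shape != p0.shape:
        raise ValueError("shapes differ")
    bad = (p > 0) & (p0 == 0)
    if bad.any():
        raise ValueError("support violation: p > 0 where p0 = 0")
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(p0[mask]))))
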