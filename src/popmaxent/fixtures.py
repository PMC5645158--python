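"""Synthetic models and surrogate rasters.

Surrogate data are generated with the (inhibited) Glauber dynamics itself:
recorded states, thinned by one sweep-equivalent (``record_every = N``)
between bins, are stacked into a binary raster whose statistics converge to
the model expectations.  Jittered multipliers turn the homogeneous reduced
model into a controlled inhomogeneous one (normally distributed h_i, J_ij).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .glauber import SamplerConfig, Variant, _run
from .models import PairwiseModel
from .raster import BinaryRaster

__all__ = ["JitterSpec", "jittered_multipliers", "surrogate_raster"]

logger = logging.getLogger(__name__)


@dataclass
class JitterSpec:
    """Normal jitter around homogeneous multipliers.

    Defaults replicate the small-jitter bistability setting: couplings
    J_ij ~ N(J_r, 0.009²) and biases h_i ~ N(h_r, 0.8²).
    """

    h_r: float
    J_r: float
    sigma_h: float = 0.8
    sigma_J: float = 0.009
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_h < 0 or self.sigma_J < 0:
            raise ValueError("standard deviations must be >= 0")


def jittered_multipliers(N: int, spec: JitterSpec,
                         J_I: float | None = None,
                         theta: float | None = None) -> PairwiseModel:
    """Inhomogeneous model with i.i.d. normal h_i and (mirrored) J_ij."""
    rng = np.random.default_rng(spec.seed)
    h = spec.h_r + spec.sigma_h * rng.standard_normal(N)
    J = np.zeros((N, N))
    iu = np.triu_indices(N, k=1)
    J[iu] = spec.J_r + spec.sigma_J * rng.standard_normal(iu[0].size)
    J = J + J.T
    if J_I is None:
        return PairwiseModel(h=h, J=J)
    return PairwiseModel.with_theta(h, J, J_I, theta)


def surrogate_raster(model: PairwiseModel, n_bins: int, seed: int = 0,
                     variant: Variant = "standard",
                     record_every: int | None = None,
                     burn_in: int | None = None) -> BinaryRaster:
    """Binary raster sampled from the model by (inhibited) Glauber dynamics.

    One recorded state per ``record_every`` update attempts (default: one
    sweep, N attempts) becomes one raster bin.  A warning is logged when the
    standard variant visibly jumps between metastable regimes during the run
    (non-ergodic sampling: the surrogate statistics are then untrustworthy).
    """
    rec = record_every or model.N
    config = SamplerConfig(
        steps=n_bins * rec, seed=seed, variant=variant,
        record_every=rec, record_states=True, burn_in=burn_in,
    )
    trace = _run(model, config)
    if variant == "standard":
        sbar = trace.total_activity / model.N
        n_win = max(1, sbar.size // 50)
        means = sbar[: (sbar.size // n_win) * n_win].reshape(-1, n_win).mean(axis=1)
        if means.size > 1 and float(means.max() - means.min()) > 0.3:
            logger.warning(
                "surrogate run jumped between metastable regimes "
                "(window s̄ spread %.2f); statistics are unreliable",
                float(means.max() - means.min()),
            )
    return BinaryRaster(values=trace.states.T.copy(), delta=3.0)
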