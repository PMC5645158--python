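"""Spike data, binary rasters and the empirical statistics used as model constraints.

A recording of ``N`` units over ``T`` milliseconds is discretised into ``n``
bins of width ``delta`` ms; a unit is "active" in a bin if it fired at least
once there.  The time-averaged activities ``m_i``, coupled activities
``g_ij = <s_i s_j>`` and their population averages are the sufficient
statistics of the pairwise maximum-entropy model.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "BinaryRaster",
    "EmpiricalStats",
    "CountCorrelation",
    "bin_spikes",
    "empirical_stats",
    "spike_count_correlation",
    "estimate_rho_from_rsc",
]

logger = logging.getLogger(__name__)


@dataclass
class SpikeTrainSet:
    """Parallel spike trains: one sorted array of spike times (ms) per unit."""

    trains: list[np.ndarray]
    duration: float  # T, ms

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for i, t in enumerate(self.trains):
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValueError(
                    f"unit {i}: spike times must lie in [0, T={self.duration})"
                )
            if np.any(np.diff(t) < 0):
                self.trains[i] = np.sort(t)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @classmethod
    def from_text(cls, path: str | Path, duration: float | None = None,
                  n_units: int | None = None) -> "SpikeTrainSet":
        """Read two-column delimited text ``unit_id  time_ms`` (header optional)."""
        ids, times = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.replace(",", " ").split()
                if not parts:
                    continue
                try:
                    u = int(parts[0])
                except ValueError:
                    continue  # header
                ids.append(u)
                times.append(float(parts[1]))
        ids_arr = np.asarray(ids, dtype=int)
        times_arr = np.asarray(times, dtype=float)
        n = n_units if n_units is not None else (ids_arr.max() + 1 if ids_arr.size else 0)
        if duration is None:
            duration = float(times_arr.max()) + 1e-9 if times_arr.size else 1.0
        trains = [np.sort(times_arr[ids_arr == i]) for i in range(n)]
        return cls(trains=trains, duration=duration)


@dataclass
class BinaryRaster:
    """N x n binary activity matrix with bin width ``delta`` ms."""

    values: np.ndarray  # (N, n) of {0,1}
    delta: float = 3.0  # ms; 3 ms is the primary binning used throughout

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("raster must be 2-D (units x bins)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_text(self, path: str | Path) -> None:
        """Write as 0/1 delimited text plus a JSON sidecar {N, n, delta_ms}."""
        path = Path(path)
        np.savetxt(path, self.values, fmt="%d", delimiter=" ")
        sidecar = {"N": self.n_units, "n": self.n_bins, "delta_ms": self.delta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_text(cls, path: str | Path) -> "BinaryRaster":
        path = Path(path)
        values = np.loadtxt(path, dtype=np.uint8, ndmin=2)
        delta = 3.0
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            delta = float(meta.get("delta_ms", delta))
        return cls(values=values, delta=delta)


@dataclass
class EmpiricalStats:
    """First- and second-order time-averaged statistics of a raster.

    ``m``    -- per-unit mean activities, ``m_i = <s_i(t)>_t``
    ``g``    -- raw correlations (coupled activities), ``g_ij = <s_i s_j>_t``,
                with ``g_ii = m_i``
    ``c``    -- covariances ``c_ij = g_ij - m_i m_j``
    ``rho``  -- Pearson correlation coefficients; NaN where a unit has zero
                variance (``m_i`` equal to 0 or 1)
    Population averages (``mbar`` etc.) are means over unordered pairs i<j;
    ``rhobar`` averages only the defined pairs.
    """

    m: np.ndarray
    g: np.ndarray
    c: np.ndarray
    rho: np.ndarray
    mbar: float
    gbar: float
    cbar: float
    rhobar: float
    rho_defined: np.ndarray = field(repr=False, default=None)  # boolean mask on pairs


@dataclass
class CountCorrelation:
    """Pearson correlation of spike counts in disjoint windows of ``tau`` bins.

    ``tau = 1`` reproduces the bin-scale Pearson matrix ``rho``; ``tau = n``
    is the (degenerate, single-window) spike-count correlation ``r_SC``.
    """

    tau: int
    nu: np.ndarray  # (N, n_windows) counts
    r: np.ndarray  # (N, N), NaN where undefined
    defined: np.ndarray  # boolean (N, N)


def bin_spikes(spikes: SpikeTrainSet, delta: float = 3.0) -> BinaryRaster:
    """Discretise spike trains into a binary raster.

    Bins are half-open ``[t*delta, (t+1)*delta)``; one or more spikes in a bin
    give the entry 1.  ``n = ceil(T / delta)``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    n = math.ceil(spikes.duration / delta)
    values = np.zeros((spikes.n_units, n), dtype=np.uint8)
    for i, train in enumerate(spikes.trains):
        if train.size:
            idx = np.floor(train / delta).astype(int)
            values[i, idx] = 1
    return BinaryRaster(values=values, delta=delta)


def empirical_stats(raster: BinaryRaster) -> EmpiricalStats:
    """Compute m, g, c, rho and their population averages from a raster."""
    x = raster.values.astype(np.float64)
    n_units, n_bins = x.shape
    if n_bins == 0:
        raise ValueError("raster has no bins")
    m = x.mean(axis=1)
    g = (x @ x.T) / n_bins
    np.fill_diagonal(g, m)  # s^2 = s for binary units
    c = g - np.outer(m, m)
    var = m - m * m
    defined = (var[:, None] > 0) & (var[None, :] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = c / np.sqrt(np.outer(var, var))
    rho[~defined] = np.nan
    iu = np.triu_indices(n_units, k=1)
    mbar = float(m.mean())
    gbar = float(g[iu].mean()) if iu[0].size else float("nan")
    cbar = float(c[iu].mean()) if iu[0].size else float("nan")
    pair_defined = defined[iu]
    if pair_defined.all():
        rhobar = float(rho[iu].mean()) if iu[0].size else float("nan")
    else:
        n_bad = int((~pair_defined).sum())
        logger.warning(
            "%d pair(s) with a silent or saturated unit excluded from rhobar", n_bad
        )
        rhobar = (
            float(rho[iu][pair_defined].mean()) if pair_defined.any() else float("nan")
        )
    return EmpiricalStats(
        m=m, g=g, c=c, rho=rho, mbar=mbar, gbar=gbar, cbar=cbar, rhobar=rhobar,
        rho_defined=defined,
    )


def spike_count_correlation(raster: BinaryRaster, tau: int) -> CountCorrelation:
    """Pearson correlation of spike counts over disjoint windows of ``tau`` bins.

    The trailing partial window is dropped.  Entries are NaN (flagged
    undefined) where a count series has zero variance.
    """
    n_bins = raster.n_bins
    if not 1 <= tau <= n_bins:
        raise ValueError(f"tau must be in [1, {n_bins}]")
    n_win = n_bins // tau
    x = raster.values[:, : n_win * tau].astype(np.float64)
    nu = x.reshape(raster.n_units, n_win, tau).sum(axis=2)
    dev = nu - nu.mean(axis=1, keepdims=True)
    cov = (dev @ dev.T) / n_win
    var = np.diag(cov).copy()
    defined = (var[:, None] > 0) & (var[None, :] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(np.outer(var, var))
    r[~defined] = np.nan
    return CountCorrelation(tau=tau, nu=nu, r=r, defined=defined)


def estimate_rho_from_rsc(rsc: float) -> float:
    """Conservative bin-scale Pearson correlation from a spike-count correlation.

    Literature surveys of r_CCG(tau) curves find the fine-timescale Pearson
    correlation satisfies ``rho >~ r_SC / 20``; the lower bound is used as a
    deliberately bimodality-averse estimate.
    """
    if abs(rsc) > 1:
        raise ValueError("|r_SC| must be <= 1")
    return rsc / 20.0
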