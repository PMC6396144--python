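"""Exact stochastic simulation (Gillespie direct method) of a TAF model.

The population state is the occupancy vector ``n_k`` = number of cells with
k TAF (k = 0..taf_cap, top bin absorbing) plus the total non-telomeric
focus count.  All propensities are linear in these counts, so the direct
method over four aggregate channels is exact:

* stress TAF gain   — aggregate propensity ``lambda_T * N``; a cell chosen
  proportionally to occupancy moves k → k+1;
* division          — ``delta_c * N``; the chosen cell is renewed in place,
  gaining Poisson(``mu_d``) TAF (constant population size);
* non-TAF gain      — ``lambda_N * N``;
* non-TAF repair    — ``rho * NF`` (first-order).

Waiting times are exponential in the total propensity and the channel is
chosen proportionally, all from one seeded NumPy generator, so a fixed seed
reproduces the trajectory bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .models import ModelSpec, mean_nontaf_analytic

__all__ = ["Trajectory", "simulate", "end_state_cells"]

logger = logging.getLogger(__name__)

_CAP_WARN_FRACTION = 0.001


@dataclass
class Trajectory:
    """Population observables sampled along one stochastic run."""

    sample_times: np.ndarray
    mean_taf: np.ndarray
    frac_taf_positive: np.ndarray
    mean_nontaf: np.ndarray
    rng_seed: int
    occupancy: np.ndarray = field(repr=False, default=None)  # (n_times, cap+1)

    def __post_init__(self) -> None:
        n = len(self.sample_times)
        if not (len(self.mean_taf) == len(self.frac_taf_positive)
                == len(self.mean_nontaf) == n):
            raise ValueError("trajectory sequences must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_months": self.sample_times,
                "mean_taf": self.mean_taf,
                "frac_taf_positive": self.frac_taf_positive,
                "mean_nontaf": self.mean_nontaf,
            }
        )


def _initial_occupancy(model: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    occ = np.zeros(model.taf_cap + 1, dtype=np.int64)
    if model.initial_mean_taf > 0:
        draws = rng.poisson(model.initial_mean_taf, size=model.n_cells)
        np.minimum(draws, model.taf_cap, out=draws)
        np.add.at(occ, draws, 1)
    else:
        occ[0] = model.n_cells
    return occ


def _pick_class(occ: np.ndarray, n_cells: int, rng: np.random.Generator) -> int:
    # inverse-CDF over occupancy; O(taf_cap) per event
    u = rng.random() * n_cells
    acc = 0.0
    for k in range(occ.shape[0]):
        acc += occ[k]
        if u < acc:
            return k
    return occ.shape[0] - 1


def simulate(
    model: ModelSpec,
    sample_times,
    seed: int,
    initial_mean_nontaf: float | None = None,
    keep_occupancy: bool = False,
) -> Trajectory:
    """Run one exact SSA realisation and record observables at ``sample_times``.

    ``initial_mean_nontaf`` defaults to the stationary mean ``lambda_N/rho``
    (total foci are observed to be flat in age, so the process is started at
    stationarity unless told otherwise).  If the total propensity reaches
    zero the state is frozen and remaining samples repeat it.
    """
    times = np.asarray(sample_times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("sample_times must be a nonempty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    if times[0] < 0 or times[-1] > model.horizon_months:
        raise ValueError("sample_times must lie within [0, horizon_months]")

    rng = np.random.default_rng(seed)
    N = model.n_cells
    cap = model.taf_cap
    occ = _initial_occupancy(model, rng)

    if initial_mean_nontaf is None:
        initial_mean_nontaf = (
            model.lambda_N / model.rho if model.rho > 0 else 0.0
        )
    nf = int(rng.poisson(initial_mean_nontaf * N)) if initial_mean_nontaf > 0 else 0

    a_taf = model.lambda_T * N
    a_div = model.delta_c * N
    a_ngain = model.lambda_N * N

    n_out = times.size
    mean_taf = np.empty(n_out)
    frac_pos = np.empty(n_out)
    mean_nf = np.empty(n_out)
    occ_out = np.empty((n_out, cap + 1), dtype=np.int64) if keep_occupancy else None

    ks = np.arange(cap + 1)

    def record(i: int) -> None:
        mean_taf[i] = float(occ @ ks) / N
        frac_pos[i] = float(N - occ[0]) / N
        mean_nf[i] = nf / N
        if keep_occupancy:
            occ_out[i] = occ

    t = 0.0
    i = 0
    frozen = False
    while i < n_out:
        if frozen:
            record(i)
            i += 1
            continue
        a0 = a_taf + a_div + a_ngain + model.rho * nf
        if a0 == 0.0:
            frozen = True
            continue
        t_next = t + rng.exponential(1.0 / a0)
        while i < n_out and times[i] < t_next:
            record(i)
            i += 1
        if i >= n_out:
            break
        t = t_next
        u = rng.random() * a0
        if u < a_taf:
            k = _pick_class(occ, N, rng)
            occ[k] -= 1
            occ[min(k + 1, cap)] += 1
        elif u < a_taf + a_div:
            k = _pick_class(occ, N, rng)
            j = int(rng.poisson(model.mu_d))
            occ[k] -= 1
            occ[min(k + j, cap)] += 1
        elif u < a_taf + a_div + a_ngain:
            nf += 1
        else:
            nf -= 1

    capped = occ[cap]
    if cap >= 1 and capped > _CAP_WARN_FRACTION * N and model.taf_accrual_rate > 0:
        logger.warning(
            "%.2f%% of cells reached the TAF cap (%d); truncation may bias "
            "the mean — raise taf_cap",
            100.0 * capped / N,
            cap,
        )

    return Trajectory(
        sample_times=times,
        mean_taf=mean_taf,
        frac_taf_positive=frac_pos,
        mean_nontaf=mean_nf,
        rng_seed=seed,
        occupancy=occ_out,
    )


def end_state_cells(model: ModelSpec, t: float, seed: int) -> np.ndarray:
    """Per-cell TAF counts at time ``t``, from one SSA run.

    Cells are exchangeable in the aggregated state, so the counts are
    materialised from the final occupancy vector.
    """
    if t > model.horizon_months:
        raise ValueError("t must be <= horizon_months")
    traj = simulate(model, [t], seed, keep_occupancy=True)
    occ = traj.occupancy[-1]
    return np.repeat(np.arange(occ.shape[0]), occ)
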