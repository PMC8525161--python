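"""Living Planet Index from abundance trajectories.

The LPI summarises population trends through annual log-ratio growth rates
``lambda_{i,t} = log10(N_{i,t+1} / N_{i,t})``.  Each year the valid lambdas
are averaged across species and the index is chained multiplicatively,

    I_0 = 1,        I_{t+1} = I_t * 10 ** mean_i(lambda_{i,t}),

which makes ``I_t`` the geometric-mean abundance ratio relative to the
baseline year.  The construction is base-consistent: using natural logs and
``exp`` (or any other base used consistently) yields the identical index.

The log scale is the crux of the null-model result.  Under zero-sum drift
every decline is matched by an equal absolute increase elsewhere, but a
doubling (+0.301 on the log10 scale) cannot offset the log-ratio of the
matching absolute decline in a smaller population, and by Jensen's
inequality ``E[log(N'/N)] < log E[N'/N] = 0`` for any non-degenerate
martingale step — so the index drifts downward even though nothing
directional is happening.

Transitions *into* extinction (``N_{t+1} = 0``) leave the log-ratio
undefined; see ``ZERO_POLICIES`` for the selectable conventions.  After a
species is extinct it contributes nothing to later yearly means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import AbundanceTrajectory, SimulationConfig, simulate

__all__ = [
    "ZERO_POLICIES",
    "LambdaMatrix",
    "LPISeries",
    "EnsembleLPI",
    "lambda_matrix",
    "compute_lpi",
    "lpi_from_abundances",
    "ensemble_lpi",
]

#: Conventions for the single transition into extinction (N_{t+1} = 0):
#:
#: ``"half"``
#:     substitute half an individual, lambda = log10(0.5 / N_t) — a finite
#:     penalty that keeps the index sensitive to extinction (default);
#: ``"floor1"``
#:     substitute one individual, lambda = log10(1 / N_t);
#: ``"exclude"``
#:     drop the transition from the yearly mean entirely.
ZERO_POLICIES = ("half", "floor1", "exclude")

_ZERO_SUBSTITUTE = {"half": 0.5, "floor1": 1.0}


@dataclass
class LambdaMatrix:
    """Per-species annual log10 growth rates with a validity mask.

    ``lambdas[i, t]`` covers the transition ``years[t] -> years[t+1]``;
    entries are valid only where the species was alive at ``years[t]`` (and
    the chosen zero policy keeps the transition).  Invalid entries are NaN.
    """

    lambdas: np.ndarray
    valid: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        if self.lambdas.shape != self.valid.shape:
            raise ValueError("lambdas and valid mask must share a shape")
        if not np.isfinite(self.lambdas[self.valid]).all():
            raise ValueError("valid lambda entries must be finite")


@dataclass
class LPISeries:
    """Chained index values, baseline exactly 1 in the first year."""

    years: np.ndarray
    index: np.ndarray

    def __post_init__(self) -> None:
        if self.index[0] != 1.0:
            raise ValueError("LPI baseline must be exactly 1")
        if not (self.index > 0).all():
            raise ValueError("LPI values must be strictly positive")


@dataclass
class EnsembleLPI:
    """Cross-replicate summary: per-year mean and 95% percentile envelope."""

    years: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_replicates: int
    #: per-replicate index values, shape (n_replicates, n_years + 1)
    indices: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not ((self.lo95 <= self.mean + 1e-12).all()
                and (self.mean <= self.hi95 + 1e-12).all()):
            raise ValueError("envelope must bracket the mean")


def _as_abundances(trajectory) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trajectory, AbundanceTrajectory):
        return np.asarray(trajectory.abundances, dtype=float), trajectory.years
    arr = np.asarray(trajectory, dtype=float)
    if arr.ndim != 2:
        raise ValueError("abundance input must be a 2-D species x year array")
    return arr, np.arange(arr.shape[1])


def lambda_matrix(trajectory, zero_policy: str = "half") -> LambdaMatrix:
    """Annual log10 abundance ratios for every species.

    Parameters
    ----------
    trajectory : AbundanceTrajectory or array-like, shape (S, T+1)
        Abundances; user-supplied arrays may be non-integer (the index is
        scale-invariant) but must be non-negative.
    zero_policy : str
        One of :data:`ZERO_POLICIES`; governs transitions into zero.
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(
            f"zero_policy must be one of {ZERO_POLICIES}, got {zero_policy!r}"
        )
    N, years = _as_abundances(trajectory)
    if (N < 0).any():
        raise ValueError("abundances must be non-negative")
    cur, nxt = N[:, :-1], N[:, 1:]
    valid = cur > 0
    lam = np.full(cur.shape, np.nan)
    alive = valid & (nxt > 0)
    lam[alive] = np.log10(nxt[alive] / cur[alive])
    died = valid & (nxt == 0)
    if died.any():
        if zero_policy == "exclude":
            valid = valid & ~died
        else:
            sub = _ZERO_SUBSTITUTE[zero_policy]
            lam[died] = np.log10(sub / cur[died])
    return LambdaMatrix(lambdas=lam, valid=valid, years=years)


def compute_lpi(lambdas: LambdaMatrix) -> LPISeries:
    """Chain the cross-species mean log-ratio into an index with baseline 1.

    If some year has no valid entries at all (every species extinct) the
    index is carried forward unchanged and a warning is emitted.
    """
    lam, valid = lambdas.lambdas, lambdas.valid
    n_valid = valid.sum(axis=0)
    mean_lam = np.zeros(lam.shape[1])
    any_valid = n_valid > 0
    if not any_valid.all():
        warnings.warn(
            f"{(~any_valid).sum()} year(s) with no surviving species; "
            "index carried forward",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        sums = np.nansum(np.where(valid, lam, 0.0), axis=0)
    mean_lam[any_valid] = sums[any_valid] / n_valid[any_valid]
    index = np.empty(lam.shape[1] + 1)
    index[0] = 1.0
    index[1:] = 10.0 ** np.cumsum(mean_lam)
    return LPISeries(years=lambdas.years if len(lambdas.years) == len(index)
                     else np.arange(len(index)), index=index)


def lpi_from_abundances(trajectory, zero_policy: str = "half") -> LPISeries:
    """Convenience: :func:`lambda_matrix` then :func:`compute_lpi`."""
    N, years = _as_abundances(trajectory)
    lam = lambda_matrix(N, zero_policy=zero_policy)
    series = compute_lpi(lam)
    return LPISeries(years=years, index=series.index)


def ensemble_lpi(
    config: SimulationConfig, zero_policy: str = "half"
) -> EnsembleLPI:
    """Simulate ``config.n_replicates`` communities and summarise their LPI.

    Returns the per-year cross-replicate mean and the distribution-free 95%
    envelope (2.5th and 97.5th percentiles across replicates).
    """
    idx = np.empty((config.n_replicates, config.n_years + 1))
    for r in range(config.n_replicates):
        traj = simulate(config, r)
        idx[r] = lpi_from_abundances(traj, zero_policy=zero_policy).index
    return EnsembleLPI(
        years=config.years,
        mean=idx.mean(axis=0),
        lo95=np.percentile(idx, 2.5, axis=0),
        hi95=np.percentile(idx, 97.5, axis=0),
        n_replicates=config.n_replicates,
        indices=idx,
    )
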