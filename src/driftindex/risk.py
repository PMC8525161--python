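"""Extinction-risk calibration, threat categories, and the Red List Index.

Under the zero-sum community update, the abundance of a single species is
marginally a binomial chain: if the species holds ``a`` of the ``J``
individuals this year, next year's abundance is ``Binomial(J, a/J)``, with
absorbing barriers at 0 (extinction) and ``J`` (mono-dominance).  This
exact marginal makes two routes to extinction probabilities available:

* an **exact oracle** for small ``J``: iterate the (J+1) x (J+1) one-step
  transition matrix ``h`` times and read off the mass absorbed at zero;
* a **Monte-Carlo calibration** at any ``J``: run many replicate chains,
  and for every visit to abundance ``a`` (the chain is Markov and
  time-homogeneous, so every visit is a fresh trial) record whether the
  chain hits zero within each horizon.

Raw Monte-Carlo frequencies are then smoothed by trial-weighted isotonic
regression (pool-adjacent-violators) so that the estimated extinction
probability is non-increasing in abundance and non-decreasing in horizon,
with the exact endpoints P(0, h) = 1 and P(J, h) = 0 pinned.

Threat categories follow the IUCN probability-of-extinction criteria:
Critically Endangered (>= 50% extinction probability within 10 years),
Endangered (>= 20% within 20 years), Vulnerable (>= 10% within 100 years).
The calibrated curves convert these into abundance cutoffs
``A_CR <= A_EN <= A_VU``; a species is Extinct at abundance zero and Least
Concern above ``A_VU`` (the model assigns no Near Threatened category,
which has no quantitative probability criterion).  The Red List Index for
a year is ``1 - sum_i w(c_i) / (w_EX * S)`` with the standard category
weights, so 1 means every species is Least Concern and 0 means every
species is Extinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .simulate import AbundanceTrajectory, SimulationConfig, replicate_rng, simulate

__all__ = [
    "CATEGORIES",
    "RLI_WEIGHTS",
    "RiskCriterion",
    "DEFAULT_CRITERIA",
    "ExtinctionRiskCurve",
    "CategoryThresholds",
    "ThreatTrajectory",
    "RLISeries",
    "marginal_step_distribution",
    "transition_matrix",
    "exact_extinction_probability",
    "exact_extinction_curve",
    "estimate_risk_curves",
    "derive_thresholds",
    "classify_trajectory",
    "compute_rli",
    "category_proportions",
]

#: Threat categories in increasing order of severity.
CATEGORIES = ("LC", "VU", "EN", "CR", "EX")

#: Category weights for the Red List Index.  "standard" is the published
#: RLI weighting (LC=0 .. EX=5, with Near Threatened = 1 present in the
#: scheme though never assigned by this model); "equal" spaces the five
#: assigned categories evenly.  Both give RLI = 1 for all-LC and 0 for
#: all-EX.
RLI_WEIGHTS = {
    "standard": {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4, "EX": 5},
    "equal": {"LC": 0, "VU": 1, "EN": 2, "CR": 3, "EX": 4},
}

# exact-oracle resource guard: the dense transition matrix is (J+1)^2
_MAX_EXACT_J = 4096


@dataclass(frozen=True)
class RiskCriterion:
    """An IUCN-style probability criterion: P(extinct within horizon) >= probability."""

    category: str
    horizon: int
    probability: float

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 year")
        if not 0 < self.probability <= 1:
            raise ValueError("probability must lie in (0, 1]")


#: The three shipped criteria: CR 50%/10y, EN 20%/20y, VU 10%/100y.
DEFAULT_CRITERIA = (
    RiskCriterion("CR", 10, 0.50),
    RiskCriterion("EN", 20, 0.20),
    RiskCriterion("VU", 100, 0.10),
)


def marginal_step_distribution(a: int, J: int) -> np.ndarray:
    """Exact one-year distribution of a single species' next abundance.

    Returns the ``Binomial(J, a/J)`` probability mass function over
    ``{0, ..., J}`` — the marginal of the community-wide multinomial
    replacement.  Mass at zero is ``(1 - a/J)**J``.
    """
    if not 0 <= a <= J:
        raise ValueError(f"abundance must lie in [0, {J}], got {a}")
    return stats.binom.pmf(np.arange(J + 1), J, a / J)


def transition_matrix(J: int) -> np.ndarray:
    """Dense one-step transition matrix of the marginal chain.

    Row ``a`` is ``Binomial(J, a/J)``; rows 0 and ``J`` are point masses,
    so both barriers are absorbing.  Guarded to modest ``J`` because the
    matrix is dense.
    """
    if J > _MAX_EXACT_J:
        raise ValueError(
            f"exact transition matrix limited to J <= {_MAX_EXACT_J} "
            f"(requested J={J}); use the Monte-Carlo estimator instead"
        )
    support = np.arange(J + 1)
    p = support / J
    return stats.binom.pmf(support[None, :], J, p[:, None])


def exact_extinction_curve(h: int, J: int) -> np.ndarray:
    """P(extinct within ``h`` years | current abundance a) for all a in {0..J}.

    Computed by ``h`` applications of the transition matrix to the
    absorption indicator at zero: ``v_h = P^h e_0``, exploiting that state
    0 is absorbing so "at zero after h steps" equals "hit zero within h".
    """
    if h < 1:
        raise ValueError("horizon must be >= 1")
    P = transition_matrix(J)
    v = np.zeros(J + 1)
    v[0] = 1.0
    for _ in range(h):
        v = P @ v
    return v


def exact_extinction_probability(a: int, h: int, J: int) -> float:
    """Exact P(extinct within ``h`` years) for one starting abundance."""
    if not 0 <= a <= J:
        raise ValueError(f"abundance must lie in [0, {J}], got {a}")
    return float(exact_extinction_curve(h, J)[a])


@dataclass
class ExtinctionRiskCurve:
    """Estimated extinction probability as a function of abundance.

    ``p_raw[h]`` holds trial-weighted Monte-Carlo frequencies on the
    abundance grid ``{0..J}`` (NaN where no trials were observed);
    ``p_smooth[h]`` is the isotonic-smoothed, endpoint-pinned curve defined
    on the whole grid (linear interpolation across unvisited abundances).
    ``n_trials[a]`` counts observation trials at abundance ``a`` (the same
    trials inform every horizon).
    """

    J: int
    horizons: tuple[int, ...]
    n_trials: np.ndarray
    p_raw: dict[int, np.ndarray]
    p_smooth: dict[int, np.ndarray]

    def probability(self, a, horizon: int):
        """Smoothed P(extinct within ``horizon`` | abundance ``a``)."""
        if horizon not in self.p_smooth:
            raise KeyError(f"horizon {horizon} not calibrated; have {self.horizons}")
        a = np.asarray(a)
        if ((a < 0) | (a > self.J)).any():
            raise ValueError(f"abundance must lie in [0, {self.J}]")
        return self.p_smooth[horizon][a]

    def to_frame(self) -> pd.DataFrame:
        """Long table: horizon, abundance, n_trials, p_raw, p_smoothed."""
        frames = []
        grid = np.arange(self.J + 1)
        for h in self.horizons:
            frames.append(
                pd.DataFrame(
                    {
                        "horizon": h,
                        "abundance": grid,
                        "n_trials": self.n_trials,
                        "p_raw": self.p_raw[h],
                        "p_smoothed": self.p_smooth[h],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _simulate_marginal_chains(
    J: int, S: int, n_iterations: int, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Replicate single-species chains, shape (n_iterations, n_steps + 1).

    Initial abundance is ``Binomial(J, 1/S)`` — the marginal of the uniform
    multinomial community initialisation.
    """
    X = np.empty((n_iterations, n_steps + 1), dtype=np.int64)
    X[:, 0] = rng.binomial(J, 1.0 / S, size=n_iterations)
    for t in range(n_steps):
        X[:, t + 1] = rng.binomial(J, X[:, t] / J)
    return X


def _simulate_community_chains(
    config: SimulationConfig, n_iterations: int, n_steps: int
) -> np.ndarray:
    """Full-community replicates flattened to per-species chains."""
    cfg = SimulationConfig(
        J=config.J,
        S=config.S,
        n_years=n_steps,
        start_year=config.start_year,
        n_replicates=n_iterations,
        seed=config.seed,
    )
    rows = [simulate(cfg, r).abundances for r in range(n_iterations)]
    return np.vstack(rows)


def estimate_risk_curves(
    config: SimulationConfig,
    horizons: Iterable[int] = (10, 20, 100),
    n_iterations: int = 10_000,
    mode: str = "marginal",
    visits: str = "all",
) -> ExtinctionRiskCurve:
    """Monte-Carlo extinction probabilities for every abundance increment.

    Runs ``n_iterations`` replicate chains for ``config.n_years +
    max(horizons)`` steps.  Every state visited during the first
    ``config.n_years`` steps (so that every trial has the full longest
    horizon of subsequent dynamics available) contributes one trial per
    horizon: at abundance ``a``, was zero hit within ``h`` further years?
    Frequencies are then isotonic-smoothed per horizon (weights = trial
    counts, exact endpoints pinned) and made monotone across horizons.

    Parameters
    ----------
    config : SimulationConfig
        Supplies ``J``, ``S`` (which sets the initial-abundance
        distribution), the observation window ``n_years``, and the seed.
    horizons : iterable of int
        Extinction horizons in years; default the IUCN criterion horizons.
    n_iterations : int
        Number of replicate chains.
    mode : {"marginal", "community"}
        "marginal" runs the exact single-species binomial marginal chain
        (fast, the default); "community" tracks every species inside full
        multinomial community replicates — statistically identical,
        retained as a cross-check.
    visits : {"all", "first"}
        "all" (default) counts every visit of a chain to an abundance bin
        as a trial — each trial is individually unbiased by the Markov
        property, but overlapping futures make trials within a bin
        correlated.  "first" counts at most one trial per chain per bin
        (its first visit), so trials per bin are independent across chains
        and the raw frequency is exactly binomial — the mode to use when
        comparing against the exact oracle at binomial standard errors.
    """
    horizons = tuple(sorted(int(h) for h in horizons))
    if not horizons:
        raise ValueError("need at least one horizon")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    J = config.J
    n_obs = config.n_years
    n_steps = n_obs + max(horizons)

    if mode == "marginal":
        rng = replicate_rng(config.seed, 0)
        X = _simulate_marginal_chains(J, config.S, n_iterations, n_steps, rng)
    elif mode == "community":
        X = _simulate_community_chains(config, n_iterations, n_steps)
    else:
        raise ValueError(f"mode must be 'marginal' or 'community', got {mode!r}")

    # first hitting time of zero (n_steps + 1 where never absorbed)
    hit = X == 0
    first_zero = np.where(hit.any(axis=1), hit.argmax(axis=1), n_steps + 1)

    if visits not in ("all", "first"):
        raise ValueError(f"visits must be 'all' or 'first', got {visits!r}")
    n_chains = X.shape[0]
    if visits == "first":
        seen = np.zeros((n_chains, J + 1), dtype=bool)
    n_trials = np.zeros(J + 1, dtype=np.int64)
    n_ext = {h: np.zeros(J + 1, dtype=np.int64) for h in horizons}
    rows = np.arange(n_chains)
    for t in range(n_obs + 1):
        a_t = X[:, t]
        if visits == "first":
            fresh = ~seen[rows, a_t]
            seen[rows[fresh], a_t[fresh]] = True
            a_use, fz_use = a_t[fresh], first_zero[fresh]
        else:
            a_use, fz_use = a_t, first_zero
        np.add.at(n_trials, a_use, 1)
        for h in horizons:
            extinct = fz_use <= t + h
            np.add.at(n_ext[h], a_use[extinct], 1)

    observed = n_trials > 0
    span = observed.nonzero()[0]
    unvisited = int(span[-1] - span[0] + 1 - observed.sum()) if span.size else 0
    if unvisited:
        warnings.warn(
            f"{unvisited} abundance bin(s) inside the visited range had no "
            "trials; their estimates are interpolated by the smoother",
            stacklevel=2,
        )

    grid = np.arange(J + 1)
    p_raw: dict[int, np.ndarray] = {}
    p_smooth: dict[int, np.ndarray] = {}
    prev = np.zeros(J + 1)
    for h in horizons:
        with np.errstate(invalid="ignore"):
            raw = np.where(observed, n_ext[h] / np.maximum(n_trials, 1), np.nan)
        raw[0], raw[J] = 1.0, 0.0  # exact absorbing endpoints
        p_raw[h] = raw
        known = ~np.isnan(raw)
        w = n_trials[known].astype(float)
        # pin the exact endpoints with overwhelming weight
        w[0] = w[-1] = max(1.0, n_trials.sum()) * 1e6
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        iso.fit(grid[known], raw[known], sample_weight=w)
        sm = np.clip(iso.predict(grid), 0.0, 1.0)
        sm[0], sm[J] = 1.0, 0.0
        # a longer horizon can never carry less risk
        sm = np.maximum(sm, prev)
        sm[J] = 0.0
        p_smooth[h] = sm
        prev = sm

    return ExtinctionRiskCurve(
        J=J, horizons=horizons, n_trials=n_trials, p_raw=p_raw, p_smooth=p_smooth
    )


@dataclass(frozen=True)
class CategoryThresholds:
    """Abundance cutoffs for CR, EN and VU (inclusive upper bounds)."""

    A_CR: int
    A_EN: int
    A_VU: int

    def __post_init__(self) -> None:
        if not 0 < self.A_CR <= self.A_EN <= self.A_VU:
            raise ValueError(
                f"need 0 < A_CR <= A_EN <= A_VU, got "
                f"({self.A_CR}, {self.A_EN}, {self.A_VU})"
            )

    def as_dict(self) -> dict[str, int]:
        return {"A_CR": self.A_CR, "A_EN": self.A_EN, "A_VU": self.A_VU}


def derive_thresholds(
    curve: ExtinctionRiskCurve,
    criteria: Sequence[RiskCriterion] = DEFAULT_CRITERIA,
) -> CategoryThresholds:
    """Convert smoothed risk curves into abundance cutoffs.

    For each criterion the cutoff is the *largest* abundance whose smoothed
    extinction probability still meets the criterion (``>=`` is inclusive:
    a bin sitting exactly on the criterion probability is classified
    threatened).  Raises on degenerate curves where no positive abundance
    meets a criterion, or where a cutoff would swallow the whole range.
    """
    cuts: dict[str, int] = {}
    for crit in criteria:
        p = curve.p_smooth.get(crit.horizon)
        if p is None:
            raise KeyError(
                f"curve has no horizon {crit.horizon} for category {crit.category}"
            )
        meets = (p >= crit.probability).nonzero()[0]
        a = int(meets.max())
        if a == 0:
            raise ValueError(
                f"degenerate curve: no positive abundance meets the "
                f"{crit.category} criterion"
            )
        if a >= curve.J:
            raise ValueError(
                f"degenerate curve: every abundance meets the "
                f"{crit.category} criterion"
            )
        cuts[crit.category] = a
    return CategoryThresholds(A_CR=cuts["CR"], A_EN=cuts["EN"], A_VU=cuts["VU"])


@dataclass
class ThreatTrajectory:
    """Per-species, per-year threat categories (strings from CATEGORIES)."""

    categories: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        bad = ~np.isin(self.categories, CATEGORIES)
        if bad.any():
            raise ValueError(
                f"unknown categories: {np.unique(self.categories[bad])}"
            )

    @property
    def n_species(self) -> int:
        return self.categories.shape[0]


def classify_trajectory(
    trajectory, thresholds: CategoryThresholds
) -> ThreatTrajectory:
    """Assign a threat category to every species-year.

    EX at abundance 0; CR for 0 < N <= A_CR; EN for A_CR < N <= A_EN; VU
    for A_EN < N <= A_VU; LC above A_VU.  Upper bounds are inclusive, so
    the classification is a total function of (abundance, thresholds).
    """
    if isinstance(trajectory, AbundanceTrajectory):
        N, years = trajectory.abundances, trajectory.years
    else:
        N = np.asarray(trajectory)
        years = np.arange(N.shape[1])
    if (N < 0).any():
        raise ValueError("abundances must be non-negative")
    cats = np.select(
        [N == 0, N <= thresholds.A_CR, N <= thresholds.A_EN, N <= thresholds.A_VU],
        ["EX", "CR", "EN", "VU"],
        default="LC",
    )
    return ThreatTrajectory(categories=cats, years=np.asarray(years))


@dataclass
class RLISeries:
    """Red List Index per year; 1 = all Least Concern, 0 = all Extinct."""

    years: np.ndarray
    rli: np.ndarray

    def __post_init__(self) -> None:
        if ((self.rli < 0) | (self.rli > 1)).any():
            raise ValueError("RLI values must lie in [0, 1]")


def compute_rli(threats: ThreatTrajectory, scheme: str = "standard") -> RLISeries:
    """Red List Index from a threat-category matrix.

    ``RLI_t = 1 - sum_i w(c_{i,t}) / (w_EX * S)`` where ``S`` is the full
    original species count — extinct species stay in the denominator, so
    extinctions permanently depress the index.
    """
    if scheme not in RLI_WEIGHTS:
        raise ValueError(f"scheme must be one of {sorted(RLI_WEIGHTS)}")
    weights = RLI_WEIGHTS[scheme]
    w = np.zeros(threats.categories.shape)
    for cat, wt in weights.items():
        w[threats.categories == cat] = wt
    total = w.sum(axis=0)
    rli = 1.0 - total / (weights["EX"] * threats.n_species)
    return RLISeries(years=threats.years, rli=rli)


def category_proportions(threats: ThreatTrajectory) -> pd.DataFrame:
    """Per-year fraction of species in each category (columns sum to 1)."""
    S = threats.n_species
    data = {
        cat: (threats.categories == cat).sum(axis=0) / S for cat in CATEGORIES
    }
    return pd.DataFrame(data, index=pd.Index(threats.years, name="year"))
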