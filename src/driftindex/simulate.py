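"""Zero-sum neutral drift simulator.

The community holds exactly ``J`` individuals from ``S`` species.  At the
start the individuals are assigned to species uniformly at random (one
multinomial draw with equal probabilities).  Each year the entire community
is replaced: the new abundances are one multinomial draw with ``J`` trials
and per-species probabilities equal to last year's relative abundances
``N_i / J``.  The total is therefore conserved exactly every year, the
expected abundance of each species equals its current abundance (a
martingale), and abundance 0 is absorbing — with no migration or
speciation, a species that drifts to zero never returns, and the community
eventually fixes on a single mono-dominant species.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "AbundanceTrajectory",
    "replicate_rng",
    "init_community",
    "step",
    "simulate",
    "simulate_ensemble",
    "write_trajectories",
    "read_trajectories",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a neutral-drift experiment.

    Parameters
    ----------
    J : int
        Community size — the fixed total number of individuals.
    S : int
        Number of species present at initialisation.
    n_years : int
        Number of annual replacement steps; ``n_years + 1`` community
        states are stored, the first labelled ``start_year``.
    start_year : int
        Calendar label for the initial state.
    n_replicates : int
        Ensemble size for replicate simulations.
    seed : int
        Master seed; replicate ``r`` uses the stream
        ``numpy.random.default_rng([seed, r])``.

    The defaults are a saturated community of 5,000 individuals from 40
    species followed over the 50 years from 1970 to 2020.
    """

    J: int = 5000
    S: int = 40
    n_years: int = 50
    start_year: int = 1970
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1 or self.J < self.S:
            raise ValueError(
                f"need J >= S >= 1, got J={self.J}, S={self.S}"
            )
        if self.n_years < 1:
            raise ValueError(f"n_years must be >= 1, got {self.n_years}")
        if self.n_replicates < 1:
            raise ValueError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )

    @property
    def years(self) -> np.ndarray:
        """Calendar labels for the stored states (length ``n_years + 1``)."""
        return np.arange(self.start_year, self.start_year + self.n_years + 1)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls(**{k: int(v) for k, v in raw.items()})


@dataclass
class AbundanceTrajectory:
    """One simulated community history.

    Attributes
    ----------
    abundances : ndarray of int, shape (S, n_years + 1)
        ``abundances[i, t]`` is species ``i``'s abundance in year
        ``years[t]``.  Every column sums to ``J``.
    years : ndarray of int, shape (n_years + 1,)
        Calendar labels.
    """

    abundances: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances)
        self.years = np.asarray(self.years)
        if self.abundances.ndim != 2:
            raise ValueError("abundances must be a 2-D species x year matrix")
        if self.abundances.shape[1] != self.years.shape[0]:
            raise ValueError("years length must match abundance columns")

    @property
    def n_species(self) -> int:
        return self.abundances.shape[0]

    @property
    def J(self) -> int:
        return int(self.abundances[:, 0].sum())

    def validate(self) -> None:
        """Raise if the zero-sum or absorbing-extinction invariants fail."""
        N = self.abundances
        if (N < 0).any():
            raise ValueError("negative abundance")
        sums = N.sum(axis=0)
        if not (sums == sums[0]).all():
            raise ValueError("column sums vary: zero-sum invariant violated")
        # once extinct, always extinct
        extinct = N == 0
        resurrected = (~extinct[:, 1:]) & extinct[:, :-1]
        if resurrected.any():
            raise ValueError("a species reappeared after extinction")

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        """Long-format table with columns replicate, species_id, year, abundance."""
        S, T = self.abundances.shape
        return pd.DataFrame(
            {
                "replicate": np.full(S * T, replicate),
                "species_id": np.repeat(np.arange(S), T),
                "year": np.tile(self.years, S),
                "abundance": self.abundances.reshape(-1),
            }
        )


def replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    """Deterministic per-replicate random stream.

    The stream is ``default_rng([seed, replicate_index])``, so ensembles can
    be generated in any order (or in parallel) without changing results.
    """
    if replicate_index < 0:
        raise ValueError("replicate_index must be non-negative")
    return np.random.default_rng([int(seed), int(replicate_index)])


def init_community(J: int, S: int, rng: np.random.Generator) -> np.ndarray:
    """Assign ``J`` individuals to ``S`` species uniformly at random.

    Returns one multinomial draw with ``J`` trials and equal per-species
    probability ``1/S``; the result always sums to ``J``.  A species may,
    with tiny probability, receive zero individuals; such a species is
    simply extinct from the start (no rejection or re-draw).
    """
    if S < 1 or J < S:
        raise ValueError(f"need J >= S >= 1, got J={J}, S={S}")
    return rng.multinomial(J, np.full(S, 1.0 / S))


def step(abundances: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One annual zero-sum replacement.

    All ``J`` individuals die and are replaced by a multinomial draw with
    probabilities ``N_i / J``.  Species at zero abundance have zero
    replacement probability, so extinction is absorbing.
    """
    N = np.asarray(abundances)
    if (N < 0).any():
        raise ValueError("abundances must be non-negative")
    J = int(N.sum())
    if J <= 0:
        raise ValueError("community is empty")
    return rng.multinomial(J, N / J)


def simulate(
    config: SimulationConfig, replicate_index: int = 0
) -> AbundanceTrajectory:
    """Run one replicate of the neutral community.

    Fully reproducible from ``(config.seed, replicate_index)``.
    """
    if not 0 <= replicate_index:
        raise ValueError("replicate_index must be non-negative")
    rng = replicate_rng(config.seed, replicate_index)
    N = np.empty((config.S, config.n_years + 1), dtype=np.int64)
    N[:, 0] = init_community(config.J, config.S, rng)
    for t in range(config.n_years):
        N[:, t + 1] = step(N[:, t], rng)
    return AbundanceTrajectory(abundances=N, years=config.years)


def simulate_ensemble(config: SimulationConfig) -> list[AbundanceTrajectory]:
    """Simulate ``config.n_replicates`` independent replicates."""
    return [simulate(config, r) for r in range(config.n_replicates)]


def write_trajectories(
    trajectories: Sequence[AbundanceTrajectory], path: str | Path
) -> None:
    """Write replicates as one long-format CSV.

    Columns: ``replicate, species_id, year, abundance`` — integers
    throughout, so the round trip through :func:`read_trajectories` is
    exact.
    """
    frames = [traj.to_frame(replicate=r) for r, traj in enumerate(trajectories)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[AbundanceTrajectory]:
    """Read trajectories written by :func:`write_trajectories`."""
    df = pd.read_csv(path)
    required = {"replicate", "species_id", "year", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out = []
    for _, grp in df.groupby("replicate", sort=True):
        wide = grp.pivot(index="species_id", columns="year", values="abundance")
        wide = wide.sort_index()
        out.append(
            AbundanceTrajectory(
                abundances=wide.to_numpy(dtype=np.int64),
                years=wide.columns.to_numpy(dtype=np.int64),
            )
        )
    return out
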