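"""Stochastic encapsulation and cultivation: droplets versus bulk.

The mechanism this simulator exists to exhibit is competition release:
when single cells are sealed into picolitre droplets, every founding
lineage grows clonally against its *own* carrying capacity, so a rare,
slow-growing strain still fills its droplet; in a shared bulk culture the
same strain is starved out by fast growers long before it amounts to
anything.

Growth is modelled as logistic with equal competition coefficients:

    dN_i/dt = r_i * N_i * (1 - sum_j N_j / K)

with the sum running over co-occupants of one droplet (K = droplet
capacity) or over the whole vessel (K = bulk capacity).  The model form is
deliberately the simplest one that produces the mechanism; no parameter
here is calibrated to any real organism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .community import StrainCommunity, _child_rng
from .errors import ConfigError, DomainError

#: default incubation horizon (hours) and per-droplet carrying capacity
DEFAULT_HOURS = 120.0
DEFAULT_DROPLET_CAPACITY = 1e4
DEFAULT_BULK_CAPACITY = 1e9
DEFAULT_INOCULUM = 1e6


@dataclass
class DropletEnsemble:
    """Founding cells per droplet, stored compactly.

    ``occupancy[i]`` is the number of founding cells in droplet ``i``;
    ``founders`` concatenates the strain indices of all founding cells in
    droplet order (use ``offsets`` to slice), indexing into ``strain_ids``.
    """

    strain_ids: list[str]
    occupancy: np.ndarray
    founders: np.ndarray

    def __post_init__(self) -> None:
        if self.occupancy.sum() != len(self.founders):
            raise ConfigError("occupancy summary inconsistent with founders")

    @property
    def n_droplets(self) -> int:
        return len(self.occupancy)

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.occupancy)])

    def occupancy_summary(self) -> dict[str, int]:
        occ = self.occupancy
        return {
            "empty": int((occ == 0).sum()),
            "single": int((occ == 1).sum()),
            "multiple": int((occ >= 2).sum()),
        }

    def founder_counts(self) -> np.ndarray:
        """Total founding cells per strain, in ``strain_ids`` order."""
        return np.bincount(self.founders, minlength=len(self.strain_ids))


@dataclass
class CultureOutcome:
    """Final cell count per strain after cultivation in one medium."""

    counts: pd.Series  # index strain_id
    medium: str
    hours: float
    mode: str  # "droplet" | "bulk" | "none"

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ConfigError("cell counts must be >= 0")

    def composition(self) -> pd.Series:
        """Relative abundances of strains in the pooled culture."""
        total = self.counts.sum()
        if total == 0:
            return self.counts * 0.0
        return self.counts / total


def encapsulate(
    community: StrainCommunity,
    n_droplets: int,
    lam: float,
    seed: int = 0,
) -> DropletEnsemble:
    """Load a community into droplets at Poisson occupancy ``lam``.

    Per-droplet founding counts are Poisson(lam); founder identities are
    drawn i.i.d. from the community's strain abundances.
    """
    if n_droplets < 1:
        raise DomainError("need at least one droplet")
    if lam < 0:
        raise DomainError("lambda must be >= 0")
    rng = _child_rng(seed, 3)
    occupancy = rng.poisson(lam, size=n_droplets)
    total = int(occupancy.sum())
    founders = rng.choice(
        len(community.strain_ids), size=total, p=community.abundances
    )
    return DropletEnsemble(
        strain_ids=community.strain_ids, occupancy=occupancy, founders=founders
    )


def _logistic_single(n0: float, rate: float, hours: float, capacity: float) -> float:
    """Closed-form single-lineage logistic growth from n0 cells."""
    if rate == 0.0 or hours == 0.0 or n0 == 0.0:
        return n0
    # N(t) = K / (1 + ((K - N0)/N0) e^{-rt}), monotone to K
    e = np.exp(-rate * hours)
    return capacity / (1.0 + (capacity - n0) / n0 * e)

def _grow_group(
    n0: np.ndarray, rates: np.ndarray, hours: float, capacity: float
) -> np.ndarray:
    """Multi-lineage shared-capacity logistic growth (numerical)."""
    if hours == 0.0 or not (rates > 0).any():
        return n0.astype(float)
    if len(n0) == 1 or len(set(rates[n0 > 0])) == 1:
        # equal rates: total follows one logistic, composition is frozen
        r = float(rates.max())
        if r == 0.0:
            return n0.astype(float)
        tot = _logistic_single(float(n0.sum()), r, hours, capacity)
        return n0 * (tot / n0.sum())

    def rhs(_t: float, n: np.ndarray) -> np.ndarray:
        return rates * n * (1.0 - n.sum() / capacity)

    sol = solve_ivp(
        rhs, (0.0, hours), n0.astype(float), method="LSODA",
        rtol=1e-8, atol=1e-6,
    )
    return np.clip(sol.y[:, -1], 0.0, None)


def grow_droplets(
    ensemble: DropletEnsemble,
    community: StrainCommunity,
    medium: str,
    hours: float = DEFAULT_HOURS,
    droplet_capacity: float = DEFAULT_DROPLET_CAPACITY,
) -> CultureOutcome:
    """Grow every droplet independently and pool the final counts.

    Within one droplet each founding lineage grows at its medium-specific
    rate against the droplet's shared capacity; lineages in different
    droplets never interact.  Droplets with identical founder multisets
    are solved once and multiplied by their multiplicity.
    """
    if hours < 0:
        raise DomainError("hours must be >= 0")
    if droplet_capacity < 1:
        raise DomainError("droplet_capacity must be >= 1")
    rates = community.rates_for(medium)  # ConfigError on unknown medium

    pooled = np.zeros(len(ensemble.strain_ids))
    offsets = ensemble.offsets
    groups: dict[tuple[int, ...], int] = {}
    for i in np.nonzero(ensemble.occupancy)[0]:
        key = tuple(sorted(ensemble.founders[offsets[i] : offsets[i + 1]]))
        groups[key] = groups.get(key, 0) + 1

    for key, mult in groups.items():
        idx, n0 = np.unique(key, return_counts=True)
        final = _grow_group(n0.astype(float), rates[idx], hours, droplet_capacity)
        pooled[idx] += mult * final

    counts = pd.Series(pooled, index=ensemble.strain_ids, name="count")
    return CultureOutcome(counts=counts, medium=medium, hours=hours, mode="droplet")


def grow_bulk(
    community: StrainCommunity,
    medium: str,
    hours: float = DEFAULT_HOURS,
    bulk_capacity: float = DEFAULT_BULK_CAPACITY,
    inoculum_size: float = DEFAULT_INOCULUM,
) -> CultureOutcome:
    """Grow the whole community in one shared vessel.

    All lineages compete for a single capacity (Lotka-Volterra with equal
    competition coefficients), so fast growers dominate the final
    composition.  The inoculum is the expected composition
    ``inoculum_size * abundance`` (deterministic).
    """
    if hours < 0:
        raise DomainError("hours must be >= 0")
    if bulk_capacity < 1 or inoculum_size <= 0:
        raise DomainError("bulk_capacity and inoculum_size must be positive")
    rates = community.rates_for(medium)
    n0 = inoculum_size * community.abundances
    final = _grow_group(n0, rates, hours, bulk_capacity)
    counts = pd.Series(final, index=community.strain_ids, name="count")
    return CultureOutcome(counts=counts, medium=medium, hours=hours, mode="bulk")


def uncultured_outcome(
    community: StrainCommunity, inoculum_size: float = DEFAULT_INOCULUM
) -> CultureOutcome:
    """The pre-culture ("gut") sample: the community itself, unsampled."""
    counts = pd.Series(
        inoculum_size * community.abundances, index=community.strain_ids, name="count"
    )
    return CultureOutcome(counts=counts, medium="none", hours=0.0, mode="none")
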