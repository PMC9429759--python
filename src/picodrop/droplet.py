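"""Poisson single-cell droplet loading design.

When a dilute cell suspension is partitioned into monodisperse droplets,
the number of cells per droplet follows a Poisson distribution whose mean
is the loading parameter ``lambda = rho * V`` — the product of the cell
density ``rho`` (CFU/mL) and the droplet volume ``V``.  This module turns
that relationship into a small design calculator: occupancy probabilities,
expected droplet counts per occupancy class, and the suspension density
required to hit a target lambda.

Unit conventions are fixed package-wide: diameters in micrometres,
volumes in picolitres, densities in CFU per millilitre.  1000 um^3 = 1 pL
and 1 mL = 1e9 pL; the conversions are explicit constants below, never
inferred from magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import DomainError

#: picolitres per cubic micrometre
PL_PER_UM3 = 1e-3
#: millilitres per picolitre
ML_PER_PL = 1e-9
#: picolitres per millilitre
PL_PER_ML = 1e9


def droplet_volume(diameter_um: float) -> float:
    """Volume in pL of a spherical droplet of the given diameter in um.

    A 30 um droplet holds (pi/6)*30^3 um^3 ~= 14.14 pL.
    """
    if not diameter_um > 0:
        raise DomainError(f"droplet diameter must be positive, got {diameter_um}")
    return (math.pi / 6.0) * diameter_um**3 * PL_PER_UM3


def loading_lambda(cell_density: float, volume_pl: float) -> float:
    """Expected cells per droplet, lambda = rho * V.

    ``cell_density`` is in CFU/mL, ``volume_pl`` in pL.
    """
    if cell_density < 0:
        raise DomainError(f"cell density must be >= 0, got {cell_density}")
    if not volume_pl > 0:
        raise DomainError(f"droplet volume must be positive, got {volume_pl}")
    return cell_density * volume_pl * ML_PER_PL  # CFU/mL * pL * (mL/pL)


def required_density(lam: float, volume_pl: float) -> float:
    """Cell density (CFU/mL) that realises loading parameter ``lam`` at the
    given droplet volume; the exact inverse of :func:`loading_lambda`."""
    if not lam > 0:
        raise DomainError(f"target lambda must be positive, got {lam}")
    if not volume_pl > 0:
        raise DomainError(f"droplet volume must be positive, got {volume_pl}")
    return lam / (volume_pl * ML_PER_PL)


def occupancy_pmf(lam: float, n: int) -> float:
    """P(X = n) for X ~ Poisson(lam), computed in log space so that large
    ``n`` cannot overflow the factorial."""
    if lam < 0:
        raise DomainError(f"lambda must be >= 0, got {lam}")
    if n < 0:
        raise DomainError(f"occupancy must be >= 0, got {n}")
    if lam == 0:
        return 1.0 if n == 0 else 0.0
    return float(math.exp(-lam + n * math.log(lam) - gammaln(n + 1)))


def prob_at_least(lam: float, k: int) -> float:
    """P(X >= k) for X ~ Poisson(lam)."""
    if lam < 0:
        raise DomainError(f"lambda must be >= 0, got {lam}")
    if k < 0:
        raise DomainError(f"occupancy must be >= 0, got {k}")
    return 1.0 - sum(occupancy_pmf(lam, n) for n in range(k))


def expected_counts(n_droplets: float, lam: float) -> tuple[float, float, float]:
    """Expected numbers of (empty, singly-occupied, multiply-occupied)
    droplets among ``n_droplets`` at loading parameter ``lam``.

    The three expectations sum to ``n_droplets`` exactly.
    """
    if n_droplets < 0:
        raise DomainError(f"droplet count must be >= 0, got {n_droplets}")
    p0 = occupancy_pmf(lam, 0)
    p1 = occupancy_pmf(lam, 1)
    empty = n_droplets * p0
    single = n_droplets * p1
    multi = n_droplets - empty - single
    return empty, single, multi


@dataclass(frozen=True)
class DropletSpec:
    """A droplet geometry: diameter in um and the implied volume in pL."""

    diameter_um: float
    volume_pl: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = droplet_volume(self.diameter_um)
        if self.volume_pl is None:
            object.__setattr__(self, "volume_pl", v)
        elif not math.isclose(self.volume_pl, v, rel_tol=1e-9):
            raise DomainError(
                f"volume {self.volume_pl} pL inconsistent with diameter "
                f"{self.diameter_um} um (expected {v:.6g} pL)"
            )


@dataclass(frozen=True)
class LoadingModel:
    """Cell density rho (CFU/mL), droplet volume V (pL), and lambda = rho*V."""

    cell_density: float
    droplet_volume: float
    lam: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lam = loading_lambda(self.cell_density, self.droplet_volume)
        if self.lam is None:
            object.__setattr__(self, "lam", lam)
        elif not math.isclose(self.lam, lam, rel_tol=1e-9):
            raise DomainError(
                f"lambda {self.lam} inconsistent with rho*V = {lam:.6g}"
            )

    def occupancy(self, n_max: int | None = None) -> "OccupancyDistribution":
        if n_max is None:
            n_max = math.ceil(self.lam) + 40
        probs = np.array([occupancy_pmf(self.lam, n) for n in range(n_max + 1)])
        return OccupancyDistribution(lam=self.lam, probs=probs)


@dataclass(frozen=True)
class OccupancyDistribution:
    """Poisson occupancy probabilities for n = 0..n_max cells per droplet."""

    lam: float
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise DomainError("occupancy probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", p)


def design_report(
    diameter_um: float,
    cell_density: float | None = None,
    target_lambda: float | None = None,
) -> dict[str, float]:
    """One-row loading design summary.

    Exactly one of ``cell_density`` or ``target_lambda`` must be given:
    from a density the realised lambda is derived; from a target lambda
    the required density is derived.
    """
    if (cell_density is None) == (target_lambda is None):
        raise DomainError("give exactly one of cell_density or target_lambda")
    volume = droplet_volume(diameter_um)
    if cell_density is not None:
        lam = loading_lambda(cell_density, volume)
        density = cell_density
    else:
        lam = float(target_lambda)  # type: ignore[arg-type]
        density = required_density(lam, volume)
    return {
        "diameter_um": diameter_um,
        "volume_pL": volume,
        "lambda": lam,
        "p_empty": occupancy_pmf(lam, 0),
        "p_single": occupancy_pmf(lam, 1),
        "p_multi": prob_at_least(lam, 2),
        "required_density_cfu_per_ml": density,
    }
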