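"""Turnover times, per-area flux scaling and seasonal-change summaries.

Turnover time of a plant-available N pool is the pool size divided by its
mean throughput — the average of production and consumption rate for the
inorganic pools, and the production rate alone for amino acids (whose
consumption is not measured by the slurry assay).

Per-area fluxes scale a gravimetric rate by the soil mass of the organic
horizon under 1 m²: bulk density × horizon depth × 10⁴ cm² m⁻², assuming
the whole horizon cycles N at the core's measured rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SiteProperties

PRODUCTION_ONLY = "production_only"
MEAN_PROD_CONS = "mean_prod_cons"


@dataclass(frozen=True)
class TurnoverResult:
    """Residence time of N in one pool of one sample."""

    sample_id: str
    pool: str  # 'amino_acids' | 'ammonium' | 'nitrate'
    turnover_h: float | None
    method: str
    qc_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AreaFlux:
    """A gravimetric rate expressed per ground area of the organic horizon."""

    species: str
    flux_gN_m2_day: float
    source_rate_ugN_gDW_day: float
    bulk_density_g_cm3: float
    horizon_depth_cm: float


def turnover_time(
    pool_size: float,
    production: float,
    consumption: float | None,
    pool: str,
    sample_id: str = "",
) -> TurnoverResult:
    """Pool size over mean throughput, hours.

    Inorganic pools use ``pool / mean(production, consumption)``; amino
    acids always use production only.  A flagged-negative consumption
    falls back to production only (flag ``CONSUMPTION_FALLBACK``); a
    non-positive denominator yields a missing value with
    ``NONPOSITIVE_RATE``.
    """
    if pool not in ("amino_acids", "ammonium", "nitrate"):
        raise ValueError(f"unknown pool {pool!r}")
    flags: set[str] = set()
    if pool == "amino_acids":
        method = PRODUCTION_ONLY
        denom = production
    elif consumption is None or consumption < 0:
        method = PRODUCTION_ONLY
        denom = production
        flags.add("CONSUMPTION_FALLBACK")
    else:
        method = MEAN_PROD_CONS
        denom = (production + consumption) / 2.0
    if production is None or denom is None or denom <= 0:
        flags.add("NONPOSITIVE_RATE")
        return TurnoverResult(sample_id, pool, None, method, frozenset(flags))
    return TurnoverResult(sample_id, pool, pool_size / denom, method, frozenset(flags))


def scale_to_area(rate_ugN_gDW_day: float, props: SiteProperties) -> AreaFlux:
    """Scale a per-g-DW daily rate to g N m⁻² day⁻¹ for one site type.

    ``flux = rate × 1e−6 g/µg × BD g cm⁻³ × depth cm × 1e4 cm² m⁻²``.
    """
    if props.bulk_density_g_cm3 <= 0 or props.horizon_depth_cm <= 0:
        raise ValueError("bulk density and horizon depth must be positive")
    if rate_ugN_gDW_day < 0:
        raise ValueError("rate must be nonnegative")
    flux = (
        rate_ugN_gDW_day
        * 1e-6
        * props.bulk_density_g_cm3
        * props.horizon_depth_cm
        * 1e4
    )
    return AreaFlux(
        species=props.species,
        flux_gN_m2_day=flux,
        source_rate_ugN_gDW_day=rate_ugN_gDW_day,
        bulk_density_g_cm3=props.bulk_density_g_cm3,
        horizon_depth_cm=props.horizon_depth_cm,
    )


def seasonal_change(
    data: pd.DataFrame,
    value: str,
    group: str = "species",
    season: str = "season",
) -> pd.DataFrame:
    """Percent change of group means from early to late growing season.

    Returns one row per group with the early and late means, the percent
    drop ``100·(early − late)/early`` and the late season as a percentage
    of the early season.  Means are on the untransformed scale.
    """
    out = []
    for g, sub in data.groupby(group, observed=True):
        seasons = set(sub[season])
        if not {"early", "late"} <= seasons:
            raise ValueError(f"group {g!r} lacks one of the two seasons")
        early = sub.loc[sub[season] == "early", value].mean()
        late = sub.loc[sub[season] == "late", value].mean()
        if not np.isfinite(early) or early <= 0:
            raise ValueError(f"early-season mean of {g!r} must be positive")
        out.append(
            {
                group: g,
                "mean_early": early,
                "mean_late": late,
                "pct_drop": 100.0 * (early - late) / early,
                "late_pct_of_early": 100.0 * late / early,
            }
        )
    return pd.DataFrame(out)


__all__ = [
    "PRODUCTION_ONLY", "MEAN_PROD_CONS", "TurnoverResult", "AreaFlux",
    "turnover_time", "scale_to_area", "seasonal_change",
]
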