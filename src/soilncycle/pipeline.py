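"""End-to-end estimation: raw assay tables → pools, rates, turnover, stats.

Thin orchestration over the assay-chemistry, pool-dilution and
derived-metrics modules.  Consumes a :class:`~soilncycle.synthetic_data.StudyBundle`
(or the equivalent CSV directory) and produces tidy result frames keyed by
sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assay_chemistry as chem
from . import derived_metrics as dm
from . import pool_dilution as pdil
from .core_io import AnalysisConfig, SPECIES_PFT


def fit_standard_curves(
    standards: pd.DataFrame,
) -> tuple[chem.StandardCurve, chem.StandardCurve]:
    """Leucine and ammonium standard curves from the standards table."""
    curves = {}
    for analyte, sub in standards.groupby("analyte"):
        curves[analyte] = chem.fit_standard_curve(
            sub["conc_uM"], sub["fluorescence"], analyte
        )
    for need in ("leucine", "ammonium"):
        if need not in curves:
            raise ValueError(f"standards table lacks {need} rows")
    return curves["leucine"], curves["ammonium"]


def estimate_pools(bundle, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Plant-available N pools per sample, µg N g⁻¹ DW.

    Amino acids from corrected OPAME fluorescence (leucine equivalents,
    1 N per leucine); ammonium and nitrate from the extract concentration
    table; all scaled to the soil-DW basis through the 1:10 extraction.
    """
    leu, nh4_curve = fit_standard_curves(bundle.standards)
    moisture = dict(zip(bundle.samples.sample_id, bundle.samples.moisture_frac))
    ratio = 10.0

    reads = bundle.plate_reads.groupby("sample_id", as_index=False).agg(
        raw_fluorescence=("raw_fluorescence", "mean"),
        background_fluorescence=("background_fluorescence", "mean"),
        nh4_conc_uM=("nh4_conc_uM", "mean"),
    )
    rows = []
    for r in reads.itertuples(index=False):
        aa_uM, floored = chem.amino_acid_concentration(
            chem.FluorometryRead(
                r.sample_id, r.raw_fluorescence, r.background_fluorescence, r.nh4_conc_uM
            ),
            leu,
            nh4_curve,
        )
        aa_soil = chem.extract_to_soil_basis(
            chem.uM_to_ugN_per_mL(aa_uM), ratio, moisture[r.sample_id]
        )
        rows.append(
            {"sample_id": r.sample_id, "amino_acids": aa_soil, "aa_floored": floored}
        )
    aa = pd.DataFrame(rows)

    ext_rows = []
    for r in bundle.extracts.itertuples(index=False):
        m = moisture[r.sample_id]
        ext_rows.append(
            {
                "sample_id": r.sample_id,
                "ammonium": chem.extract_to_soil_basis(r.nh4_ugN_per_mL, ratio, m),
                "nitrate": chem.extract_to_soil_basis(r.no3_ugN_per_mL, ratio, m),
            }
        )
    pools = aa.merge(pd.DataFrame(ext_rows), on="sample_id")
    return pools


def estimate_depolymerisation(bundle) -> pd.DataFrame:
    """Protein depolymerisation rate per sample from the slurry time courses."""
    moisture = dict(zip(bundle.samples.sample_id, bundle.samples.moisture_frac))
    rows = []
    for sid, sub in bundle.slurry.groupby("sample_id"):
        sub = sub.sort_values("time_h")
        tc = chem.SlurryTimecourse(
            sample_id=sid,
            times_h=tuple(sub["time_h"]),
            aa_conc_slurry_ugN_per_mL=tuple(sub["conc_ugN_per_mL"]),
        )
        rate, negative = chem.depolymerisation_rate(tc, moisture[sid])
        rows.append(
            {"sample_id": sid, "depolymerisation": rate, "depoly_negative": negative}
        )
    return pd.DataFrame(rows)


def estimate_gross_rates(bundle, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Gross production, net rate and consumption per sample × pool.

    Duplicate assay subsamples are averaged at the observation level
    (pool sizes and atom % per timepoint) before estimation.
    """
    cfg = config or AnalysisConfig()
    rows = []
    for (sid, pool), sub in bundle.irms.groupby(["sample_id", "pool"]):
        by_tp = sub.groupby("timepoint_h").agg(
            A=("pool_ugN_per_gDW", "mean"), atom=("atom_pct_15N", "mean")
        )
        tps = sorted(by_tp.index)
        if len(tps) != 2 or tps[0] != 0.0:
            raise ValueError(f"{sid}/{pool}: expected timepoints 0 and t")
        t = tps[1]
        obs = pdil.IsotopeAssayObservation(
            sample_id=sid,
            pool=pool,
            A0=float(by_tp.loc[tps[0], "A"]),
            At=float(by_tp.loc[tps[1], "A"]),
            atom_pct_0=float(by_tp.loc[tps[0], "atom"]),
            atom_pct_t=float(by_tp.loc[tps[1], "atom"]),
            background_atom_pct=cfg.background_atom_pct,
            t=t,
        )
        res = pdil.gross_rates(obs)
        rows.append(
            {
                "sample_id": sid,
                "pool": pool,
                "gross_production": res.gross_production,
                "net_rate": res.net_rate,
                "gross_consumption": res.gross_consumption,
                "flags": ";".join(sorted(res.qc_flags)),
            }
        )
    return pd.DataFrame(rows)


def compute_turnover(
    pools: pd.DataFrame, rates: pd.DataFrame, depoly: pd.DataFrame
) -> pd.DataFrame:
    """Turnover times (h) of the three plant-available N pools per sample."""
    wide = rates.pivot(index="sample_id", columns="pool")
    merged = pools.merge(depoly, on="sample_id").set_index("sample_id")
    rows = []
    for sid, r in merged.iterrows():
        specs = [
            ("amino_acids", r["amino_acids"], r["depolymerisation"], None),
            (
                "ammonium",
                r["ammonium"],
                wide.loc[sid, ("gross_production", "ammonium")],
                wide.loc[sid, ("gross_consumption", "ammonium")],
            ),
            (
                "nitrate",
                r["nitrate"],
                wide.loc[sid, ("gross_production", "nitrate")],
                wide.loc[sid, ("gross_consumption", "nitrate")],
            ),
        ]
        for pool, size, prod, cons in specs:
            if prod is None or (isinstance(prod, float) and np.isnan(prod)):
                rows.append(
                    {"sample_id": sid, "pool": pool, "turnover_h": np.nan,
                     "method": dm.MEAN_PROD_CONS, "flags": "MISSING_PRODUCTION"}
                )
                continue
            cons_val = None if cons is None or np.isnan(cons) else float(cons)
            res = dm.turnover_time(float(size), float(prod), cons_val, pool, sid)
            rows.append(
                {
                    "sample_id": sid,
                    "pool": pool,
                    "turnover_h": np.nan if res.turnover_h is None else res.turnover_h,
                    "method": res.method,
                    "flags": ";".join(sorted(res.qc_flags)),
                }
            )
    return pd.DataFrame(rows)


def run_study_analysis(bundle, config: AnalysisConfig | None = None) -> dict:
    """Full estimation pass over one study bundle.

    Returns a dict of tidy frames: ``pools``, ``depoly``, ``rates``,
    ``turnover`` and a wide per-sample ``responses`` table (design columns
    plus every response analysed by the mixed models).
    """
    cfg = config or AnalysisConfig()
    pools = estimate_pools(bundle, cfg)
    depoly = estimate_depolymerisation(bundle)
    rates = estimate_gross_rates(bundle, cfg)
    turnover = compute_turnover(pools, rates, depoly)

    wide_rates = rates.pivot(index="sample_id", columns="pool")
    resp = bundle.samples[
        ["sample_id", "block", "species", "season", "location_id"]
    ].copy()
    resp["pft"] = resp["species"].map(SPECIES_PFT)
    resp = resp.merge(pools.drop(columns=["aa_floored"]), on="sample_id")
    resp = resp.merge(depoly.drop(columns=["depoly_negative"]), on="sample_id")

    def _col(stat: str, pool: str) -> pd.Series:
        return wide_rates[(stat, pool)]

    rate_cols = pd.DataFrame(
        {
            "gross_min": _col("gross_production", "ammonium"),
            "net_min": _col("net_rate", "ammonium"),
            "nh4_consumption": _col("gross_consumption", "ammonium"),
            "gross_nitrification": _col("gross_production", "nitrate"),
            "net_nitrification": _col("net_rate", "nitrate"),
            "no3_consumption": _col("gross_consumption", "nitrate"),
        }
    ).reset_index()
    resp = resp.merge(rate_cols, on="sample_id")

    wide_turn = turnover.pivot(index="sample_id", columns="pool", values="turnover_h")
    wide_turn = wide_turn.rename(
        columns={p: f"turnover_{p}" for p in wide_turn.columns}
    ).reset_index()
    resp = resp.merge(wide_turn, on="sample_id")

    return {
        "pools": pools,
        "depoly": depoly,
        "rates": rates,
        "turnover": turnover,
        "responses": resp,
    }


def area_flux_by_pft(
    responses: pd.DataFrame,
    site_properties: pd.DataFrame,
    rate_col: str = "depolymerisation",
) -> pd.DataFrame:
    """Per-area daily flux of a gravimetric rate, averaged within PFT.

    The hourly rate is converted to per-day, scaled per species by its
    bulk density and organic-horizon depth, then averaged over the shrub
    and moss species respectively.
    """
    from .core_io import SiteProperties

    per_species = (
        responses.groupby("species", observed=True)[rate_col].mean().reset_index()
    )
    props = {
        r.species: SiteProperties(
            species=r.species,
            c_pct=r.c_pct,
            n_pct=r.n_pct,
            cn_ratio=r.cn_ratio,
            moisture_pct_fw=r.moisture_pct_fw,
            ph=r.ph,
            bulk_density_g_cm3=r.bulk_density_g_cm3,
            horizon_depth_cm=r.horizon_depth_cm,
        )
        for r in site_properties.itertuples(index=False)
    }
    rows = []
    for r in per_species.itertuples(index=False):
        flux = dm.scale_to_area(float(r[1]) * 24.0, props[r.species])
        rows.append(
            {
                "species": r.species,
                "pft": SPECIES_PFT[r.species],
                "rate_ugN_gDW_day": flux.source_rate_ugN_gDW_day,
                "flux_gN_m2_day": flux.flux_gN_m2_day,
            }
        )
    per_species_flux = pd.DataFrame(rows)
    per_pft = (
        per_species_flux.groupby("pft", observed=True)["flux_gN_m2_day"]
        .mean()
        .reset_index()
    )
    return per_species_flux, per_pft


__all__ = [
    "fit_standard_curves", "estimate_pools", "estimate_depolymerisation",
    "estimate_gross_rates", "compute_turnover", "run_study_analysis",
    "area_flux_by_pft",
]
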