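"""Domain types, tabular I/O and configuration for the tundra N-cycling pipeline.

The study design is a subarctic tundra heath sampled in five replicate
blocks under six plant species — three dwarf shrubs (*Empetrum
hermaphroditum*, *Arctostaphylos alpinus*, *Betula nana*) and three mosses
(*Hylocomium splendens*, *Aulacomnium turgidum*, *Tomentypnum nitens*) —
in early and late growing season.  The late-season core of each sampling
location was taken next to the early-season core, so the two seasonal
samples of one spot share a ``location_id`` (the repeated-measures unit of
the mixed models).

All tabular I/O is plain CSV (UTF-8, decimal point).  Internal rate unit
is µg N g⁻¹ DW h⁻¹; the reporting layer converts to per-day on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger("soilncycle")

#: Fixed species → plant-functional-type map (3 dwarf shrubs, 3 mosses).
SPECIES_PFT: Mapping[str, str] = {
    "E. hermaphroditum": "shrub",
    "A. alpinus": "shrub",
    "B. nana": "shrub",
    "H. splendens": "moss",
    "A. turgidum": "moss",
    "T. nitens": "moss",
}

SHRUB_SPECIES = tuple(s for s, p in SPECIES_PFT.items() if p == "shrub")
MOSS_SPECIES = tuple(s for s, p in SPECIES_PFT.items() if p == "moss")
SEASONS = ("early", "late")

#: Mass of one µmol of nitrogen, µg (one N atom per leucine assumed for
#: µM leucine-equivalents → µg N conversions).
UG_N_PER_UMOL = 14.0067


class SchemaError(ValueError):
    """A table does not match its documented CSV schema."""


@dataclass(frozen=True)
class SoilSample:
    """One bulked soil core with its design factors and physical properties."""

    sample_id: str
    block: int
    species: str
    season: str
    location_id: str
    fresh_weight_g: float
    moisture_frac: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES_PFT:
            raise SchemaError(f"unmapped species {self.species!r}")
        if self.season not in SEASONS:
            raise SchemaError(f"unknown season {self.season!r}")
        if not 0.0 < self.moisture_frac < 1.0:
            raise SchemaError(
                f"moisture_frac must be in (0,1), got {self.moisture_frac}"
            )
        if self.fresh_weight_g <= 0:
            raise SchemaError("fresh_weight_g must be positive")

    @property
    def pft(self) -> str:
        """Plant functional type, derived from the fixed species map."""
        return SPECIES_PFT[self.species]

    @property
    def dry_weight_g(self) -> float:
        return fresh_to_dry(self.fresh_weight_g, self.moisture_frac)


@dataclass(frozen=True)
class SiteProperties:
    """Per-species soil characteristics of the organic horizon.

    Means over both samplings (n = 5 blocks); standard errors travel in the
    CSV but are only used by the synthetic generator.
    """

    species: str
    c_pct: float
    n_pct: float
    cn_ratio: float
    moisture_pct_fw: float
    ph: float
    bulk_density_g_cm3: float
    horizon_depth_cm: float

    def __post_init__(self) -> None:
        for name in (
            "c_pct", "n_pct", "cn_ratio", "moisture_pct_fw",
            "ph", "bulk_density_g_cm3", "horizon_depth_cm",
        ):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be strictly positive")
        # printed C:N is rounded; allow 10% slack
        implied = self.c_pct / self.n_pct
        if abs(implied - self.cn_ratio) > 0.1 * implied:
            raise SchemaError(
                f"cn_ratio {self.cn_ratio} inconsistent with C%/N% = {implied:.1f}"
            )


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the estimation pipeline.

    t_hours
        Pool-dilution incubation interval between the two extractions.
        The 4 h extraction is timepoint 0 of the assay and the 24 h
        extraction is time t, hence 20 h.
    background_atom_pct
        Atom % ¹⁵N of unlabelled soil N.  Natural abundance 0.3663 atom %
        by default; configurable because IRMS background runs may differ.
    transform_map
        Response name → 'none' | 'sqrt' | 'log' for the ANOVA layer.
    interaction_threshold
        p-value below which season × species interactions switch post-hoc
        contrasts to within-stratum conditioning.
    """

    t_hours: float = 20.0
    background_atom_pct: float = 0.3663
    transform_map: Mapping[str, str] = field(default_factory=dict)
    interaction_threshold: float = 0.05
    seed: int = 0
    per_day: bool = False

    def __post_init__(self) -> None:
        if self.t_hours <= 0:
            raise ValueError("t_hours must be positive")
        if not 0.0 < self.background_atom_pct < 1.0:
            raise ValueError("background_atom_pct must be in (0, 1) atom %")
        if not 0.0 < self.interaction_threshold < 1.0:
            raise ValueError("interaction_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "t_hours": self.t_hours,
            "background_atom_pct": self.background_atom_pct,
            "transform_map": dict(self.transform_map),
            "interaction_threshold": self.interaction_threshold,
            "seed": self.seed,
            "per_day": self.per_day,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


#: Response → variance-stabilising transform, as used for the field data.
DEFAULT_TRANSFORMS: Mapping[str, str] = {
    "amino_acids": "log",
    "ammonium": "log",
    "nitrate": "sqrt",
    "depolymerisation": "log",
    "gross_min": "sqrt",
    "net_min": "none",
    "nh4_consumption": "sqrt",
    "gross_nitrification": "sqrt",
    "net_nitrification": "none",
    "no3_consumption": "sqrt",
    "turnover_amino_acids": "sqrt",
    "turnover_ammonium": "log",
    "turnover_nitrate": "log",
}


def fresh_to_dry(fresh_weight_g: float, moisture_frac: float) -> float:
    """Convert fresh weight to dry weight given gravimetric moisture.

    ``DW = FW × (1 − moisture_frac)`` with moisture as a fraction of fresh
    weight (Table-1 convention: soil moisture in % of FW).
    """
    if not 0.0 <= moisture_frac < 1.0:
        raise ValueError(f"moisture_frac must be in [0,1), got {moisture_frac}")
    if fresh_weight_g < 0:
        raise ValueError("fresh weight must be nonnegative")
    return fresh_weight_g * (1.0 - moisture_frac)


_SAMPLE_COLUMNS = (
    "sample_id", "block", "species", "season",
    "location_id", "fresh_weight_g", "moisture_frac",
)


def read_sample_table(path: str | Path) -> list[SoilSample]:
    """Read samples.csv into validated :class:`SoilSample` records."""
    df = pd.read_csv(path)
    missing = set(_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"samples table missing columns: {sorted(missing)}")
    samples = [
        SoilSample(
            sample_id=str(row.sample_id),
            block=int(row.block),
            species=str(row.species),
            season=str(row.season),
            location_id=str(row.location_id),
            fresh_weight_g=float(row.fresh_weight_g),
            moisture_frac=float(row.moisture_frac),
        )
        for row in df.itertuples(index=False)
    ]
    counts = pd.Series([s.location_id for s in samples]).value_counts()
    if (counts > len(SEASONS)).any():
        bad = counts[counts > len(SEASONS)].index.tolist()
        raise SchemaError(f"location_id appears in more than 2 seasons: {bad}")
    logger.info("read %d samples from %s", len(samples), path)
    return samples


def write_sample_table(samples: Iterable[SoilSample], path: str | Path) -> None:
    df = samples_to_frame(samples)
    df.to_csv(path, index=False)


def samples_to_frame(samples: Iterable[SoilSample]) -> pd.DataFrame:
    """Tidy frame of the design, with derived pft and dry weight."""
    rows = [
        {
            "sample_id": s.sample_id,
            "block": s.block,
            "species": s.species,
            "season": s.season,
            "location_id": s.location_id,
            "fresh_weight_g": s.fresh_weight_g,
            "moisture_frac": s.moisture_frac,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=list(_SAMPLE_COLUMNS))


def read_site_properties(path: str | Path | None = None) -> list[SiteProperties]:
    """Read the per-species site-property table.

    With no argument the packaged table of the study site (means and SEs
    over both samplings, n = 5) is returned.
    """
    if path is None:
        path = resources.files("soilncycle.data") / "site_properties.csv"
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if df["species"].duplicated().any():
        dupes = df.loc[df["species"].duplicated(), "species"].tolist()
        raise SchemaError(f"duplicate species rows: {dupes}")
    return [
        SiteProperties(
            species=str(r.species),
            c_pct=float(r.c_pct),
            n_pct=float(r.n_pct),
            cn_ratio=float(r.cn_ratio),
            moisture_pct_fw=float(r.moisture_pct_fw),
            ph=float(r.ph),
            bulk_density_g_cm3=float(r.bulk_density_g_cm3),
            horizon_depth_cm=float(r.horizon_depth_cm),
        )
        for r in df.itertuples(index=False)
    ]


def site_properties_frame(path: str | Path | None = None) -> pd.DataFrame:
    """The raw site-property table (including SE columns) as a DataFrame."""
    if path is None:
        res = resources.files("soilncycle.data") / "site_properties.csv"
        with resources.as_file(res) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


__all__ = [
    "SPECIES_PFT", "SHRUB_SPECIES", "MOSS_SPECIES", "SEASONS",
    "UG_N_PER_UMOL", "DEFAULT_TRANSFORMS", "SchemaError",
    "SoilSample", "SiteProperties", "AnalysisConfig",
    "fresh_to_dry", "read_sample_table", "write_sample_table",
    "samples_to_frame", "read_site_properties", "site_properties_frame",
]
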