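"""Mixed-effect ANOVA, Tukey post-hoc contrasts and correlation summaries.

Responses (N pools, N-cycling rates, turnover times) are analysed by a
linear mixed-effect ANOVA with season, plant species and their interaction
as fixed factors and block plus sampling location nested within block as
random intercepts — the location term carries the repeated-measures
structure of resampling each spot in both seasons.  Plant-functional-type
(PFT) models replace species by the shrub/moss factor and add species as a
further random intercept.

Fixed effects are tested with Type-III F-statistics and Satterthwaite
denominator degrees of freedom on the REML fit; explained variance is
summarised by marginal R² (fixed effects only) and conditional R² (fixed
plus random), computed from the variance partition

    R²m = σ²_fixed / (σ²_fixed + Σσ²_random + σ²_resid)
    R²c = (σ²_fixed + Σσ²_random) / (σ²_fixed + Σσ²_random + σ²_resid).

Post-hoc comparisons are Tukey-adjusted contrasts of estimated marginal
means; when the season × species interaction is significant, contrasts are
conditioned on the interaction (species within season, season within
species).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats

from .mixed import VarCompModel, VarCompResult


class TransformDomainError(ValueError):
    """A response value lies outside the domain of the requested transform."""


def transform_response(values, transform: str) -> np.ndarray:
    """Apply 'none' | 'sqrt' | 'log' elementwise, with row-level diagnostics."""
    x = np.asarray(values, dtype=float)
    if transform == "none":
        return x.copy()
    if transform == "sqrt":
        bad = np.flatnonzero(x < 0)
        if bad.size:
            raise TransformDomainError(
                f"sqrt transform: negative values at rows {bad.tolist()}"
            )
        return np.sqrt(x)
    if transform == "log":
        bad = np.flatnonzero(x <= 0)
        if bad.size:
            raise TransformDomainError(
                f"log transform: non-positive values at rows {bad.tolist()}"
            )
        return np.log(x)
    raise ValueError(f"unknown transform {transform!r}")


def inverse_transform(values, transform: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if transform == "none":
        return x.copy()
    if transform == "sqrt":
        return x**2
    if transform == "log":
        return np.exp(x)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Which mixed model to fit for one response."""

    response: str
    transform: str = "none"
    species_factor: str = "species"  # 'species' or 'pft'
    random: tuple[str, ...] = ("block", "location_id")

    @property
    def fixed_formula(self) -> str:
        return f"C(season, Sum) * C({self.species_factor}, Sum)"


@dataclass(frozen=True)
class TermTest:
    term: str
    F: float
    df_num: int
    df_den: float
    p: float


@dataclass
class MixedAnovaResult:
    """Per-term Type-III F-tests plus variance-explained summaries."""

    spec: ModelSpec
    terms: dict[str, TermTest]
    r2_marginal: float
    r2_conditional: float
    varcomps: dict[str, float]
    sigma2_resid: float
    fit: VarCompResult = field(repr=False)
    design_info: object = field(repr=False)
    data: pd.DataFrame = field(repr=False)


def r2_from_variances(
    sigma2_fixed: float, sigma2_random: float, sigma2_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R² from a variance partition."""
    total = sigma2_fixed + sigma2_random + sigma2_resid
    return sigma2_fixed / total, (sigma2_fixed + sigma2_random) / total


def fit_mixed_anova(data: pd.DataFrame, spec: ModelSpec) -> MixedAnovaResult:
    """REML fit of the nested mixed model with Type-III Satterthwaite tests."""
    df = data.reset_index(drop=True)
    needed = {spec.response, "season", spec.species_factor, *spec.random}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"data lacks columns: {sorted(missing)}")
    df = df.dropna(subset=[spec.response]).reset_index(drop=True)
    y = transform_response(df[spec.response].to_numpy(), spec.transform)

    dm = dmatrix(spec.fixed_formula, df, return_type="dataframe")
    design_info = dm.design_info
    X = dm.to_numpy()

    random_factors = {name: df[name].to_numpy() for name in spec.random}
    model = VarCompModel(y, X, random_factors)
    fit = model.fit()

    # friendly term names
    rename = {
        f"C(season, Sum)": "season",
        f"C({spec.species_factor}, Sum)": spec.species_factor,
        f"C(season, Sum):C({spec.species_factor}, Sum)": f"season:{spec.species_factor}",
    }
    terms: dict[str, TermTest] = {}
    for term_name, sl in design_info.term_name_slices.items():
        if term_name == "Intercept":
            continue
        cols = range(sl.start, sl.stop)
        L = np.zeros((len(cols), X.shape[1]))
        for i, c in enumerate(cols):
            L[i, c] = 1.0
        F, q, df_den, p = fit.f_test(L)
        nice = rename.get(term_name, term_name)
        terms[nice] = TermTest(nice, F, q, df_den, p)

    sigma2_fixed = float(np.var(X @ fit.beta, ddof=1))
    sigma2_random = float(sum(fit.varcomps.values()))
    r2m, r2c = r2_from_variances(sigma2_fixed, sigma2_random, fit.sigma2_resid)

    return MixedAnovaResult(
        spec=spec,
        terms=terms,
        r2_marginal=r2m,
        r2_conditional=r2c,
        varcomps=fit.varcomps,
        sigma2_resid=fit.sigma2_resid,
        fit=fit,
        design_info=design_info,
        data=df,
    )


# -- estimated marginal means and Tukey contrasts -----------------------


def _emm_rows(result: MixedAnovaResult) -> tuple[pd.DataFrame, np.ndarray]:
    """Reference grid (season × species) and its design matrix rows."""
    spec = result.spec
    seasons = sorted(result.data["season"].unique())
    species = sorted(result.data[spec.species_factor].unique())
    grid = pd.DataFrame(
        [(s, sp) for s in seasons for sp in species],
        columns=["season", spec.species_factor],
    )
    (mat,) = build_design_matrices([result.design_info], grid)
    return grid, np.asarray(mat)


@dataclass
class ContrastSet:
    """Tukey-adjusted pairwise contrasts of estimated marginal means."""

    factor: str
    conditioning: str  # 'overall' | 'within-season' | 'within-species'
    table: pd.DataFrame  # stratum, level_a, level_b, estimate, se, df, t, p_adj
    letters: dict[tuple[str, str], str]  # (stratum, level) -> letter string


def compact_letters(
    levels: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display; ties broken alphabetically."""
    levels = sorted(levels)
    groups: list[set[str]] = [set(levels)]
    for a, b in sorted(significant_pairs):
        nxt: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                nxt.append(g - {a})
                nxt.append(g - {b})
            else:
                nxt.append(g)
        # absorb sets contained in another set (keep first of duplicates)
        groups = []
        for i, g in enumerate(nxt):
            redundant = any(
                (g < h) or (g == h and j < i) for j, h in enumerate(nxt) if j != i
            )
            if g and not redundant:
                groups.append(g)
    groups.sort(key=lambda g: min(levels.index(x) for x in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, g in zip(alphabet, groups):
        for lv in g:
            out[lv] += letter
    return out


def _pairwise(
    result: MixedAnovaResult,
    grid: pd.DataFrame,
    rows: np.ndarray,
    by_col: str | None,
    level_col: str,
) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    records = []
    letters: dict[tuple[str, str], str] = {}
    strata = [None] if by_col is None else sorted(grid[by_col].unique())
    for stratum in strata:
        if stratum is None:
            sub = grid
            label = "all"
        else:
            sub = grid[grid[by_col] == stratum]
            label = str(stratum)
        levels = sorted(sub[level_col].unique())
        if len(levels) < 2:
            raise ValueError(f"factor {level_col!r} needs at least two levels")
        k = len(levels)
        # EMM row for each level: average design rows over the other factor
        lvec = {}
        for lv in levels:
            mask = (sub[level_col] == lv).to_numpy()
            lvec[lv] = rows[sub.index.to_numpy()[mask]].mean(axis=0)
        sig: set[tuple[str, str]] = set()
        for a, b in itertools.combinations(levels, 2):
            l = lvec[a] - lvec[b]
            est, se, df = result.fit.t_test(l)
            t = est / se if se > 0 else 0.0
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            p_adj = min(max(p_adj, 0.0), 1.0)
            records.append(
                {
                    "stratum": label,
                    "level_a": a,
                    "level_b": b,
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": t,
                    "p_adj": p_adj,
                }
            )
            if p_adj < 0.05:
                sig.add((a, b))
        for lv, s in compact_letters(levels, sig).items():
            letters[(label, lv)] = s
    return pd.DataFrame(records), letters


def posthoc_contrasts(
    result: MixedAnovaResult,
    factor: str,
    condition_on: str = "none",
    interaction_threshold: float = 0.05,
) -> list[ContrastSet]:
    """Tukey-adjusted pairwise comparisons of estimated marginal means.

    With ``condition_on='none'`` the requested factor is compared averaging
    over the other.  With ``condition_on='interaction'`` the interaction
    test decides: if its p-value is below the threshold, species contrasts
    are estimated within each season and season contrasts within each
    species; otherwise the overall contrasts are returned.
    """
    spec = result.spec
    if factor not in ("season", spec.species_factor):
        raise ValueError(f"factor {factor!r} not in the fixed part")
    grid, rows = _emm_rows(result)
    inter = result.terms.get(f"season:{spec.species_factor}")
    conditioned = (
        condition_on == "interaction"
        and inter is not None
        and inter.p < interaction_threshold
    )
    out: list[ContrastSet] = []
    if not conditioned:
        table, letters = _pairwise(result, grid, rows, None, factor)
        out.append(ContrastSet(factor, "overall", table, letters))
        return out
    if factor == spec.species_factor:
        table, letters = _pairwise(result, grid, rows, "season", factor)
        out.append(ContrastSet(factor, "within-season", table, letters))
    else:
        table, letters = _pairwise(result, grid, rows, spec.species_factor, factor)
        out.append(ContrastSet(factor, "within-species", table, letters))
    return out


def pearson_correlations(
    table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Product-moment r and two-sided p per variable pair."""
    records = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({a}, {b}): need at least 3 complete pairs")
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"pair ({a}, {b}): zero variance")
        r, p = stats.pearsonr(x, y)
        records.append({"var_a": a, "var_b": b, "n": len(sub), "r": r, "p": p})
    return pd.DataFrame(records)


def anova_summary_table(
    data: pd.DataFrame,
    responses: dict[str, str],
    species_factor: str = "species",
    random: tuple[str, ...] = ("block", "location_id"),
) -> pd.DataFrame:
    """Fit one mixed ANOVA per response and stack the term tests tidily.

    ``responses`` maps response column → transform name.
    """
    rows = []
    for resp, transform in responses.items():
        res = fit_mixed_anova(
            data, ModelSpec(resp, transform, species_factor, random)
        )
        for t in res.terms.values():
            rows.append(
                {
                    "response": resp,
                    "transform": transform,
                    "term": t.term,
                    "F": t.F,
                    "df1": t.df_num,
                    "df2": t.df_den,
                    "p": t.p,
                    "r2m": res.r2_marginal,
                    "r2c": res.r2_conditional,
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "TransformDomainError", "transform_response", "inverse_transform",
    "ModelSpec", "TermTest", "MixedAnovaResult", "r2_from_variances",
    "fit_mixed_anova", "ContrastSet", "compact_letters",
    "posthoc_contrasts", "pearson_correlations", "anova_summary_table",
]
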