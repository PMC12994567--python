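"""Covariate models: richness/diversity/sharing GLMs with EMM post-hoc tests.

Richness is modelled with a gamma-family GLM (log link; the response is a
strictly positive proportion) and the diversity indices with Gaussian GLMs,
all on the design  receptor_type + site + age + sex + age:sex.  Pairwise
sharing is modelled with a Gaussian GLM on the six-term design
receptor_type + same_sex + age_diff + age_sum + age_diff:receptor_type +
age_sum:receptor_type.  Estimated marginal means (EMMs) average model
predictions over a reference grid (factors crossed equally, covariates at
their means); pairwise EMM contrasts use Tukey's studentized-range
adjustment, and per-level covariate slopes are the EMM analogue of trend
estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .repertoire_io import MouseMetadata

__all__ = [
    "ModelResult",
    "EMMContrast",
    "fit_richness_model",
    "fit_diversity_model",
    "fit_sharing_model",
    "emm_means",
    "emm_contrasts",
    "emm_slopes",
]


@dataclass
class ModelResult:
    """A fitted GLM with its tidy coefficient table.

    ``coefficients`` has one row per design term: estimate, standard error,
    test statistic (t, on the residual degrees of freedom) and p-value.
    """

    formula: str
    family: str
    coefficients: pd.DataFrame
    n_obs: int
    result: object  # statsmodels GLMResults
    data: pd.DataFrame
    factors: Dict[str, List] = field(default_factory=dict)
    covariates: List[str] = field(default_factory=list)
    diagnostics: Dict[str, float] = field(default_factory=dict)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        ci = self.result.conf_int(alpha=1 - level)
        ci.columns = ["lower", "upper"]
        return ci


@dataclass
class EMMContrast:
    """One pairwise EMM contrast with its multiplicity-adjusted p-value."""

    factor: str
    level_a: str
    level_b: str
    estimate: float
    se: float
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    adjustment: str = "tukey"


def _metadata_frame(metadata: Union[Sequence[MouseMetadata], pd.DataFrame]) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        return metadata.copy()
    return pd.DataFrame(
        [{"mouse_id": m.mouse_id, "sex": m.sex, "age": m.age,
          "site": m.site, "cohort": m.cohort} for m in metadata]
    )


def _prune_terms(df: pd.DataFrame, factors: List[str], covariates: List[str],
                 interactions: List[Tuple[str, str]]):
    """Drop single-level factors (with a warning) and their interactions;
    error on zero-variance covariates."""
    kept_factors = []
    for f in factors:
        n_levels = df[f].nunique()
        if n_levels < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped from design")
        else:
            kept_factors.append(f)
    for c in covariates:
        if float(np.var(df[c].to_numpy(dtype=float))) == 0.0:
            raise ValueError(f"covariate {c!r} has zero variance")
    kept_inter = [(a, b) for a, b in interactions
                  if (a in kept_factors or a in covariates)
                  and (b in kept_factors or b in covariates)]
    return kept_factors, covariates, kept_inter


def _fit_glm(
    df: pd.DataFrame,
    response: str,
    factors: List[str],
    covariates: List[str],
    interactions: List[Tuple[str, str]],
    family_name: str,
    standardize: bool = False,
) -> ModelResult:
    df = df.copy()
    y = df[response].to_numpy(dtype=float)
    if float(np.var(y)) == 0.0:
        raise ValueError(f"response {response!r} is constant")
    factors, covariates, interactions = _prune_terms(
        df, factors, covariates, interactions
    )
    for f in factors:
        df[f] = df[f].astype(str)
    if standardize:
        for c in covariates:
            col = df[c].to_numpy(dtype=float)
            df[c] = (col - col.mean()) / col.std(ddof=0)
    terms = factors + covariates + [f"{a}:{b}" for a, b in interactions]
    formula = f"{response} ~ " + " + ".join(terms)
    if family_name == "gamma_log":
        family = sm.families.Gamma(link=sm.families.links.Log())
    elif family_name == "gaussian":
        family = sm.families.Gaussian()
    else:
        raise ValueError(f"unknown family {family_name!r}")
    model = smf.glm(formula, data=df, family=family)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        names = model.exog_names
        # identify aliased columns: those whose removal does not reduce rank
        aliased = []
        for j in range(model.exog.shape[1]):
            sub = np.delete(model.exog, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    params = res.params
    se = res.bse
    tstat = params / se
    df_resid = res.df_resid
    pvals = 2 * stats.t.sf(np.abs(tstat), df_resid)
    coeff = pd.DataFrame({
        "term": params.index,
        "estimate": params.to_numpy(),
        "se": se.to_numpy(),
        "statistic": tstat.to_numpy(),
        "p_value": pvals,
    }).set_index("term")
    resid = res.resid_pearson
    diagnostics = {
        "dispersion": float(res.pearson_chi2 / df_resid) if df_resid else np.nan,
        "resid_mean": float(np.mean(resid)),
        "resid_skew": float(stats.skew(resid)),
        "converged": float(res.converged),
    }
    return ModelResult(
        formula=formula,
        family=family_name,
        coefficients=coeff,
        n_obs=int(res.nobs),
        result=res,
        data=df,
        factors={f: sorted(df[f].unique()) for f in factors},
        covariates=list(covariates),
        diagnostics=diagnostics,
    )


def _richness_frame(diversity_tbl: pd.DataFrame,
                    metadata) -> pd.DataFrame:
    meta = _metadata_frame(metadata)
    tbl = diversity_tbl.drop_duplicates(["mouse_id", "receptor_type"])[
        ["mouse_id", "receptor_type", "richness"]
    ]
    return tbl.merge(meta, on="mouse_id", how="left")


def fit_richness_model(
    diversity_tbl: pd.DataFrame,
    metadata: Union[Sequence[MouseMetadata], pd.DataFrame],
    standardize: bool = False,
) -> ModelResult:
    """Gamma GLM (log link) of repertoire richness on
    receptor_type + site + age + sex + age:sex."""
    df = _richness_frame(diversity_tbl, metadata)
    return _fit_glm(df, "richness",
                    factors=["receptor_type", "site", "sex"],
                    covariates=["age"],
                    interactions=[("age", "sex")],
                    family_name="gamma_log",
                    standardize=standardize)


def fit_diversity_model(
    diversity_tbl: pd.DataFrame,
    metadata: Union[Sequence[MouseMetadata], pd.DataFrame],
    index: str = "shannon",
    standardize: bool = False,
) -> ModelResult:
    """Gaussian GLM of a diversity index (``shannon`` or ``simpson_log``)
    on receptor_type + site + age + sex + age:sex."""
    if index not in ("shannon", "simpson_log"):
        raise ValueError(f"index must be shannon or simpson_log, got {index!r}")
    meta = _metadata_frame(metadata)
    idx_name = "shannon" if index == "shannon" else "simpson"
    tbl = diversity_tbl[diversity_tbl["index"] == idx_name][
        ["mouse_id", "receptor_type", index]
    ]
    df = tbl.merge(meta, on="mouse_id", how="left")
    return _fit_glm(df, index,
                    factors=["receptor_type", "site", "sex"],
                    covariates=["age"],
                    interactions=[("age", "sex")],
                    family_name="gaussian",
                    standardize=standardize)


def fit_sharing_model(
    pairs: pd.DataFrame, standardize: bool = False
) -> ModelResult:
    """Gaussian GLM of pairwise shared counts on the six-term design
    receptor_type + same_sex + age_diff + age_sum
    + age_diff:receptor_type + age_sum:receptor_type.

    Pair rows are not independent (each mouse appears in many pairs); the
    model is fitted on them as stated, and permutation-based significance is
    available separately via :func:`sharing_permutation_pvalues`.
    """
    if pairs["receptor_type"].nunique() < 2:
        raise ValueError("need >= 2 receptor types in the pair table")
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 pairs, got {len(pairs)}")
    if pairs["mouse_a"].nunique() + pairs["mouse_b"].nunique() < 3:
        raise ValueError("pairs must involve more than one mouse")
    df = pairs.copy()
    df["same_sex"] = df["same_sex"].astype(bool).astype(str)
    return _fit_glm(df, "shared",
                    factors=["receptor_type", "same_sex"],
                    covariates=["age_diff", "age_sum"],
                    interactions=[("age_diff", "receptor_type"),
                                  ("age_sum", "receptor_type")],
                    family_name="gaussian",
                    standardize=standardize)


def _reference_grid(model: ModelResult) -> pd.DataFrame:
    """All factor-level combinations, covariates at their data means."""
    grids = [pd.DataFrame({f: levels}).assign(_key=1)
             for f, levels in model.factors.items()]
    grid = grids[0]
    for g in grids[1:]:
        grid = grid.merge(g, on="_key")
    grid = grid.drop(columns="_key")
    for c in model.covariates:
        grid[c] = float(model.data[c].mean())
    return grid


def _design_rows(model: ModelResult, grid: pd.DataFrame) -> np.ndarray:
    design_info = model.result.model.data.design_info
    (mat,) = patsy.build_design_matrices([design_info], grid)
    return np.asarray(mat)


def emm_means(model: ModelResult, factor: str) -> pd.DataFrame:
    """EMMs (on the link scale) for each level of ``factor``, averaging
    equally over the other factors with covariates at their means."""
    if factor not in model.factors:
        raise ValueError(f"factor {factor!r} not in model ({list(model.factors)})")
    grid = _reference_grid(model)
    X = _design_rows(model, grid)
    beta = model.result.params.to_numpy()
    V = model.result.cov_params().to_numpy()
    rows = []
    for level in model.factors[factor]:
        mask = (grid[factor] == level).to_numpy()
        L = X[mask].mean(axis=0)
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        rows.append({"level": level, "emm": est, "se": se})
    return pd.DataFrame(rows)


def emm_contrasts(model: ModelResult, factor: str) -> List[EMMContrast]:
    """All pairwise EMM contrasts for ``factor`` with Tukey adjustment.

    k levels yield k(k-1)/2 contrasts; the adjusted p-value uses the
    studentized range on the model's residual degrees of freedom, so it is
    always >= the unadjusted t-test p-value.
    """
    if factor not in model.factors:
        raise ValueError(f"factor {factor!r} not in model ({list(model.factors)})")
    grid = _reference_grid(model)
    X = _design_rows(model, grid)
    beta = model.result.params.to_numpy()
    V = model.result.cov_params().to_numpy()
    levels = model.factors[factor]
    k = len(levels)
    df_resid = float(model.result.df_resid)
    Ls = {}
    for level in levels:
        mask = (grid[factor] == level).to_numpy()
        Ls[level] = X[mask].mean(axis=0)
    out: List[EMMContrast] = []
    for a, b in combinations(levels, 2):
        L = Ls[a] - Ls[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        t = est / se
        p_raw = float(2 * stats.t.sf(abs(t), df_resid))
        p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df_resid))
        out.append(EMMContrast(factor=factor, level_a=a, level_b=b,
                               estimate=est, se=se, statistic=t,
                               p_unadjusted=p_raw,
                               p_adjusted=min(max(p_adj, p_raw), 1.0)))
    return out


def emm_slopes(model: ModelResult, covariate: str, by: str) -> pd.DataFrame:
    """Per-level slopes of ``covariate`` (EMM trend estimates), one for each
    level of the factor ``by``, averaged over the other design factors."""
    if covariate not in model.covariates:
        raise ValueError(f"covariate {covariate!r} not in model")
    if by not in model.factors:
        raise ValueError(f"factor {by!r} not in model")
    grid = _reference_grid(model)
    beta = model.result.params.to_numpy()
    V = model.result.cov_params().to_numpy()
    df_resid = float(model.result.df_resid)
    rows = []
    for level in model.factors[by]:
        sub = grid[grid[by] == level].copy()
        lo, hi = sub.copy(), sub.copy()
        hi[covariate] = hi[covariate] + 0.5
        lo[covariate] = lo[covariate] - 0.5
        L = (_design_rows(model, hi) - _design_rows(model, lo)).mean(axis=0)
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        t = est / se
        rows.append({"level": level, "slope": est, "se": se, "statistic": t,
                     "p_value": float(2 * stats.t.sf(abs(t), df_resid))})
    return pd.DataFrame(rows)


def sharing_permutation_pvalues(
    pairs: pd.DataFrame,
    metadata: Union[Sequence[MouseMetadata], pd.DataFrame],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-values for the age terms of the sharing model.

    Mouse ages are shuffled across mice (respecting the pair structure:
    age_diff/age_sum are recomputed from the shuffled ages), the GLM is
    refitted, and two-sided p-values are the fraction of permuted |t| at
    least as large as observed.  This addresses the non-independence of pair
    rows that the Gaussian GLM ignores.
    """
    meta = _metadata_frame(metadata).set_index("mouse_id")
    observed = fit_sharing_model(pairs)
    terms = [t for t in observed.coefficients.index
             if "age_diff" in t or "age_sum" in t]
    obs_t = observed.coefficients.loc[terms, "statistic"].to_numpy()
    rng = np.random.default_rng(seed)
    mice = sorted(set(pairs["mouse_a"]) | set(pairs["mouse_b"]))
    ages = meta.loc[mice, "age"].to_numpy(dtype=float)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = dict(zip(mice, rng.permutation(ages)))
        shuffled = pairs.copy()
        pa = shuffled["mouse_a"].map(perm)
        pb = shuffled["mouse_b"].map(perm)
        shuffled["age_diff"] = (pa - pb).abs()
        shuffled["age_sum"] = pa + pb
        try:
            fit = fit_sharing_model(shuffled)
        except ValueError:
            continue
        perm_t = fit.coefficients.reindex(terms)["statistic"].to_numpy()
        exceed += np.abs(perm_t) >= np.abs(obs_t)
    pvals = (exceed + 1) / (n_perm + 1)
    return pd.DataFrame({"term": terms, "statistic": obs_t,
                         "p_permutation": pvals}).set_index("term")
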