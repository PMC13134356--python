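"""End-to-end orchestration of the height-residual analysis.

Stages: cohort ingestion (synthetic or file-based) -> polygenic score ->
GRM and ancestry PCs -> mixed-model fits (model 1: PGS + sex + PCs;
model 2: + age + age^2) -> fixed-effects residuals (height_rez,
height_rez_age) -> LE8 and cognition scoring -> SEP-category derivation ->
residual-validity analysis against childhood socioeconomic indicators ->
survey-weighted associations of the residual with cardiovascular health and
cognition under three nested covariate tiers, with age-group / birth-cohort
stratification and interaction tests -> under-60 sensitivity rerun.

All estimation that involves the survey design goes through
:mod:`heightrez.survey`; the exposure enters association models divided by
its sample SD, so betas are per 1 SD of height_rez_age.
"""

from __future__ import annotations

import json
import platform
import warnings

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataError, InvalidParameterError
from .pgs import MatchedWeights, WeightTable, compute_pgs, match_alleles
from .residualize import extract_residuals, fit_height_model, standardize_height
from .scores import compute_cvh_scores, cognition_composites
from .survey import AssocResult, SurveyDesign, svy_interaction_test, svy_lm
from .synth import (EDUC_LEVELS, MIGRATION_LEVELS, SimParams, simulate_cohort,
                    weight_table_from_truth)
from .varcomp import compute_grm, top_pcs

AGE_GROUPS = [(18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, None)]
BIRTH_COHORTS = [(1930, 1949), (1950, 1959), (1960, 1969), (1970, 1979),
                 (1980, 1999)]

TIER1 = ["age", "sex", "center", "hispanic_background", "us_nativity",
         "years_in_us", "marital_status", "language_pref"]
TIER2 = TIER1 + ["education", "income_band", "insurance"]
TIER3_BEHAVIOR = ["diet_score_cvh", "pa_score", "nicotine_score", "sleep_score"]

CATEGORICAL = {"sex", "center", "hispanic_background", "us_nativity",
               "marital_status", "language_pref", "education",
               "age_group", "birth_cohort"}

SEP_VARIABLES = {
    "parental_educ": EDUC_LEVELS,
    "us_born_migration": MIGRATION_LEVELS,
    "birth_cohort": None,  # filled from BIRTH_COHORTS labels
    "hardship_group": ["none", "0-12 only", "13-18 only", "both"],
    "plumbing": ["no", "yes"],
    "sewer": ["no", "yes"],
    "electricity": ["no", "yes"],
    "phone": ["no", "yes"],
}


def _interval_label(lo, hi):
    return f"{lo}+" if hi is None else f"{lo}-{hi}"


def _cut_intervals(x, intervals):
    """Assign values to [lo, hi] intervals (closed on both printed endpoints)."""
    out = np.full(len(x), None, dtype=object)
    for lo, hi in intervals:
        lab = _interval_label(lo, hi)
        m = (x >= lo) if hi is None else ((x >= lo) & (x <= hi))
        out[np.asarray(m)] = lab
    return out


def derive_sep_categories(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add derived SEP and stratification columns.

    ``parental_educ`` is the highest of paternal/maternal education (missing
    only when both are missing); ``birth_cohort`` and ``age_group`` follow
    the standard closed-interval schemes; ``hardship_group`` combines the
    two childhood-hardship windows; ``us_nativity`` dichotomizes migration
    history. Unknown category labels raise with the offending values listed.
    """
    df = cohort.copy()
    rank = {lvl: i for i, lvl in enumerate(EDUC_LEVELS)}
    for col in ("paternal_educ", "maternal_educ"):
        bad = set(df[col].dropna()) - set(EDUC_LEVELS)
        if bad:
            raise DataError(f"unknown {col} label(s): {sorted(bad)}")
    pat = df["paternal_educ"].map(rank)
    mat = df["maternal_educ"].map(rank)
    best = pd.concat([pat, mat], axis=1).max(axis=1)
    df["parental_educ"] = best.map({v: k for k, v in rank.items()})

    bad = set(df["us_born_migration"].dropna()) - set(MIGRATION_LEVELS)
    if bad:
        raise DataError(f"unknown us_born_migration label(s): {sorted(bad)}")
    df["us_nativity"] = np.where(df["us_born_migration"] == "US born",
                                 "US born", "foreign born")

    df["birth_cohort"] = _cut_intervals(df["birth_year"].to_numpy(float),
                                        BIRTH_COHORTS)
    df["age_group"] = _cut_intervals(df["age"].to_numpy(float), AGE_GROUPS)

    h1 = df["hardship_0_12"].map({"yes": True, "no": False})
    h2 = df["hardship_13_18"].map({"yes": True, "no": False})
    grp = np.select(
        [h1.eq(True) & h2.eq(True), h1.eq(True) & h2.eq(False),
         h1.eq(False) & h2.eq(True), h1.eq(False) & h2.eq(False)],
        ["both", "0-12 only", "13-18 only", "none"], default=None)
    df["hardship_group"] = grp
    return df


def build_design(df: pd.DataFrame, columns, add_intercept=True):
    """Numeric design matrix: categoricals dummy-coded dropping the first level.

    Returns ``(X, names)``; rows with missing values carry NaN (complete-case
    handling is downstream, in the survey estimators).
    """
    cols, names = [], []
    if add_intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for c in columns:
        if c in CATEGORICAL or df[c].dtype == object:
            s = df[c].astype(object)
            levels = [l for l in pd.unique(s.dropna())]
            levels = sorted(levels, key=lambda v: str(v))
            for lvl in levels[1:]:
                x = np.where(s.isna(), np.nan, (s == lvl).astype(float))
                cols.append(x)
                names.append(f"{c}[{lvl}]")
        else:
            cols.append(df[c].to_numpy(float))
            names.append(c)
    return np.column_stack(cols), names


def validity_analysis(residuals: pd.DataFrame, cohort: pd.DataFrame,
                      design: SurveyDesign, variables=None) -> pd.DataFrame:
    """Category mean differences of the height residuals by SEP variable.

    For each SEP variable and each residual (height_rez, height_rez_age), a
    survey-weighted regression of the residual on category dummies gives
    mean differences vs the reference (first) category with 95% CIs, and the
    variable-level weighted R^2.
    """
    variables = variables or dict(SEP_VARIABLES)
    rows = []
    merged = cohort.reset_index(drop=True)
    for var, levels in variables.items():
        s = merged[var].astype(object)
        if levels is None:
            levels = [_interval_label(lo, hi) for lo, hi in BIRTH_COHORTS]
        present = [l for l in levels if (s == l).any()]
        if not present:
            raise DataError(f"reference category empty for {var!r}")
        ref = present[0]
        dummies = [np.where(s.isna(), np.nan, (s == l).astype(float))
                   for l in present[1:]]
        X = np.column_stack([np.ones(len(s))] + dummies)
        names = ["intercept"] + [f"{var}[{l}]" for l in present[1:]]
        for res_col in ("height_rez", "height_rez_age"):
            fit = svy_lm(residuals[res_col].to_numpy(), X, design, names=names)
            rows.append({"variable": var, "residual": res_col, "category": ref,
                         "mean_diff": 0.0, "ci_lo": 0.0, "ci_hi": 0.0,
                         "r_squared": fit.r_squared, "n": fit.n})
            for l in present[1:]:
                r = fit[f"{var}[{l}]"]
                rows.append({"variable": var, "residual": res_col,
                             "category": l, "mean_diff": r["beta"],
                             "ci_lo": r["ci_lo"], "ci_hi": r["ci_hi"],
                             "r_squared": fit.r_squared, "n": fit.n})
    return pd.DataFrame(rows)


def _exposure(residuals: pd.DataFrame, column="height_rez_age"):
    r = residuals[column].to_numpy(float)
    sd = np.nanstd(r, ddof=1)
    if not sd > 0:
        raise DataError("residual SD is zero; cannot scale exposure")
    return r / sd


def health_association(outcome: str, analysis_df: pd.DataFrame,
                       design: SurveyDesign, tier: int = 1,
                       stratify_by: str | None = None,
                       min_stratum_n: int = 50,
                       include_age2: bool = True,
                       exposure_col: str = "height_rez_age") -> dict:
    """Association of the per-SD height residual with a health outcome.

    ``analysis_df`` must contain the outcome, the residual, the covariates of
    the requested tier, and (for stratified runs) the stratification column.
    Cognition outcomes (columns ending ``_z`` or ``global_cognition``) are
    restricted to age >= 45 and, at tier 3, additionally adjusted for the
    health-domain CVH score. Returns pooled and per-stratum results plus a
    joint Wald interaction p-value from the pooled model.
    """
    df = analysis_df.copy()
    is_cognition = outcome == "global_cognition" or outcome.endswith("_z")
    if is_cognition:
        df = df[df["age"].to_numpy(float) >= 45].reset_index(drop=True)
        design_used = design.subset(analysis_df["age"].to_numpy(float) >= 45)
    else:
        design_used = design
    covars = list(TIER1 if tier == 1 else TIER2)
    if tier == 3:
        covars = list(TIER2) + list(TIER3_BEHAVIOR)
        if is_cognition:
            covars.append("health_domain_score")
    if tier not in (1, 2, 3):
        raise InvalidParameterError("tier must be 1, 2 or 3")

    sd = np.nanstd(df[exposure_col].to_numpy(float), ddof=1)
    if not sd > 0:
        raise DataError("residual SD is zero in the analysis sample")
    df["_exposure"] = df[exposure_col].to_numpy(float) / sd

    def one_fit(sub_df, sub_design):
        Xc, names = build_design(sub_df, covars)
        if include_age2:
            Xc = np.column_stack([Xc, sub_df["age"].to_numpy(float) ** 2])
            names = names + ["age2"]
        X = np.column_stack([Xc, sub_df["_exposure"].to_numpy(float)])
        names = names + ["exposure"]
        fit = svy_lm(sub_df[outcome].to_numpy(float), X, sub_design, names=names)
        base = svy_lm(sub_df[outcome].to_numpy(float), Xc, sub_design,
                      names=names[:-1])
        r2_exposure = fit.r_squared - base.r_squared
        return fit, r2_exposure

    pooled_fit, pooled_r2 = one_fit(df, design_used)
    out = {"outcome": outcome, "tier": tier,
           "pooled": pooled_fit, "pooled_exposure": dict(
               beta=float(pooled_fit["exposure"]["beta"]),
               ci_lo=float(pooled_fit["exposure"]["ci_lo"]),
               ci_hi=float(pooled_fit["exposure"]["ci_hi"]),
               r2_exposure=float(pooled_r2),
               n=pooled_fit.n),
           "strata": {}, "interaction_p": None}

    if stratify_by:
        levels = [l for l in pd.unique(df[stratify_by].dropna())]
        levels = sorted(levels, key=str)
        for lvl in levels:
            m = (df[stratify_by] == lvl).to_numpy()
            if m.sum() < min_stratum_n:
                warnings.warn(f"stratum {stratify_by}={lvl!r} has n={m.sum()} "
                              f"< {min_stratum_n}; skipped")
                continue
            strat_covars = [c for c in covars if c != stratify_by]
            sub = df[m].reset_index(drop=True)
            try:
                Xc, names = build_design(sub, strat_covars)
                if include_age2:
                    Xc = np.column_stack([Xc, sub["age"].to_numpy(float) ** 2])
                    names += ["age2"]
                X = np.column_stack([Xc, sub["_exposure"].to_numpy(float)])
                fit = svy_lm(sub[outcome].to_numpy(float), X,
                             design_used.subset(m), names=names + ["exposure"])
                out["strata"][str(lvl)] = fit
            except Exception as exc:  # stratum-level failures are non-fatal
                warnings.warn(f"stratum {lvl!r} fit failed: {exc}")
        # pooled interaction model: exposure x stratum dummies
        Xc, names = build_design(df, covars + [stratify_by])
        if include_age2:
            Xc = np.column_stack([Xc, df["age"].to_numpy(float) ** 2])
            names += ["age2"]
        strat_dummy_idx = [i for i, nm in enumerate(names)
                           if nm.startswith(f"{stratify_by}[")]
        inter_cols = [Xc[:, i] * df["_exposure"].to_numpy(float)
                      for i in strat_dummy_idx]
        inter_names = [f"exposure:{names[i]}" for i in strat_dummy_idx]
        X = np.column_stack([Xc, df["_exposure"].to_numpy(float)] + inter_cols)
        fit = svy_lm(df[outcome].to_numpy(float), X, design_used,
                     names=names + ["exposure"] + inter_names)
        _, p = svy_interaction_test(fit, inter_names)
        out["interaction_p"] = float(p)
        out["interaction_fit"] = fit
    return out


# ---------------------------------------------------------------------------
# full pipeline

def _analyze(cohort, residuals, design, outcomes, tiers=(1, 2, 3),
             stratify=("age_group", "birth_cohort")):
    """Validity + association analyses on an already-residualized sample."""
    results = {"validity": validity_analysis(residuals, cohort, design),
               "associations": []}
    merged = cohort.reset_index(drop=True).copy()
    for col in ("height_rez", "height_rez_age"):
        merged[col] = residuals[col].to_numpy()
    for outcome in outcomes:
        for tier in tiers:
            entry = health_association(outcome, merged, design, tier=tier)
            results["associations"].append(
                {"outcome": outcome, "tier": tier, "stratify": None,
                 **entry["pooled_exposure"]})
        for strat in stratify:
            entry = health_association(outcome, merged, design, tier=min(tiers),
                                       stratify_by=strat)
            results["associations"].append(
                {"outcome": outcome, "tier": min(tiers), "stratify": strat,
                 "interaction_p": entry["interaction_p"],
                 **entry["pooled_exposure"]})
    results["associations"] = pd.DataFrame(results["associations"])
    return results


def fit_residual_models(cohort, grm, pcs, pgs, kernels=None):
    """Standardize height, fit models 1 and 2, extract both residuals.

    With ``grm=None`` (precomputed-PGS bypass) the random effects reduce to
    household and census block.
    """
    z = standardize_height(cohort["height_cm"].to_numpy(float),
                           cohort["sex"].to_numpy())
    if kernels is None:
        kernels = [cohort["household_id"].to_numpy(),
                   cohort["block_id"].to_numpy()]
        kernel_names = ["household", "block"]
        if grm is not None:
            kernels = [grm] + kernels
            kernel_names = ["grm"] + kernel_names
    else:
        kernel_names = [f"k{j}" for j in range(len(kernels))]
    m1 = fit_height_model(z, pgs, cohort["sex"].to_numpy(), pcs, kernels,
                          kernel_names=kernel_names)
    m2 = fit_height_model(z, pgs, cohort["sex"].to_numpy(), pcs, kernels,
                          kernel_names=kernel_names, include_age=True,
                          age=cohort["age"].to_numpy(float))
    res = extract_residuals(cohort["id"].to_numpy(), z, m1, m2, pgs,
                            cohort["sex"].to_numpy(), pcs,
                            cohort["age"].to_numpy(float))
    return res, m1, m2


def sensitivity_under60(cohort, geno_dosages_pgs, grm, pcs, design_cols,
                        outcomes, age_cut=60.0, min_n=200):
    """Refit the whole residualization and analysis below the age cut.

    Standardization, REML models and residuals are recomputed on the
    restricted sample; validity and association analyses are rerun. Returns
    the same result bundle as the main analysis, tagged with the cut.
    """
    age = cohort["age"].to_numpy(float)
    if not (age.min() <= age_cut):
        raise InvalidParameterError("age_cut below the observed age range")
    keep = age <= age_cut
    if keep.sum() < min_n:
        raise DataError(f"restricted sample n={keep.sum()} < {min_n}")
    sub = cohort[keep].reset_index(drop=True)
    grm_sub = grm[np.ix_(keep, keep)] if grm is not None else None
    pcs_sub = pcs[keep]
    pgs_sub = np.asarray(geno_dosages_pgs)[keep]
    res, m1, m2 = fit_residual_models(sub, grm_sub, pcs_sub, pgs_sub)
    design = SurveyDesign.from_frame(sub, *design_cols)
    out = _analyze(sub, res.table, design, outcomes)
    out["age_cut"] = age_cut
    out["n"] = int(keep.sum())
    return out


def run_pipeline(config: dict) -> dict:
    """Execute the full pipeline from a config dict; returns a result bundle.

    Config keys: ``sim`` (SimParams fields) for a synthetic cohort, or
    ``cohort_path``/``genotype_path``/``genotype_meta_path``/``weights_path``
    for file inputs; ``pgs_column`` to bypass scoring with a precomputed PGS
    column (then ``pc_columns`` must list supplied PC columns); ``n_pcs``
    (default 5); ``outcomes``; ``out_dir`` to write TSVs and a manifest;
    ``sensitivity_age_cut`` (default 60, ``None`` to skip).
    """
    from pathlib import Path
    from .synth import GenotypeMatrix
    from .pgs import read_weight_table

    manifest = {"version": __version__, "python": platform.python_version(),
                "config": {k: v for k, v in config.items()
                           if k not in ("sim", "out_dir")},
                "stages": []}
    if "sim" in config:
        params = SimParams(**config["sim"])
        manifest["config"]["sim"] = json.loads(json.dumps(params.__dict__, default=list))
        geno, cohort, truth = simulate_cohort(params)
        weights = WeightTable(weight_table_from_truth(geno, truth))
        manifest["stages"].append("simulate")
    else:
        cohort = pd.read_csv(config["cohort_path"], sep="\t")
        geno = None
        truth = None
        if "genotype_path" in config:
            geno = GenotypeMatrix.read_tsv(config["genotype_path"],
                                           config["genotype_meta_path"])
        weights = (read_weight_table(config["weights_path"])
                   if "weights_path" in config else None)
        manifest["stages"].append("ingest")

    n_pcs = int(config.get("n_pcs", 5))
    if config.get("pgs_column"):
        pgs = cohort[config["pgs_column"]].to_numpy(float)
        pcs = cohort[list(config["pc_columns"])].to_numpy(float)
        grm = None
        if geno is not None:
            grm, _ = compute_grm(geno)
        manifest["stages"].append("pgs-bypass")
    else:
        if geno is None or weights is None:
            raise InvalidParameterError(
                "need genotypes and weights, or a precomputed pgs_column")
        matched = match_alleles(weights, geno.snp_meta,
                                drop_ambiguous=bool(config.get("drop_ambiguous")))
        pgs = compute_pgs(geno, matched)
        manifest["n_excluded_snps"] = int(len(matched.excluded))
        grm, _ = compute_grm(geno)
        pcs, _ = top_pcs(grm, n_pcs)
        manifest["stages"] += ["pgs", "grm-pcs"]

    cohort = derive_sep_categories(cohort)
    res, m1, m2 = fit_residual_models(cohort, grm, pcs, pgs)
    manifest["stages"] += ["model1", "model2", "residuals"]
    manifest["model1"] = m1.to_json_dict()
    manifest["model2"] = m2.to_json_dict()

    cvh = compute_cvh_scores(cohort)
    cog = cognition_composites(cohort)
    analysis = cohort.reset_index(drop=True).copy()
    for frame in (cvh, cog):
        for c in frame.columns:
            if c != "id":
                analysis[c] = frame[c].to_numpy()
    manifest["stages"].append("scores")

    design_cols = tuple(config.get("design_columns", ("stratum", "psu", "weight")))
    design = SurveyDesign.from_frame(analysis, *design_cols)
    outcomes = list(config.get("outcomes", ["health_domain_score",
                                            "global_cognition"]))
    results = _analyze(analysis, res.table, design, outcomes)
    manifest["stages"] += ["validity", "associations"]

    cut = config.get("sensitivity_age_cut", 60.0)
    if cut is not None:
        results["sensitivity"] = sensitivity_under60(
            analysis, pgs, grm, pcs, design_cols, outcomes, age_cut=float(cut))
        manifest["stages"].append("sensitivity")

    results["residuals"] = res.table
    results["manifest"] = manifest
    results["fits"] = {"model1": m1, "model2": m2}

    if config.get("out_dir"):
        out = Path(config["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        res.table.to_csv(out / "residuals.tsv", sep="\t", index=False)
        results["validity"].to_csv(out / "validity.tsv", sep="\t", index=False)
        results["associations"].to_csv(out / "associations.tsv", sep="\t",
                                       index=False)
        if "sensitivity" in results:
            results["sensitivity"]["validity"].to_csv(
                out / "validity_under60.tsv", sep="\t", index=False)
            results["sensitivity"]["associations"].to_csv(
                out / "associations_under60.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return results
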