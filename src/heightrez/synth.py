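"""Synthetic cohort generator.

Emulates the statistical structure of a multi-site Hispanic/Latino community
cohort: an additive polygenic architecture for adult height with full-sib
family relatedness, household and census-block clustering, sex-specific
height distributions, a secular (birth-cohort) height trend, age-related
height loss after 60, childhood socioeconomic-position (SEP) effects on the
environmental component of height, cardiovascular-health raw inputs and
cognitive test scores coupled to that environmental component, and a
stratified two-stage survey design with unequal sampling weights.

Every draw flows from a single :class:`numpy.random.Generator` seeded by
``SimParams.seed``, so identical parameters yield byte-identical output.
A :class:`TruthTable` records each participant's latent components, enabling
parameter-recovery tests downstream (heritability, residual validity,
association direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, DesignError

EDUC_LEVELS = ["elementary", "middle", "high", "college"]
MIGRATION_LEVELS = ["19+", "13-18", "0-12", "US born"]  # increasing childhood SEP
NICOTINE_LEVELS = ["never", "quit_5y+", "quit_1_5y", "quit_<1y", "current"]
HISPANIC_BACKGROUNDS = [
    "Dominican", "Central American", "Cuban", "Mexican",
    "Puerto Rican", "South American", "More than one",
]
# Marginal category frequencies mirroring a large US Hispanic/Latino cohort.
_PAT_EDUC_P = [0.417, 0.131, 0.260, 0.192]
_MAT_EDUC_P = [0.415, 0.138, 0.279, 0.168]
_MIGRATION_P = [0.557, 0.105, 0.106, 0.231]
_HISPANIC_P = [0.101, 0.073, 0.222, 0.352, 0.160, 0.050, 0.042]


@dataclass
class SimParams:
    """Parameters of the synthetic cohort.

    Variance-fraction parameters (``h2_true``, ``var_household``,
    ``var_block``) are shares of the unit-variance latent height scale; the
    residual noise share is whatever remains after also accounting for the
    SEP, birth-cohort-trend and age-loss components, so total latent variance
    is ~1 and empirical component shares match their targets.
    """

    n_participants: int = 2000
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_families: int = 200
    sibs_per_family: int = 2
    h2_true: float = 0.53
    var_household: float = 0.05
    var_block: float = 0.05
    sep_effect_sd: float = 0.04          # height SD per SEP ordinal unit
    cohort_trend_sd_per_decade: float = 0.15
    height_loss_per_year_after60: float = 0.1   # cm/year
    sex_height_mean_f: float = 156.6
    sex_height_sd_f: float = 6.5
    sex_height_mean_m: float = 169.7
    sex_height_sd_m: float = 7.0
    n_strata: int = 8
    psus_per_stratum: int = 4
    weight_range: tuple[float, float] = (0.5, 4.0)
    reference_year: int = 2009
    cog_env_slope: float = 0.15          # cognition z per SD of environment
    informative_weights: bool = False
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = dict(n_participants=self.n_participants, n_snps=self.n_snps,
                      n_families=self.n_families,
                      sibs_per_family=self.sibs_per_family,
                      n_strata=self.n_strata,
                      psus_per_stratum=self.psus_per_stratum)
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise InvalidParameterError(f"{name} must be a count >= 1, got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidParameterError(
                f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("h2_true", "var_household", "var_block"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise InvalidParameterError(f"{name} must be in [0,1), got {v}")
        if self.h2_true + self.var_household + self.var_block >= 1.0:
            raise InvalidParameterError(
                "variance fractions h2_true + var_household + var_block must sum to < 1")
        if self.n_families * self.sibs_per_family > self.n_participants:
            raise InvalidParameterError(
                "n_families * sibs_per_family exceeds n_participants")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidParameterError("missing_rate must be in [0,1)")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        for k in ("maf_range", "weight_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GenotypeMatrix:
    """n x m dosage matrix with SNP metadata; dosage counts ``allele1``."""

    dosages: np.ndarray                  # float64, values in [0,2]
    snp_meta: pd.DataFrame               # variant_id, chrom, pos, allele1, allele2, freq
    ids: np.ndarray                      # participant ids, row order
    family_id: np.ndarray | None = None  # kinship block structure; -1 = unrelated

    @property
    def n(self):
        return self.dosages.shape[0]

    @property
    def m(self):
        return self.dosages.shape[1]

    def write_tsv(self, dosage_path, meta_path):
        df = pd.DataFrame(self.dosages, columns=self.snp_meta["variant_id"])
        df.insert(0, "id", self.ids)
        df.to_csv(dosage_path, sep="\t", index=False)
        self.snp_meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, dosage_path, meta_path):
        df = pd.read_csv(dosage_path, sep="\t")
        meta = pd.read_csv(meta_path, sep="\t")
        ids = df["id"].to_numpy()
        dos = df.drop(columns="id").to_numpy(float)
        return cls(dosages=dos, snp_meta=meta, ids=ids)


@dataclass
class TruthTable:
    """Latent generative components per participant plus simulation constants."""

    table: pd.DataFrame
    snp_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    couplings: dict = field(default_factory=dict)

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(params: SimParams) -> GenotypeMatrix:
    """Simulate unlinked biallelic dosages with full-sib family blocks.

    The first ``n_families * sibs_per_family`` participants are full sibs in
    families of size ``sibs_per_family`` (two unobserved founder parents per
    family; each child inherits one haplotype per parent per SNP), giving an
    expected within-family GRM relatedness of 0.5. Remaining participants are
    unrelated founders drawn from Hardy-Weinberg proportions.
    """
    if params.n_snps < 1:
        raise InvalidParameterError("n_snps must be >= 1")
    rng = np.random.default_rng(params.seed)
    n, m = params.n_participants, params.n_snps
    p = rng.uniform(params.maf_range[0], params.maf_range[1], size=m)

    n_rel = params.n_families * params.sibs_per_family
    dos = np.empty((n, m), dtype=np.float64)
    fam = np.full(n, -1, dtype=np.int64)

    # parental haplotypes: (families, 4 haplotypes, snps)
    hap = (rng.random((params.n_families, 4, m)) < p).astype(np.float64)
    for s in range(params.sibs_per_family):
        pick_pat = (rng.random((params.n_families, m)) < 0.5)
        pick_mat = (rng.random((params.n_families, m)) < 0.5)
        pat = np.where(pick_pat, hap[:, 0, :], hap[:, 1, :])
        mat = np.where(pick_mat, hap[:, 2, :], hap[:, 3, :])
        rows = np.arange(params.n_families) * params.sibs_per_family + s
        dos[rows] = pat + mat
        fam[rows] = np.arange(params.n_families)

    if n > n_rel:
        dos[n_rel:] = rng.binomial(2, p, size=(n - n_rel, m)).astype(np.float64)

    bases = np.array(list("ACGT"))
    a1 = rng.integers(0, 4, size=m)
    a2 = (a1 + rng.integers(1, 4, size=m)) % 4
    meta = pd.DataFrame({
        "variant_id": [f"rs{j + 1}" for j in range(m)],
        "chrom": rng.integers(1, 23, size=m),
        "pos": np.sort(rng.integers(1, 10**8, size=m)),
        "allele1": bases[a1],
        "allele2": bases[a2],
        "freq": p,
    })
    ids = np.array([f"P{i + 1:06d}" for i in range(n)])
    return GenotypeMatrix(dosages=dos, snp_meta=meta, ids=ids, family_id=fam)


# ---------------------------------------------------------------------------
# phenotypes

def _scale_to_var(x, target_var):
    """Rescale a centered draw to an exact empirical variance."""
    sd = x.std()
    if sd == 0 or target_var == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd * np.sqrt(target_var)


def _ordinal_cut(latent, probs, rng, noise_sd=1.0):
    """Cut `latent + noise` at its own quantiles to hit marginal `probs`.

    Category means are monotone in the latent by construction.
    """
    z = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    cuts = np.quantile(z, np.cumsum(probs)[:-1])
    return np.searchsorted(cuts, z, side="right")


def simulate_phenotypes(genotypes: GenotypeMatrix, params: SimParams):
    """Generate phenotypes, SEP covariates, LE8 inputs and cognition scores.

    Height (in cm) is ``sex_mean + sex_sd * latent`` where the unit-variance
    latent sums genetic, household, block, SEP, birth-cohort trend, age-loss
    and noise components. Genetic, household and block draws are empirically
    rescaled to their exact target variance shares; the noise share is the
    remainder after the SEP/trend/age-loss variance, so the decomposition is
    exact in-sample. Returns ``(CohortTable, TruthTable)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n, m = genotypes.n, genotypes.m
    fam = genotypes.family_id
    if fam is None:
        fam = np.full(n, -1, dtype=np.int64)

    # demographics
    age = rng.integers(18, 75, size=n).astype(float)
    birth_year = params.reference_year - age
    sex = np.where(rng.random(n) < 0.511, "F", "M")
    sex_mean = np.where(sex == "F", params.sex_height_mean_f, params.sex_height_mean_m)
    sex_sd = np.where(sex == "F", params.sex_height_sd_f, params.sex_height_sd_m)

    # households: sib groups co-housed with prob 0.5, everyone else in
    # households of size 1-3; households nested in census blocks of ~5
    household = np.full(n, -1, dtype=np.int64)
    next_hh = 0
    for f in np.unique(fam[fam >= 0]):
        members = np.where(fam == f)[0]
        if rng.random() < 0.5:
            household[members] = next_hh
            next_hh += 1
        else:
            for i in members:
                household[i] = next_hh
                next_hh += 1
    singles = np.where(household < 0)[0]
    rng.shuffle(singles)
    i = 0
    while i < len(singles):
        size = int(rng.integers(1, 4))
        household[singles[i:i + size]] = next_hh
        next_hh += 1
        i += size
    n_hh = next_hh
    hh_to_block = np.repeat(np.arange((n_hh + 4) // 5), 5)[:n_hh]
    rng.shuffle(hh_to_block)
    block = hh_to_block[household]
    n_blk = int(block.max()) + 1

    # genetic value: all SNPs causal, effects iid normal on the standardized
    # dosage scale, rescaled to the exact h2 share
    p_hat = genotypes.snp_meta["freq"].to_numpy()
    u = rng.normal(0.0, 1.0, size=m)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (genotypes.dosages - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    z = np.nan_to_num(z)
    g = _scale_to_var(z @ u, params.h2_true)

    hh_eff = _scale_to_var(rng.normal(0.0, 1.0, size=n_hh)[household], params.var_household)
    blk_eff = _scale_to_var(rng.normal(0.0, 1.0, size=n_blk)[block], params.var_block)

    # childhood SEP: a family-level latent drives all SEP covariates so that
    # category means are monotone in the realized environment
    fam_lat = rng.normal(0.0, 1.0, size=params.n_families + n)
    sep_lat = np.where(fam >= 0, fam_lat[np.maximum(fam, 0)],
                       fam_lat[params.n_families + np.arange(n)])
    pat_educ = _ordinal_cut(sep_lat, _PAT_EDUC_P, rng)
    mat_educ = _ordinal_cut(sep_lat, _MAT_EDUC_P, rng)
    mig = _ordinal_cut(sep_lat, _MIGRATION_P, rng)
    hardship_0_12 = _ordinal_cut(sep_lat, [0.463, 0.537], rng) == 0
    hardship_13_18 = _ordinal_cut(sep_lat, [0.381, 0.619], rng) == 0
    no_plumbing = _ordinal_cut(sep_lat, [0.176, 0.824], rng) == 0
    no_sewer = _ordinal_cut(sep_lat, [0.174, 0.826], rng) == 0
    no_electricity = _ordinal_cut(sep_lat, [0.096, 0.904], rng) == 0
    no_phone = _ordinal_cut(sep_lat, [0.428, 0.572], rng) == 0

    par_educ = np.maximum(pat_educ, mat_educ)
    sep_units = par_educ + mig
    sep_comp = params.sep_effect_sd * (sep_units - sep_units.mean())

    trend = params.cohort_trend_sd_per_decade * (birth_year - birth_year.mean()) / 10.0
    ageloss = -params.height_loss_per_year_after60 * np.maximum(age - 60.0, 0.0) / sex_sd

    extra = sep_comp + trend + ageloss
    var_e = 1.0 - params.h2_true - params.var_household - params.var_block - extra.var()
    if var_e <= 0:
        raise InvalidParameterError(
            "variance fractions plus SEP/trend/age-loss variance sum to >= 1; "
            "reduce h2_true/var_household/var_block or the trend/SEP effects")
    noise = _scale_to_var(rng.normal(0.0, 1.0, size=n), var_e)

    latent = g + hh_eff + blk_eff + extra + noise
    height_cm = sex_mean + sex_sd * latent
    env = latent - g  # full non-genetic remainder, in SD units

    # LE8 raw inputs, linearly coupled to the environmental component
    cpl = {
        "bmi_per_env": -1.0, "non_hdl_per_env": -6.0, "glucose_per_env": -3.0,
        "hba1c_per_env": -0.1, "sbp_per_env": -3.0, "dbp_per_env": -1.5,
        "diet_per_env": 4.0, "log_pa_per_env": 0.3, "sleep_per_env": 0.2,
        "cog_z_per_env": params.cog_env_slope,
    }
    older = np.maximum(age - 45.0, 0.0)
    bmi = 29.0 + cpl["bmi_per_env"] * env + rng.normal(0, 4.0, n)
    bmi = np.clip(bmi, 15.0, 60.0)
    non_hdl = 145.0 + cpl["non_hdl_per_env"] * env + 0.5 * older + rng.normal(0, 28.0, n)
    lipid_med = rng.random(n) < np.where(age >= 45, 0.15, 0.04)
    glucose = 98.0 + cpl["glucose_per_env"] * env + 0.35 * older + rng.normal(0, 14.0, n)
    hba1c = 5.6 + cpl["hba1c_per_env"] * env + 0.012 * older + rng.normal(0, 0.5, n)
    glucose_med = rng.random(n) < np.where(age >= 45, 0.14, 0.03)
    sbp = 121.0 + cpl["sbp_per_env"] * env + 0.45 * older + rng.normal(0, 12.0, n)
    dbp = 74.0 + cpl["dbp_per_env"] * env + 0.1 * older + rng.normal(0, 8.0, n)
    bp_med = rng.random(n) < np.where(age >= 45, 0.22, 0.05)
    diet = np.clip(35.0 + cpl["diet_per_env"] * env + rng.normal(0, 8.0, n), 0.0, 80.0)
    pa_minutes = np.exp(4.0 + cpl["log_pa_per_env"] * env + rng.normal(0, 1.0, n))
    pa_minutes = np.clip(pa_minutes, 0.0, 2500.0)
    zero_pa = rng.random(n) < 0.15
    pa_minutes[zero_pa] = 0.0
    nic = _ordinal_cut(-env, [0.60, 0.12, 0.05, 0.03, 0.20], rng, noise_sd=3.0)
    nicotine_status = np.array(NICOTINE_LEVELS, dtype=object)[nic]
    sleep = np.clip(7.3 + cpl["sleep_per_env"] * env + rng.normal(0, 1.2, n), 3.0, 12.0)

    # cognition raw scores: z-scale coupling cog_env_slope, unit residual sd
    def cog_raw(mean, sd):
        return mean + sd * (cpl["cog_z_per_env"] * env + rng.normal(0, 1.0, n))

    sis = np.clip(np.round(cog_raw(4.8, 1.2)), 0, 6)
    bsevlt_sum = np.clip(cog_raw(28.0, 6.0), 0, 45)
    bsevlt_recall = np.clip(cog_raw(9.0, 3.0), 0, 15)
    word_fluency = np.clip(cog_raw(17.0, 6.0), 0, None)
    dss = np.clip(cog_raw(33.0, 12.0), 0, None)

    years_in_us = np.where(mig == 3, age,
                           np.maximum(age - np.array([25.0, 16.0, 6.0, 0.0])[np.minimum(mig, 2)],
                                      0.0))
    income_band = _ordinal_cut(sep_lat + rng.normal(0, 1, n), [0.3, 0.3, 0.2, 0.2], rng)
    own_educ = _ordinal_cut(0.5 * sep_lat, [0.3, 0.2, 0.3, 0.2], rng)
    hb = rng.choice(len(HISPANIC_BACKGROUNDS), size=n, p=_HISPANIC_P)

    cohort = pd.DataFrame({
        "id": genotypes.ids,
        "sex": sex,
        "age": age,
        "birth_year": birth_year,
        "height_cm": height_cm,
        "household_id": household,
        "block_id": block,
        "stratum": -1,
        "psu": -1,
        "weight": 1.0,
        "center": block % 4,
        "paternal_educ": np.array(EDUC_LEVELS, dtype=object)[pat_educ],
        "maternal_educ": np.array(EDUC_LEVELS, dtype=object)[mat_educ],
        "us_born_migration": np.array(MIGRATION_LEVELS, dtype=object)[mig],
        "hardship_0_12": np.where(hardship_0_12, "yes", "no"),
        "hardship_13_18": np.where(hardship_13_18, "yes", "no"),
        "plumbing": np.where(no_plumbing, "no", "yes"),
        "sewer": np.where(no_sewer, "no", "yes"),
        "electricity": np.where(no_electricity, "no", "yes"),
        "phone": np.where(no_phone, "no", "yes"),
        "bmi": bmi,
        "non_hdl_mgdl": non_hdl,
        "lipid_med": np.where(lipid_med, "yes", "no"),
        "fasting_glucose_mgdl": glucose,
        "hba1c_pct": hba1c,
        "glucose_med": np.where(glucose_med, "yes", "no"),
        "sbp_mmhg": sbp,
        "dbp_mmhg": dbp,
        "bp_med": np.where(bp_med, "yes", "no"),
        "diet_score": diet,
        "pa_minutes": pa_minutes,
        "nicotine_status": nicotine_status,
        "sleep_hours": sleep,
        "sis": sis,
        "bsevlt_sum": bsevlt_sum,
        "bsevlt_recall": bsevlt_recall,
        "word_fluency": word_fluency,
        "dss": dss,
        "education": np.array(EDUC_LEVELS, dtype=object)[own_educ],
        "insurance": np.where(rng.random(n) < 0.5, "yes", "no"),
        "income_band": income_band,
        "marital_status": rng.choice(["single", "married", "other"], size=n,
                                     p=[0.3, 0.55, 0.15]),
        "language_pref": np.where(rng.random(n) < 0.77, "Spanish", "English"),
        "years_in_us": years_in_us,
        "hispanic_background": np.array(HISPANIC_BACKGROUNDS, dtype=object)[hb],
    })

    if params.missing_rate > 0:
        maskable = ["paternal_educ", "maternal_educ", "hardship_0_12",
                    "hardship_13_18", "plumbing", "sewer", "electricity", "phone",
                    "bmi", "non_hdl_mgdl", "fasting_glucose_mgdl", "hba1c_pct",
                    "sbp_mmhg", "dbp_mmhg", "diet_score", "pa_minutes",
                    "sleep_hours", "sis", "bsevlt_sum", "bsevlt_recall",
                    "word_fluency", "dss"]
        for col in maskable:
            hit = rng.random(n) < params.missing_rate
            cohort.loc[hit, col] = np.nan

    truth = TruthTable(
        table=pd.DataFrame({
            "id": genotypes.ids,
            "true_genetic_value": g,
            "true_env_sep_component": sep_comp,
            "true_household_effect": hh_eff,
            "true_block_effect": blk_eff,
            "true_trend_component": trend,
            "true_ageloss_component": ageloss,
            "true_noise": noise,
            "true_nongenetic": env,
        }),
        snp_effects=u,
        couplings=cpl,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# survey design

def assign_survey_design(cohort: pd.DataFrame, params: SimParams,
                         truth: TruthTable | None = None) -> pd.DataFrame:
    """Assign (stratum, psu, weight) by census-block geography, in place.

    Blocks are partitioned into ``n_strata`` strata and, within each stratum,
    into ``psus_per_stratum`` PSUs, so clustering follows geography as in a
    two-stage area sample. Weights are uniform draws from ``weight_range``;
    with ``informative_weights`` they are additionally tilted by the block
    effect (correlation recorded in the truth table couplings) to mimic
    informative sampling. Returns the cohort with design columns filled.
    """
    if params.psus_per_stratum < 2:
        raise DesignError("psus_per_stratum must be >= 2 for variance estimation")
    n_cells = params.n_strata * params.psus_per_stratum
    if n_cells > len(cohort):
        raise InvalidParameterError("more design cells than participants")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    blocks = np.sort(cohort["block_id"].unique())
    if len(blocks) < n_cells:
        raise DesignError(
            f"need >= {n_cells} blocks to fill {params.n_strata} strata x "
            f"{params.psus_per_stratum} PSUs, have {len(blocks)}")
    stratum_of_block = np.array_split(blocks, params.n_strata)
    b2s, b2p = {}, {}
    for s, blk_group in enumerate(stratum_of_block):
        psus = np.array_split(blk_group, params.psus_per_stratum)
        for p_idx, psu_blocks in enumerate(psus):
            for b in psu_blocks:
                b2s[b] = s
                b2p[b] = p_idx
    cohort["stratum"] = cohort["block_id"].map(b2s).astype(int)
    cohort["psu"] = cohort["block_id"].map(b2p).astype(int)
    w = rng.uniform(params.weight_range[0], params.weight_range[1], size=len(cohort))
    if params.informative_weights and truth is not None:
        blk = truth.table["true_block_effect"].to_numpy()
        w = w * np.exp(1.5 * blk)
        truth.couplings["weight_block_corr"] = float(np.corrcoef(w, blk)[0, 1])
    elif params.informative_weights:
        raise InvalidParameterError("informative_weights requires the truth table")
    cohort["weight"] = w
    return cohort


def weight_table_from_truth(genotypes: GenotypeMatrix, truth: TruthTable) -> pd.DataFrame:
    """PLINK-style weight table whose score is collinear with the true
    genetic value (the generator's causal effects on the dosage scale)."""
    p = genotypes.snp_meta["freq"].to_numpy()
    w = truth.snp_effects / np.sqrt(2 * p * (1 - p))
    return pd.DataFrame({
        "variant_id": genotypes.snp_meta["variant_id"],
        "effect_allele": genotypes.snp_meta["allele1"],
        "other_allele": genotypes.snp_meta["allele2"],
        "weight": w,
    })


def simulate_cohort(params: SimParams):
    """Convenience wrapper: genotypes + phenotypes + survey design.

    Returns ``(genotypes, cohort, truth)``.
    """
    geno = simulate_genotypes(params)
    cohort, truth = simulate_phenotypes(geno, params)
    assign_survey_design(cohort, params, truth)
    return geno, cohort, truth
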