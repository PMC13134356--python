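import numpy as np
import pandas as pd
import pytest

import heightrez as hr


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic cohort shared by read-only tests."""
    params = hr.SimParams(n_participants=600, n_snps=250, n_families=120,
                          seed=20240901)
    geno, cohort, truth = hr.simulate_cohort(params)
    return params, geno, cohort, truth


@pytest.fixture(scope="session")
def small_grm(small_sim):
    _, geno, _, _ = small_sim
    g, ids = hr.compute_grm(geno)
    return g, ids


def jackknife_psu_mean_se(x, design):
    """Delete-one-PSU jackknife SE of the weighted mean (test oracle)."""
    x = np.asarray(x, float)
    strata = np.asarray(design.stratum)
    psus = np.asarray(design.psu)
    w = np.asarray(design.weight, float)
    var = 0.0
    for s in np.unique(strata):
        in_s = strata == s
        psu_ids = np.unique(psus[in_s])
        nh = len(psu_ids)
        reps = []
        for drop in psu_ids:
            keep = ~(in_s & (psus == drop))
            wk = w.copy()
            wk[in_s & keep] *= nh / (nh - 1)
            reps.append(np.sum(wk[keep] * x[keep]) / np.sum(wk[keep]))
        reps = np.array(reps)
        var += (nh - 1) / nh * np.sum((reps - reps.mean()) ** 2)
    return np.sqrt(var)


def jackknife_psu_lm_se(y, X, design):
    """Delete-one-PSU jackknife SEs of weighted LS coefficients (oracle)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    strata = np.asarray(design.stratum)
    psus = np.asarray(design.psu)
    w = np.asarray(design.weight, float)

    def wls(wvec):
        xw = X * wvec[:, None]
        return np.linalg.solve(xw.T @ X, xw.T @ y)

    var = np.zeros(X.shape[1])
    for s in np.unique(strata):
        in_s = strata == s
        psu_ids = np.unique(psus[in_s])
        nh = len(psu_ids)
        reps = []
        for drop in psu_ids:
            wk = w.copy()
            wk[in_s & (psus == drop)] = 0.0
            wk[in_s & (psus != drop)] *= nh / (nh - 1)
            reps.append(wls(wk))
        reps = np.array(reps)
        var += (nh - 1) / nh * np.sum((reps - reps.mean(axis=0)) ** 2, axis=0)
    return np.sqrt(var)


def random_survey_design(rng, n_strata=2, psus_per_stratum=3, per_psu=4,
                         slope=1.0):
    """Small random stratified design with a known regression slope."""
    rows = []
    for s in range(n_strata):
        u_s = rng.normal(0, 0.3)
        for p in range(psus_per_stratum):
            u_p = rng.normal(0, 0.5)
            for _ in range(per_psu):
                x = rng.normal()
                y = 1.0 + slope * x + u_s + u_p + rng.normal()
                rows.append((s, p, rng.uniform(0.5, 2.0), x, y))
    df = pd.DataFrame(rows, columns=["stratum", "psu", "weight", "x", "y"])
    design = hr.SurveyDesign(df["stratum"].to_numpy(), df["psu"].to_numpy(),
                             df["weight"].to_numpy())
    return df, design
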