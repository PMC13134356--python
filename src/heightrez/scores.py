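"""Life's Essential 8 cardiovascular-health scores and cognitive composites.

Each CVH component maps raw clinical or behavioural inputs to 0-100 points
(higher = better health) through an externalized JSON rubric; the overall
health-domain score is the arithmetic mean of the four health-factor scores
(BMI, lipids, glucose, blood pressure) among participants with complete
information on all four. The rubric is validated at load time: numeric bands
must tile the real line without gaps or overlaps and every points value must
lie in [0, 100].

Cognitive composites: the five neurocognitive tests (SIS mental-status
screener, B-SEVLT learning and recall, word fluency, digit-symbol
substitution) are z-standardized within the cognition-eligible subsample
(age >= 45); global cognition is the standardized mean of the four non-SIS
z-scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DataError, RubricError

HEALTH_FACTORS = ["bmi_score", "lipid_score", "glucose_score", "bp_score"]
BEHAVIORS = ["diet_score_cvh", "pa_score", "nicotine_score", "sleep_score"]
COGNITIVE_TESTS = ["sis", "bsevlt_sum", "bsevlt_recall", "word_fluency", "dss"]
GLOBAL_COGNITION_TESTS = ["bsevlt_sum", "bsevlt_recall", "word_fluency", "dss"]


def _validate_bands(bands, where):
    if not bands:
        raise RubricError(f"{where}: empty band list")
    lo0 = bands[0][0]
    if lo0 is not None:
        raise RubricError(f"{where}: first band must be unbounded below")
    if bands[-1][1] is not None:
        raise RubricError(f"{where}: last band must be unbounded above")
    for k, (lo, hi, pts) in enumerate(bands):
        if not (0 <= pts <= 100):
            raise RubricError(f"{where}: points {pts} outside [0,100]")
        if k > 0 and lo != bands[k - 1][1]:
            raise RubricError(
                f"{where}: bands must tile contiguously; gap/overlap at band {k}")
        if lo is not None and hi is not None and not lo < hi:
            raise RubricError(f"{where}: band {k} has low >= high")


def _band_points(x, bands):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    for lo, hi, pts in bands:
        if (lo is None or x >= lo) and (hi is None or x < hi):
            return float(pts)
    raise RubricError(f"no band matched value {x}")  # unreachable if validated


def _yes(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return str(v).strip().lower() in {"yes", "y", "true", "1"}


@dataclass
class ScoreRubric:
    """Validated component-scoring rubric loaded from JSON."""

    spec: dict
    glucose_precedence: tuple = ("medication", "hba1c", "fbg")

    def __post_init__(self):
        for comp in ("bmi", "lipid", "diet", "pa", "sleep"):
            _validate_bands(self.spec[comp]["bands"], comp)
        _validate_bands(self.spec["bp"]["sbp_bands"], "bp.sbp")
        _validate_bands(self.spec["bp"]["dbp_bands"], "bp.dbp")
        g = self.spec["glucose"]
        for key in ("nondiabetic_fbg_bands", "nondiabetic_hba1c_bands",
                    "diabetic_hba1c_bands"):
            _validate_bands(g[key], f"glucose.{key}")
        for cat, pts in self.spec["nicotine"]["categories"].items():
            if not (0 <= pts <= 100):
                raise RubricError(f"nicotine category {cat!r}: points outside [0,100]")

    @classmethod
    def default(cls) -> "ScoreRubric":
        text = resources.files("heightrez").joinpath("data/le8_rubric.json").read_text()
        return cls(json.loads(text))

    @classmethod
    def from_json(cls, path) -> "ScoreRubric":
        with open(path) as fh:
            return cls(json.load(fh))

    # -- per-component scorers ------------------------------------------------

    def score_banded(self, component, value, on_medication=None):
        """Score a simple banded component, with optional medication penalty."""
        comp = self.spec[component]
        pts = _band_points(value, comp["bands"])
        if np.isnan(pts):
            return np.nan
        if on_medication and "med_penalty" in comp:
            pts = max(pts - comp["med_penalty"], 0.0)
        return pts

    def score_bp(self, sbp, dbp, on_medication=None):
        comp = self.spec["bp"]
        s = _band_points(sbp, comp["sbp_bands"])
        d = _band_points(dbp, comp["dbp_bands"])
        if np.isnan(s) or np.isnan(d):
            return np.nan
        pts = min(s, d)
        if on_medication:
            pts = max(pts - comp["med_penalty"], 0.0)
        return pts

    def score_glucose(self, fbg, hba1c, on_medication=None):
        """Glucose CVH: diabetes-status rule first, then HbA1c, then FBG.

        Diabetic (medication, or FBG/HbA1c over the diagnostic cut) scores by
        HbA1c control bands; if HbA1c is unavailable for a diabetic the score
        is missing. Non-diabetics score by FBG bands, falling back to HbA1c
        bands when FBG is missing.
        """
        g = self.spec["glucose"]
        fbg_na = fbg is None or (isinstance(fbg, float) and np.isnan(fbg))
        a1c_na = hba1c is None or (isinstance(hba1c, float) and np.isnan(hba1c))
        diabetic = bool(on_medication)
        if not diabetic and not fbg_na and fbg >= g["diabetes_if"]["fbg_at_least"]:
            diabetic = True
        if not diabetic and not a1c_na and hba1c >= g["diabetes_if"]["hba1c_at_least"]:
            diabetic = True
        if diabetic:
            if a1c_na:
                return np.nan
            return _band_points(hba1c, g["diabetic_hba1c_bands"])
        if not fbg_na:
            return _band_points(fbg, g["nondiabetic_fbg_bands"])
        if not a1c_na:
            return _band_points(hba1c, g["nondiabetic_hba1c_bands"])
        return np.nan

    def score_nicotine(self, status):
        if status is None or (isinstance(status, float) and np.isnan(status)):
            return np.nan
        cats = self.spec["nicotine"]["categories"]
        if status not in cats:
            raise DataError(f"unknown nicotine_status {status!r}")
        return float(cats[status])


def score_component(component, inputs, rubric: ScoreRubric | None = None):
    """Score one CVH component from a dict/Series of raw inputs.

    ``component`` is one of bmi, lipid, glucose, bp, diet, pa, nicotine,
    sleep. Missing required inputs yield a missing score, never an error.
    """
    rubric = rubric or ScoreRubric.default()
    get = inputs.get if hasattr(inputs, "get") else inputs.__getitem__
    if component == "bmi":
        return rubric.score_banded("bmi", get("bmi"))
    if component == "lipid":
        return rubric.score_banded("lipid", get("non_hdl_mgdl"),
                                   _yes(get("lipid_med")))
    if component == "glucose":
        return rubric.score_glucose(get("fasting_glucose_mgdl"),
                                    get("hba1c_pct"), _yes(get("glucose_med")))
    if component == "bp":
        return rubric.score_bp(get("sbp_mmhg"), get("dbp_mmhg"),
                               _yes(get("bp_med")))
    if component == "diet":
        return rubric.score_banded("diet", get("diet_score"))
    if component == "pa":
        return rubric.score_banded("pa", get("pa_minutes"))
    if component == "nicotine":
        return rubric.score_nicotine(get("nicotine_status"))
    if component == "sleep":
        return rubric.score_banded("sleep", get("sleep_hours"))
    raise DataError(f"unknown component {component!r}")


def health_domain_score(bmi_score, lipid_score, glucose_score, bp_score):
    """Mean of the four health-factor scores; missing if any is missing."""
    vals = np.array([bmi_score, lipid_score, glucose_score, bp_score], dtype=float)
    if np.isnan(vals).any():
        return np.nan
    return float(vals.mean())


def compute_cvh_scores(cohort: pd.DataFrame,
                       rubric: ScoreRubric | None = None) -> pd.DataFrame:
    """All eight component scores plus the health-domain score, per participant."""
    rubric = rubric or ScoreRubric.default()
    out = pd.DataFrame({"id": cohort["id"].to_numpy()})
    comps = {"bmi_score": "bmi", "lipid_score": "lipid",
             "glucose_score": "glucose", "bp_score": "bp",
             "diet_score_cvh": "diet", "pa_score": "pa",
             "nicotine_score": "nicotine", "sleep_score": "sleep"}
    for col, comp in comps.items():
        out[col] = [score_component(comp, row, rubric)
                    for _, row in cohort.iterrows()]
    out["health_domain_score"] = [
        health_domain_score(b, l, g, p)
        for b, l, g, p in zip(out["bmi_score"], out["lipid_score"],
                              out["glucose_score"], out["bp_score"])]
    return out


def cognition_composites(cohort: pd.DataFrame, min_age: float = 45.0) -> pd.DataFrame:
    """Z-scores of the five cognitive tests and global cognition.

    Standardization (mean/SD, ddof=1) uses the eligible subsample
    (age >= ``min_age``); younger participants get missing values on every
    cognition field. Global cognition is the mean of the four non-SIS
    z-scores (complete cases), re-standardized within the eligible sample.
    """
    eligible = cohort["age"].to_numpy(float) >= min_age
    if eligible.sum() < 2:
        raise DataError("cognition-eligible subsample has < 2 members")
    out = pd.DataFrame({"id": cohort["id"].to_numpy()})
    zcols = {}
    for test in COGNITIVE_TESTS:
        x = cohort[test].to_numpy(float)
        ref = x[eligible & np.isfinite(x)]
        if len(ref) < 2 or ref.std(ddof=1) == 0:
            raise DataError(f"cannot standardize {test}: eligible sample degenerate")
        z = (x - ref.mean()) / ref.std(ddof=1)
        z[~eligible] = np.nan
        zcols[test] = z
        out[f"{test}_z"] = z
    # plain row mean: any missing test leaves global cognition missing
    avg = np.column_stack([zcols[t] for t in GLOBAL_COGNITION_TESTS]).mean(axis=1)
    ref = avg[eligible & np.isfinite(avg)]
    gc = (avg - ref.mean()) / ref.std(ddof=1)
    gc[~eligible] = np.nan
    out["global_cognition"] = gc
    return out
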