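"""Author the packaged default model-spec JSON files and reference CSVs.

Intercepts are computed so that each dynamic-factor model is approximately
stationary at the default marginal means (equilibrium covariate effects are
converted to raw coefficients via beta = effect * (1 - rho_lag - rho_mean)).
Run from the repo root: python scripts/author_default_models.py
"""

import json
import math
from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "chronosim" / "data"
MODELS = DATA / "models"
MODELS.mkdir(parents=True, exist_ok=True)

logit = lambda p: math.log(p / (1 - p))

MEANS = {
    "age": 45.9,
    "sex_male": 0.483,
    "race_nh_black": 0.115,
    "race_hispanic": 0.136,
    "race_other": 0.065,
    "smoking_current": 0.20,
    "bmi": 28.5,
    "log_sbp": math.log(122.0),
    "log_dbp": math.log(72.0),
    "sbp": 122.0,
    "dbp": 72.0,
    "total_chol": 196.0,
    "trig": 130.0,
    "ldl": 115.0,
    "hdl": 53.0,
    "a1c": 5.6,
    "waist": 97.0,
    "physical_activity": 5.0,
    "statin": 0.16,
    "other_lipid_agent": 0.05,
}

RHO_LAG, RHO_MEAN = 0.70, 0.28
S = 1.0 - RHO_LAG - RHO_MEAN  # equilibrium shrinkage


def cov_mean(name):
    for prefix in ("lagmean_", "lag_"):
        if name.startswith(prefix):
            name = name[len(prefix):]
    return MEANS[name]


def kind_for(name):
    if name.startswith(("sex_", "race_", "education_")):
        return "static"
    if name.startswith("smoking_"):
        return "indicator"
    if name.startswith("lagmean_"):
        return "lagged_mean"
    return "lagged"


def write(name, payload):
    with open(MODELS / f"{name}.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    print("wrote", name)


def factor_spec(outcome, mu, sigma, effects, log_outcome=False):
    """Continuous dynamic-factor spec with stationarity-consistent intercept."""
    target = math.log(MEANS[outcome]) if log_outcome else MEANS[outcome]
    lag_name = f"lag_log_{outcome}" if log_outcome else f"lag_{outcome}"
    mean_name = f"lagmean_log_{outcome}" if log_outcome else f"lagmean_{outcome}"
    coeffs = {lag_name: RHO_LAG, mean_name: RHO_MEAN}
    intercept = S * target
    for cov, eff in effects.items():
        beta = eff * S
        coeffs[cov] = beta
        intercept -= beta * cov_mean(cov)
    coeffs["intercept"] = intercept
    return {
        "name": outcome,
        "family": "linear",
        "outcome": outcome,
        "coefficients": coeffs,
        "residual": {"mean": 0.0, "sd": sigma},
        "transform": "log-outcome" if log_outcome else "none",
        "covariate_kinds": {c: kind_for(c) for c in coeffs if c != "intercept"},
    }


# equilibrium effects (outcome units per covariate unit, about covariate means)
factor_defs = {
    "sbp": dict(mu=122.0, sigma=0.025, log=True,
                effects={"age": 0.0033, "sex_male": 0.02, "race_nh_black": 0.03,
                         "smoking_current": 0.01, "lag_bmi": 0.004}),
    "dbp": dict(mu=72.0, sigma=0.025, log=True,
                effects={"age": -0.001, "sex_male": 0.01, "lag_bmi": 0.003}),
    "total_chol": dict(mu=196.0, sigma=8.0, log=False,
                       effects={"age": 0.3, "sex_male": -5.0, "lag_bmi": 0.5}),
    "trig": dict(mu=130.0, sigma=18.0, log=False,
                 effects={"age": 0.5, "sex_male": 15.0, "lag_bmi": 2.0}),
    "ldl": dict(mu=115.0, sigma=7.0, log=False,
                effects={"age": 0.2, "sex_male": -2.0, "lag_bmi": 0.4}),
    "hdl": dict(mu=53.0, sigma=3.0, log=False,
                effects={"sex_male": -8.0, "lag_bmi": -0.4, "smoking_current": -3.0}),
    "a1c": dict(mu=5.6, sigma=0.18, log=False,
                effects={"age": 0.01, "lag_bmi": 0.03, "race_nh_black": 0.2}),
    "bmi": dict(mu=28.5, sigma=1.3, log=False, effects={"age": 0.02}),
    "waist": dict(mu=97.0, sigma=3.2, log=False,
                  effects={"lag_bmi": 2.0, "age": 0.1, "sex_male": 8.0}),
    "physical_activity": dict(mu=5.0, sigma=0.7, log=False,
                              effects={"age": -0.05, "sex_male": 1.0}),
}

for outcome, d in factor_defs.items():
    write(outcome, factor_spec(outcome, d["mu"], d["sigma"], d["effects"], d["log"]))

# --- behavioral / medication logistic specs ---------------------------------
def logistic_spec(name, outcome, coeffs, target_p, extra_kinds=None):
    intercept = logit(target_p) - sum(b * cov_mean(c) for c, b in coeffs.items())
    full = {"intercept": intercept, **coeffs}
    kinds = {c: kind_for(c) for c in coeffs}
    if extra_kinds:
        kinds.update(extra_kinds)
    return {
        "name": name,
        "family": "logistic",
        "outcome": outcome,
        "coefficients": full,
        "residual": {"mean": 0.0, "sd": 0.0},
        "transform": "none",
        "covariate_kinds": kinds,
    }


MEANS["lag_statin"] = MEANS["statin"]
MEANS["lag_other_lipid_agent"] = MEANS["other_lipid_agent"]

write("smoking_status", logistic_spec("smoking_quit", "smoking_status", {"age": 0.01}, 0.03))
write(
    "n_antihypertensives",
    logistic_spec("antihypertensive_add", "n_antihypertensives",
                  {"lag_log_sbp": 2.0, "age": 0.01}, 0.02),
)
write("statin", logistic_spec("statin_use", "statin", {"lag_statin": 6.0, "age": 0.02}, 0.02))
write(
    "other_lipid_agent",
    logistic_spec("other_lipid_use", "other_lipid_agent",
                  {"lag_other_lipid_agent": 5.0, "age": 0.01}, 0.01),
)

# --- stroke-vs-MI partition ---------------------------------------------------
partition_coeffs = {
    "lag_age": 0.015,
    "lag_log_sbp": 1.2,
    "lag_log_dbp": 0.5,
    "lag_bmi": -0.01,
    "lag_trig": -0.001,
    "lag_a1c": 0.05,
    "sex_male": -0.15,
    "race_nh_black": 0.35,
    "race_hispanic": 0.05,
    "race_other": 0.0,
}
write("stroke_partition", logistic_spec("stroke_partition", "stroke_partition",
                                        partition_coeffs, 0.40))

# --- non-CV mortality --------------------------------------------------------
MEANS["age_squared"] = MEANS["age"] ** 2
mort_coeffs = {
    "age": 0.085,
    "age_squared": 0.0002,
    "sex_male": 0.25,
    "race_nh_black": 0.15,
    "race_hispanic": -0.10,
    "race_other": 0.0,
    "lagmean_sbp": 0.004,
    "lagmean_dbp": -0.002,
    "lag_a1c": 0.10,
    "lag_total_chol": 0.0005,
    "lag_trig": 0.0002,
    "lag_bmi": 0.01,
    "smoking_current": 0.5,
}
mort = logistic_spec("non_cv_mortality", "non_cv_mortality", mort_coeffs, 0.0015,
                     extra_kinds={"age": "current", "age_squared": "current"})
write("non_cv_mortality", mort)

# --- PCE coefficients ---------------------------------------------------------
pce_base = {
    "age": 0.075,
    "sbp_untreated": 0.018,
    "sbp_treated": 0.018,
    "total_chol": 0.003,
    "hdl": -0.012,
    "a1c": 0.20,
    "smoking_current": 0.55,
}
ref = {"age": 60.0, "sbp_untreated": 130.0, "sbp_treated": 0.0,
       "total_chol": 200.0, "hdl": 50.0, "a1c": 5.6, "smoking_current": 0.0}
ref_risk = {"female_nonblack": 0.06, "female_black": 0.08,
            "male_nonblack": 0.10, "male_black": 0.12}
strata = {}
for name, p in ref_risk.items():
    intercept = logit(p) - sum(pce_base[c] * ref[c] for c in pce_base)
    strata[name] = {"intercept": intercept, **pce_base}
with open(DATA / "pce_coefficients.json", "w") as fh:
    json.dump(strata, fh, indent=1, sort_keys=True)
print("wrote pce_coefficients.json")

# --- dementia Cox spec --------------------------------------------------------
cox = {
    "hazard_ratios": {
        "baseline_gcp": 0.927,
        "gcp_slope": 0.999,
        "baseline_age": 1.108,
        "sex_female": 1.1,
        "education_less_than_high_school": 1.032,
        "education_some_high_school": 1.088,
        "education_high_school_grad": 0.919,
        "education_some_college": 0.797,
        "race_nh_black": 1.214,
    },
    "references": {"baseline_gcp": 50.0, "baseline_age": 75.0},
    "baseline": [-3.06, 0.10259, 0.0],
}
with open(DATA / "dementia_cox.json", "w") as fh:
    json.dump(cox, fh, indent=1, sort_keys=True)
print("wrote dementia_cox.json")

# --- synthetic life table (Gompertz-Makeham stand-in) ------------------------
ages = np.arange(18, 111)
qx = np.minimum(1.0, 8e-4 + 2e-5 * np.exp(0.095 * ages))
qx[-1] = 1.0
with open(DATA / "life_table_synthetic.csv", "w") as fh:
    fh.write("age,qx\n")
    for a, q in zip(ages, qx):
        fh.write(f"{a},{q:.6f}\n")
print("wrote life_table_synthetic.csv")

# --- US 2000 projected standard million --------------------------------------
std = [
    ("0-4", 0, 4, 69135), ("5-9", 5, 9, 72533), ("10-14", 10, 14, 73032),
    ("15-19", 15, 19, 72169), ("20-24", 20, 24, 66478), ("25-29", 25, 29, 64529),
    ("30-34", 30, 34, 71044), ("35-39", 35, 39, 80762), ("40-44", 40, 44, 81851),
    ("45-49", 45, 49, 72118), ("50-54", 50, 54, 62716), ("55-59", 55, 59, 48454),
    ("60-64", 60, 64, 38793), ("65-69", 65, 69, 34264), ("70-74", 70, 74, 31773),
    ("75-79", 75, 79, 26999), ("80-84", 80, 84, 17842), ("85+", 85, 120, 15508),
]
assert sum(w for *_, w in std) == 1_000_000
with open(DATA / "standard_population_us2000.csv", "w") as fh:
    fh.write("band,age_lo,age_hi,weight\n")
    for band, lo, hi, w in std:
        fh.write(f"{band},{lo},{hi},{w}\n")
print("wrote standard_population_us2000.csv")
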