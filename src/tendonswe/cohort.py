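"""Subject-level cohort simulation with a linear generative SWV model.

Emulates a two-group case-control design (elite alpine skiers vs. healthy
controls): per-group Gaussian demographics, derived BMI, and regional
patellar-tendon SWV generated from a linear model in group, sex, age and
tendon length with Gaussian residuals.  Sex and group enter as 0/1 indicators
(female = 0, male = 1; control = 0, skier = 1).

``reference_cohort_params`` packages the default parameterization whose
marginal group means, group sizes, sex composition and covariate effects
match the reported case-control study of 30 elite competitive alpine skiers
vs. 38 healthy controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import SWV_BOUNDS

__all__ = [
    "GroupSpec",
    "RegionModel",
    "CohortParams",
    "simulate_cohort",
    "reference_cohort_params",
    "pooled_sd",
    "COHORT_COLUMNS",
    "REGION_ORDER",
]

REGION_ORDER = ("proximal", "mid", "distal", "overall")

#: Fixed cohort CSV column order.
COHORT_COLUMNS = [
    "id", "group", "sex", "age", "weight", "height", "bmi",
    "tendon_length", "csa",
    "swv_overall", "swv_proximal", "swv_mid", "swv_distal",
]


@dataclass(frozen=True)
class GroupSpec:
    """Size, sex composition and demographic distributions of one group."""

    n: int
    n_female: int
    age_mean: float
    age_sd: float
    weight_mean: float
    weight_sd: float
    height_mean: float
    height_sd: float

    def __post_init__(self):
        if self.n < 0 or self.n_female < 0 or self.n_female > self.n:
            raise ValueError("need 0 <= n_female <= n")
        for name in ("age_sd", "weight_sd", "height_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RegionModel:
    """Linear generative model for one region's SWV (m/s).

    ``swv = intercept + group_effect * skier + sex_effect * male
           + age_effect * age + tendon_length_effect * L + N(0, residual_sd)``

    ``sex_effect_control`` / ``sex_effect_skier`` override the common
    ``sex_effect`` per group when set (used to reproduce a sex effect present
    only under heavy tendon loading).
    """

    intercept: float
    group_effect: float = 0.0
    sex_effect: float = 0.0
    sex_effect_control: float | None = None
    sex_effect_skier: float | None = None
    age_effect: float = 0.0
    tendon_length_effect: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def sex_effect_for(self, is_skier: np.ndarray) -> np.ndarray:
        ctrl = self.sex_effect if self.sex_effect_control is None \
            else self.sex_effect_control
        ski = self.sex_effect if self.sex_effect_skier is None \
            else self.sex_effect_skier
        return np.where(is_skier, ski, ctrl)


@dataclass(frozen=True)
class CohortParams:
    """Full cohort parameterization.

    ``swv_model`` maps region name -> :class:`RegionModel`.  If it contains an
    ``"overall"`` entry, swv_overall is drawn from that model directly;
    otherwise it is derived as the 10 : (L - 20) : 10 length-weighted mean of
    the three regional draws.
    """

    control: GroupSpec
    skier: GroupSpec
    tendon_length_mean: float = 46.0
    tendon_length_sd: float = 4.0
    csa_mean: float = 100.0
    csa_sd: float = 15.0
    swv_model: dict = field(default_factory=dict)
    swv_bounds: tuple[float, float] = SWV_BOUNDS
    seed: int = 0

    def __post_init__(self):
        if self.tendon_length_sd < 0 or self.csa_sd < 0:
            raise ValueError("SDs must be >= 0")
        for name in self.swv_model:
            if name not in REGION_ORDER:
                raise ValueError(f"unknown region {name!r} in swv_model")


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Pooled within-group SD: sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2))."""
    return math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                     / (n1 + n2 - 2))


def _draw_group(rng: np.random.Generator, spec: GroupSpec, label: str,
                start_id: int) -> pd.DataFrame:
    n = spec.n
    sex = np.array(["female"] * spec.n_female + ["male"] * (n - spec.n_female))
    return pd.DataFrame({
        "id": [f"{label[0].upper()}{start_id + i:03d}" for i in range(n)],
        "group": label,
        "sex": sex,
        "age": rng.normal(spec.age_mean, spec.age_sd, n),
        "weight": rng.normal(spec.weight_mean, spec.weight_sd, n),
        "height": rng.normal(spec.height_mean, spec.height_sd, n),
    })


def simulate_cohort(params: CohortParams,
                    seed: int | np.random.Generator | None = None
                    ) -> pd.DataFrame:
    """Generate a subject table; deterministic given the seed.

    BMI is derived (weight / (height/100)^2), never drawn.  Regional SWV
    values are clipped to the physical bounds after adding residual noise.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(params.seed if seed is None else seed)

    parts = []
    if params.control.n > 0:
        parts.append(_draw_group(rng, params.control, "control", 0))
    if params.skier.n > 0:
        parts.append(_draw_group(rng, params.skier, "skier", 0))
    if not parts:
        raise ValueError("cohort has no subjects")
    df = pd.concat(parts, ignore_index=True)
    n = len(df)
    df["bmi"] = df["weight"] / (df["height"] / 100.0) ** 2
    df["tendon_length"] = rng.normal(params.tendon_length_mean,
                                     params.tendon_length_sd, n)
    df["csa"] = rng.normal(params.csa_mean, params.csa_sd, n)

    is_skier = (df["group"] == "skier").to_numpy()
    is_male = (df["sex"] == "male").to_numpy().astype(float)
    lo, hi = params.swv_bounds
    regional = {}
    for region in REGION_ORDER:
        model = params.swv_model.get(region)
        if model is None:
            continue
        mu = (model.intercept
              + model.group_effect * is_skier
              + model.sex_effect_for(is_skier) * is_male
              + model.age_effect * df["age"].to_numpy()
              + model.tendon_length_effect * df["tendon_length"].to_numpy())
        vals = mu + rng.normal(0.0, 1.0, n) * model.residual_sd
        regional[region] = np.clip(vals, lo, hi)

    for region in ("proximal", "mid", "distal"):
        df[f"swv_{region}"] = regional.get(region, np.nan)

    if "overall" in regional:
        df["swv_overall"] = regional["overall"]
    elif all(r in regional for r in ("proximal", "mid", "distal")):
        L = df["tendon_length"].to_numpy()
        w_end = 10.0 / L
        w_mid = (L - 20.0) / L
        df["swv_overall"] = (w_end * (regional["proximal"] + regional["distal"])
                             + w_mid * regional["mid"])
    else:
        df["swv_overall"] = np.nan
    return df[COHORT_COLUMNS]


# --- default parameterization matching the reported case-control study -----

# Marginal group means of overall tendon SWV (m/s), skier / control.
_MEAN_SKIER = 10.4
_MEAN_CONTROL = 8.9
# Reported group SDs used to pool the residual SD.
_SD_SKIER, _N_SKIER, _F_SKIER = 1.32, 30, 14
_SD_CONTROL, _N_CONTROL, _F_CONTROL = 1.59, 38, 20
# Whole-population regional skier-group effects (m/s).
_GROUP_EFFECTS = {"proximal": 1.184, "mid": 1.401, "distal": 2.202}
# Tendon-length effects retained in the whole-population models (m/s per mm).
_TL_EFFECTS = {"proximal": 0.054, "mid": 0.045, "distal": 0.0}
# Within-skier male-sex effects per region (m/s); controls showed none.
_SKIER_SEX_EFFECTS = {"proximal": 0.927, "mid": 1.080, "distal": 0.035}

_TENDON_LENGTH_MEAN = 46.0  # mm, field-typical patellar tendon
_TENDON_LENGTH_SD = 4.0
_CSA_MEAN = 100.0  # mm^2
_CSA_SD = 15.0


def reference_cohort_params(seed: int = 0) -> CohortParams:
    """Default cohort parameterization of the modeled case-control study.

    Structure: 38 controls (20 female) and 30 elite skiers (14 female) with
    the reported demographic distributions; regional skier-group effects and
    tendon-length effects as reported for the whole population; male-sex
    effects present in the skier group only (control sex effect 0), using the
    reported within-skier regional estimates.

    Calibration: regional intercepts put every region's control marginal mean
    at the reported control overall mean (per-region means were not reported;
    flat across regions is the documented modeling choice).  The overall
    region is drawn directly from its own model whose male-sex effect is the
    10:26:10 length-weighted mean of the regional skier sex effects and whose
    group effect is set so the marginal skier and control means equal the
    reported 10.4 and 8.9 m/s given the sex composition.  The residual SD is
    the pooled within-group SD of the reported group SDs.
    """
    resid = pooled_sd(_SD_SKIER, _N_SKIER, _SD_CONTROL, _N_CONTROL)
    p_male_skier = (_N_SKIER - _F_SKIER) / _N_SKIER

    w_end = 10.0 / _TENDON_LENGTH_MEAN
    w_mid = (_TENDON_LENGTH_MEAN - 20.0) / _TENDON_LENGTH_MEAN
    sex_overall = (w_end * (_SKIER_SEX_EFFECTS["proximal"]
                            + _SKIER_SEX_EFFECTS["distal"])
                   + w_mid * _SKIER_SEX_EFFECTS["mid"])
    group_overall = (_MEAN_SKIER - _MEAN_CONTROL) - p_male_skier * sex_overall

    swv_model = {}
    for region in ("proximal", "mid", "distal"):
        swv_model[region] = RegionModel(
            intercept=_MEAN_CONTROL - _TL_EFFECTS[region] * _TENDON_LENGTH_MEAN,
            group_effect=_GROUP_EFFECTS[region],
            sex_effect_control=0.0,
            sex_effect_skier=_SKIER_SEX_EFFECTS[region],
            tendon_length_effect=_TL_EFFECTS[region],
            residual_sd=resid,
        )
    swv_model["overall"] = RegionModel(
        intercept=_MEAN_CONTROL,
        group_effect=group_overall,
        sex_effect_control=0.0,
        sex_effect_skier=sex_overall,
        residual_sd=resid,
    )
    return CohortParams(
        control=GroupSpec(n=_N_CONTROL, n_female=_F_CONTROL,
                          age_mean=24.9, age_sd=2.50,
                          weight_mean=65.9, weight_sd=10.3,
                          height_mean=172.0, height_sd=8.71),
        skier=GroupSpec(n=_N_SKIER, n_female=_F_SKIER,
                        age_mean=23.6, age_sd=2.50,
                        weight_mean=73.7, weight_sd=10.7,
                        height_mean=173.0, height_sd=9.37),
        tendon_length_mean=_TENDON_LENGTH_MEAN,
        tendon_length_sd=_TENDON_LENGTH_SD,
        csa_mean=_CSA_MEAN,
        csa_sd=_CSA_SD,
        swv_model=swv_model,
        seed=seed,
    )
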