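"""Derived anthropometric and metabolic indices for ALS cohort records.

Implements the quantities a nutritional work-up of an early-ALS admission
derives from raw measurements: BMI and percent ideal body weight (%IBW,
computed as BMI / 22 so that the 90 % malnutrition line falls at a BMI of
19.8), monthly BMI and ALSFRS-R decline rates, the respiratory quotient,
resting energy expenditure measured by indirect calorimetry (abbreviated
Weir equation, no urinary nitrogen) and predicted by the original
Harris-Benedict equations, the mREE/LSTM hypermetabolism ratio, and the
BMI-muscle-metabolism (BMM) product index

    BMM = (BMI - 19.8) x (mREE/LSTM - 38)

which is positive when nutritional and metabolic state deviate from their
reference values in the *same* direction (well-nourished and hypermetabolic,
or malnourished and hypometabolic) -- the configuration associated with
shorter survival.

All scalar operations propagate ``None``/NaN inputs to missing outputs;
classification flags are missing exactly when a required input is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Any

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Thresholds",
    "compute_bmi",
    "percent_ibw",
    "delta_bmi",
    "delta_alsfrs",
    "respiratory_quotient",
    "weir_mree",
    "harris_benedict_pree",
    "bmm_index",
    "classify_profile",
    "MetabolicProfiler",
    "PROFILE_COLUMNS",
    "FLAG_COLUMNS",
]

#: Columns appended by :class:`MetabolicProfiler`, in output order.
PROFILE_COLUMNS = [
    "bmi", "premorbid_bmi", "pct_ibw", "delta_bmi", "delta_alsfrs",
    "rq", "mree", "pree", "mree_per_lstm", "mree_per_pree", "bmm",
]
FLAG_COLUMNS = [
    "malnourished", "hypermetabolic", "high_bmm", "excess_weight_loss",
    "high_fat", "low_rq", "high_ldl", "high_mree_pree",
]


@dataclass(frozen=True)
class Thresholds:
    """Classification cut-offs.

    Defaults are the study definitions: hypermetabolism mREE/LSTM >= 38
    kcal/kg/day, malnutrition %IBW < 0.9 (equivalently BMI < 19.8 with the
    ideal-BMI constant of 22 kg/m2), high BMM index >= 1, mREE/pREE > 1.1,
    fat-dominant fuel use RQ < 0.85, high LDL >= 100 mg/dL, high body fat
    > 25 % (men) / > 30 % (women), excess weight loss > 10 % of premorbid
    weight, and a 24-month horizon for the time-dependent ROC.
    """

    hypermetabolism_cut: float = 38.0      # kcal/kg/day, closed bound (>=)
    malnutrition_pct_ibw: float = 0.9      # fraction, open bound (<)
    bmm_cut: float = 1.0                   # score, closed bound (>=)
    mree_pree_cut: float = 1.1             # ratio, strict (>)
    rq_cut: float = 0.85                   # ratio, strict (<)
    ldl_cut: float = 100.0                 # mg/dL, closed bound (>=)
    fat_cut_male: float = 25.0             # percent, strict (>)
    fat_cut_female: float = 30.0           # percent, strict (>)
    weight_loss_cut: float = 0.10          # fraction of premorbid weight, strict (>)
    ibw_bmi_constant: float = 22.0         # kg/m2 defining 100 % ideal body weight
    bmm_bmi_reference: float = 19.8        # kg/m2, = 0.9 * 22
    roc_horizon: float = 24.0              # months from onset

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"threshold {f.name!r} must be positive, got {v!r}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Thresholds":
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


_DEFAULT = Thresholds()


def _missing(x: Any) -> bool:
    if x is None:
        return True
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) over squared height (m)."""
    if _missing(weight) or _missing(height):
        return math.nan
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / height**2


def percent_ibw(bmi: float, thresholds: Thresholds = _DEFAULT) -> float:
    """Percent of ideal body weight as a fraction: BMI / 22.

    The ideal weight at a given height is the weight giving a BMI of 22
    kg/m2, so %IBW reduces to BMI / 22 and the %IBW < 0.9 malnutrition
    criterion is exactly BMI < 19.8.
    """
    if _missing(bmi):
        return math.nan
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    return bmi / thresholds.ibw_bmi_constant


def delta_bmi(premorbid_bmi: float, admission_bmi: float,
              months_since_onset: float) -> float:
    """Monthly BMI change since onset; negative means decline."""
    if _missing(premorbid_bmi) or _missing(admission_bmi) or _missing(months_since_onset):
        return math.nan
    if months_since_onset <= 0:
        raise ValueError("months_since_onset must be positive")
    return (admission_bmi - premorbid_bmi) / months_since_onset


def delta_alsfrs(alsfrs_r: float, months_since_onset: float) -> float:
    """Monthly ALSFRS-R decline from the 48-point ceiling since onset."""
    if _missing(alsfrs_r) or _missing(months_since_onset):
        return math.nan
    if not 0 <= alsfrs_r <= 48:
        raise ValueError("alsfrs_r must lie in [0, 48]")
    if months_since_onset <= 0:
        raise ValueError("months_since_onset must be positive")
    return (48.0 - alsfrs_r) / months_since_onset


def respiratory_quotient(vo2: float, vco2: float) -> float:
    """Respiratory quotient VCO2/VO2 (~0.7 fat oxidation, ~1.0 carbohydrate)."""
    if _missing(vo2) or _missing(vco2):
        return math.nan
    if vo2 <= 0:
        raise ValueError("vo2 must be positive")
    if vco2 < 0:
        raise ValueError("vco2 must be non-negative")
    return vco2 / vo2


def weir_mree(vo2: float, vco2: float) -> float:
    """Measured resting energy expenditure in kcal/day.

    Abbreviated Weir equation without urinary nitrogen, gas rates in
    mL/min: 1.44 * (3.941 VO2 + 1.106 VCO2).
    """
    if _missing(vo2) or _missing(vco2):
        return math.nan
    if vo2 < 0 or vco2 < 0:
        raise ValueError("gas exchange rates must be non-negative")
    return 1.44 * (3.941 * vo2 + 1.106 * vco2)


def harris_benedict_pree(sex: str, weight: float, height_m: float,
                         age: float) -> float:
    """Predicted resting energy expenditure (kcal/day), Harris-Benedict.

    Original 1919 coefficient sets; ``height_m`` in metres (converted to cm
    internally), ``sex`` is ``"M"``/``"male"`` or ``"F"``/``"female"``.
    """
    if _missing(weight) or _missing(height_m) or _missing(age) or _missing(sex):
        return math.nan
    if weight <= 0 or height_m <= 0 or age <= 0:
        raise ValueError("weight, height and age must be positive")
    h_cm = height_m * 100.0
    s = str(sex).strip().lower()
    if s in ("m", "male"):
        return 66.4730 + 13.7516 * weight + 5.0033 * h_cm - 6.7550 * age
    if s in ("f", "female"):
        return 655.0955 + 9.5634 * weight + 1.8496 * h_cm - 4.6756 * age
    raise ValueError(f"unknown sex {sex!r}")


def bmm_index(bmi: float, mree_per_lstm: float,
              thresholds: Thresholds = _DEFAULT) -> float:
    """BMI-muscle-metabolism index (BMI - 19.8) * (mREE/LSTM - 38).

    Missing factors propagate to a missing index.
    """
    if _missing(bmi) or _missing(mree_per_lstm):
        return math.nan
    return ((bmi - thresholds.bmm_bmi_reference)
            * (mree_per_lstm - thresholds.hypermetabolism_cut))


def _flag(value: float, cut: float, kind: str) -> Any:
    """Boundary conventions: 'ge' closed, 'gt'/'lt' strict."""
    if _missing(value):
        return None
    if kind == "ge":
        return bool(value >= cut)
    if kind == "gt":
        return bool(value > cut)
    if kind == "lt":
        return bool(value < cut)
    raise ValueError(kind)


def classify_profile(record: dict[str, Any],
                     thresholds: Thresholds = _DEFAULT) -> dict[str, Any]:
    """All derived indices and classification flags for one patient record.

    ``record`` maps cohort-CSV field names to values (missing = None/NaN).
    Returns a dict with the :data:`PROFILE_COLUMNS` and :data:`FLAG_COLUMNS`
    keys; every flag is None exactly when a required input is missing.
    Deterministic and idempotent: profile keys already present in ``record``
    are ignored and recomputed.
    """
    t = thresholds
    g = record.get
    height = g("height")
    out: dict[str, Any] = {}

    bmi = compute_bmi(g("admission_weight"), height)
    out["bmi"] = bmi
    out["premorbid_bmi"] = compute_bmi(g("premorbid_weight"), height)
    out["pct_ibw"] = percent_ibw(bmi, t) if not _missing(bmi) else math.nan
    out["delta_bmi"] = delta_bmi(out["premorbid_bmi"], bmi, g("months_since_onset"))
    out["delta_alsfrs"] = delta_alsfrs(g("alsfrs_r"), g("months_since_onset"))
    out["rq"] = respiratory_quotient(g("vo2"), g("vco2"))
    out["mree"] = weir_mree(g("vo2"), g("vco2"))
    out["pree"] = harris_benedict_pree(g("sex"), g("admission_weight"), height, g("age"))

    lstm = g("lstm")
    out["mree_per_lstm"] = (out["mree"] / lstm
                            if not (_missing(out["mree"]) or _missing(lstm)) else math.nan)
    out["mree_per_pree"] = (out["mree"] / out["pree"]
                            if not (_missing(out["mree"]) or _missing(out["pree"])) else math.nan)
    out["bmm"] = bmm_index(bmi, out["mree_per_lstm"], t)

    out["malnourished"] = _flag(out["pct_ibw"], t.malnutrition_pct_ibw, "lt")
    out["hypermetabolic"] = _flag(out["mree_per_lstm"], t.hypermetabolism_cut, "ge")
    out["high_bmm"] = _flag(out["bmm"], t.bmm_cut, "ge")
    pre_w, adm_w = g("premorbid_weight"), g("admission_weight")
    if _missing(pre_w) or _missing(adm_w):
        out["excess_weight_loss"] = None
    else:
        out["excess_weight_loss"] = bool((pre_w - adm_w) / pre_w > t.weight_loss_cut)
    fat = g("body_fat_pct")
    sex = g("sex")
    if _missing(fat) or _missing(sex):
        out["high_fat"] = None
    else:
        cut = t.fat_cut_male if str(sex).strip().lower() in ("m", "male") else t.fat_cut_female
        out["high_fat"] = bool(fat > cut)
    out["low_rq"] = _flag(out["rq"], t.rq_cut, "lt")
    out["high_ldl"] = _flag(g("ldl"), t.ldl_cut, "ge")
    out["high_mree_pree"] = _flag(out["mree_per_pree"], t.mree_pree_cut, "gt")
    return out


class MetabolicProfiler(BaseEstimator, TransformerMixin):
    """Transformer appending the derived metabolic profile to a cohort table.

    ``transform`` takes a DataFrame in the cohort-CSV schema and returns a
    copy augmented with the derived columns and flags (flags as nullable
    booleans). Stateless: ``fit`` only validates the schema.

    Parameters
    ----------
    thresholds : Thresholds, optional
        Classification cut-offs; study defaults when omitted.
    """

    _REQUIRED = ("height", "admission_weight")

    def __init__(self, thresholds: Thresholds | None = None):
        self.thresholds = thresholds

    def _resolved(self) -> Thresholds:
        return self.thresholds if self.thresholds is not None else Thresholds()

    def fit(self, X: pd.DataFrame, y: Any = None) -> "MetabolicProfiler":
        missing = [c for c in self._REQUIRED if c not in X.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns: {missing}")
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        t = self._resolved()
        rows = [classify_profile(rec, t)
                for rec in X.to_dict(orient="records")]
        prof = pd.DataFrame(rows, index=X.index)
        for c in FLAG_COLUMNS:
            prof[c] = prof[c].astype("boolean")
        base = X.drop(columns=[c for c in prof.columns if c in X.columns])
        return pd.concat([base, prof[PROFILE_COLUMNS + FLAG_COLUMNS]], axis=1)


def profile_cohort(cohort: pd.DataFrame,
                   thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`MetabolicProfiler`."""
    return MetabolicProfiler(thresholds=thresholds).fit(cohort).transform(cohort)
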