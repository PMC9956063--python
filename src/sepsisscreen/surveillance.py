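"""Rule-based sepsis surveillance labelling from ICU-course data.

Implements the clinical surveillance definition of sepsis (Rhee et al.):
presumed serious infection — a blood culture obtained plus at least four
qualifying antimicrobial days — together with at least one acute
organ-dysfunction criterion within a window around the culture day
(vasopressor initiation, mechanical-ventilation initiation, lactate >= 2.0
mmol/L, creatinine doubling excluding ESRD, bilirubin >= 2.0 mg/dL and
doubled, or a platelet fall below 100 x10^3/uL with a >= 50% decline from a
baseline >= 100).  Every threshold is a named entry of
:class:`~sepsisscreen.config.SurveillanceConfig`.

Septic shock (not spelled out in the study's main text) defaults to the
Sepsis-3-consistent rule: sepsis plus vasopressor requirement plus lactate
>= 2 mmol/L.  In-hospital mortality is the recorded disposition, not inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SurveillanceConfig
from .errors import DataError

__all__ = ["OutcomeLabels", "label_sepsis", "label_septic_shock", "label_cohort"]

_NONNEG_FIELDS = (
    "blood_culture_day", "antimicrobial_days", "lactate_max",
    "creatinine_baseline", "creatinine_peak", "bilirubin_baseline",
    "bilirubin_peak", "platelet_baseline", "platelet_nadir",
)


@dataclass(frozen=True)
class OutcomeLabels:
    sepsis: bool
    septic_shock: bool
    in_hospital_mortality: bool
    criteria_met: tuple[str, ...] = ()

    def __post_init__(self):
        if self.septic_shock and not self.sepsis:
            raise DataError("septic_shock implies sepsis")


def _get(course, key, default=np.nan):
    v = course.get(key, default) if hasattr(course, "get") else default
    return default if v is None else v


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and np.isnan(v)) and not pd.isna(v)


def _in_window(day, culture_day, window: int) -> bool:
    if not _present(day) or not _present(culture_day):
        return False
    return abs(float(day) - float(culture_day)) <= window


def label_sepsis(
    course: pd.Series | dict | None,
    config: SurveillanceConfig | None = None,
) -> tuple[bool, tuple[str, ...]]:
    """Label one patient's ICU course; returns (sepsis, criteria_met).

    An absent course (no ICU admission / no data) labels False with no
    criteria.  ``criteria_met`` lists every satisfied rule, with
    ``"infection"`` for the presumed-serious-infection clause.
    """
    config = config or SurveillanceConfig()
    if course is None:
        return False, ()
    for f in _NONNEG_FIELDS:
        v = _get(course, f)
        if _present(v) and float(v) < 0:
            raise DataError(f"negative value for {f}: {v!r}")

    culture_day = _get(course, "blood_culture_day")
    abx = _get(course, "antimicrobial_days", 0)
    infection = _present(culture_day) and float(abx) >= config.min_antimicrobial_days
    if not infection:
        return False, ()

    met = ["infection"]
    w = config.window_days
    if bool(_get(course, "vasopressor", False)) and _in_window(
        _get(course, "vasopressor_day"), culture_day, w
    ):
        met.append("vasopressor")
    if bool(_get(course, "ventilation", False)) and _in_window(
        _get(course, "ventilation_day"), culture_day, w
    ):
        met.append("ventilation")
    lact = _get(course, "lactate_max")
    if _present(lact) and float(lact) >= config.lactate_min and _in_window(
        _get(course, "lactate_day"), culture_day, w
    ):
        met.append("lactate")
    creat_b, creat_p = _get(course, "creatinine_baseline"), _get(course, "creatinine_peak")
    if (
        not bool(_get(course, "esrd", False))
        and _present(creat_b) and _present(creat_p) and float(creat_b) > 0
        and float(creat_p) >= config.creatinine_fold * float(creat_b)
    ):
        met.append("creatinine")
    bili_b, bili_p = _get(course, "bilirubin_baseline"), _get(course, "bilirubin_peak")
    if (
        _present(bili_b) and _present(bili_p)
        and float(bili_p) >= config.bilirubin_min
        and float(bili_p) >= config.bilirubin_fold * float(bili_b)
    ):
        met.append("bilirubin")
    plt_b, plt_n = _get(course, "platelet_baseline"), _get(course, "platelet_nadir")
    if (
        _present(plt_b) and _present(plt_n)
        and float(plt_b) >= config.platelet_baseline_min
        and float(plt_n) < config.platelet_max
        and float(plt_n) <= (1 - config.platelet_decline) * float(plt_b)
    ):
        met.append("platelets")

    if len(met) == 1:  # infection without organ dysfunction
        return False, ()
    return True, tuple(met)


def label_septic_shock(
    course: pd.Series | dict | None,
    config: SurveillanceConfig | None = None,
    sepsis: bool | None = None,
) -> bool:
    """Septic shock: sepsis AND vasopressor AND lactate >= threshold (default)."""
    config = config or SurveillanceConfig()
    if course is None:
        return False
    if sepsis is None:
        sepsis, _ = label_sepsis(course, config)
    if not sepsis:
        return False
    vaso_ok = bool(_get(course, "vasopressor", False)) or not config.shock_requires_vasopressor
    lact = _get(course, "lactate_max")
    lact_ok = _present(lact) and float(lact) >= config.shock_lactate_min
    return bool(vaso_ok and lact_ok)


def label_cohort(
    cohort: pd.DataFrame,
    config: SurveillanceConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Label every record; returns (cohort with outcome columns, prevalence summary).

    Adds ``sepsis``, ``septic_shock``, ``in_hospital_mortality`` and
    ``criteria_met`` (semicolon-delimited provenance) columns.  Records
    without an ICU course (``icu_admitted`` false or missing course fields)
    label False; mortality is passed through from the recorded disposition.
    """
    config = config or SurveillanceConfig()
    out = cohort.copy()
    n = len(out)
    sepsis = np.zeros(n, dtype=bool)
    shock = np.zeros(n, dtype=bool)
    criteria = [""] * n
    has_course = (
        out["icu_admitted"].astype(bool).to_numpy()
        if "icu_admitted" in out.columns
        else np.ones(n, dtype=bool)
    )
    for i, (_, row) in enumerate(out.iterrows()):
        if not has_course[i]:
            continue
        s, met = label_sepsis(row, config)
        sepsis[i] = s
        criteria[i] = ";".join(met)
        shock[i] = label_septic_shock(row, config, sepsis=s)
    out["sepsis"] = sepsis
    out["septic_shock"] = shock
    out["in_hospital_mortality"] = (
        out["died_in_hospital"].astype(bool)
        if "died_in_hospital" in out.columns
        else False
    )
    out["criteria_met"] = criteria
    summary = {
        "n": n,
        "sepsis": {"count": int(sepsis.sum()),
                   "pct": round(100 * sepsis.mean(), 1) if n else 0.0},
        "septic_shock": {"count": int(shock.sum()),
                         "pct": round(100 * shock.mean(), 1) if n else 0.0},
        "in_hospital_mortality": {
            "count": int(out["in_hospital_mortality"].sum()),
            "pct": round(100 * out["in_hospital_mortality"].mean(), 1) if n else 0.0,
        },
    }
    return out, summary
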