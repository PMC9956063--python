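"""Configuration objects for simulation, imputation, labelling and evaluation.

All tunable constants of the pipeline live here as dataclasses that can be
round-tripped through YAML/JSON.  A single global seed is fanned out to
per-stage seeds with :func:`spawn_seeds`, so each stage is individually
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .errors import ConfigurationError

STAGES = ("pre", "ed")
#: the seven vital-sign parameters recorded at each stage
VITALS = ("sbp", "dbp", "hr", "rr", "bt", "gcs", "spo2")
#: continuous vitals drawn from truncated normals (GCS is a two-part mixture)
CONTINUOUS_VITALS = ("sbp", "dbp", "hr", "rr", "bt", "spo2")

#: qSOFA component thresholds (Sepsis-3): sBP <= 100 mmHg, RR >= 22 /min,
#: altered mental status as GCS <= 14.
QSOFA_SBP_MAX = 100.0
QSOFA_RR_MIN = 22.0
QSOFA_GCS_MAX = 14


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p!r}")


@dataclass
class VitalSpec:
    """Marginal law of one continuous vital at one stage.

    The vital is drawn from a truncated normal with location ``median`` and
    scale ``iqr / 1.349`` (the normal IQR-to-sigma factor), truncated to
    ``[lo, hi]``; patients with latent sepsis get an additive location shift
    ``sepsis_shift``.
    """

    median: float
    iqr: float
    lo: float
    hi: float
    sepsis_shift: float = 0.0

    @property
    def scale(self) -> float:
        return self.iqr / 1.349

    def loc(self, sepsis: bool) -> float:
        return self.median + (self.sepsis_shift if sepsis else 0.0)

    def validate(self, name: str = "vital") -> None:
        if self.iqr <= 0:
            raise ConfigurationError(f"{name}: iqr must be positive")
        if self.lo >= self.hi:
            raise ConfigurationError(f"{name}: lo must be < hi")


def _default_vital_params() -> dict[str, dict[str, VitalSpec]]:
    # Locations/IQRs follow the suspected-infection cohort marginals; the
    # sepsis shifts are the simulator's own effect sizes (see docs/methods.md).
    return {
        "sbp": {
            "pre": VitalSpec(138, 42, 40, 260, sepsis_shift=-10.0),
            "ed": VitalSpec(138, 42, 40, 260, sepsis_shift=-10.0),
        },
        "dbp": {
            "pre": VitalSpec(78, 28, 20, 180, sepsis_shift=-5.0),
            "ed": VitalSpec(80, 24, 20, 180, sepsis_shift=-5.0),
        },
        "hr": {
            "pre": VitalSpec(100, 30, 20, 220, sepsis_shift=5.0),
            "ed": VitalSpec(97, 28, 20, 220, sepsis_shift=5.0),
        },
        "rr": {
            "pre": VitalSpec(24, 6, 4, 60, sepsis_shift=2.5),
            "ed": VitalSpec(22, 7, 4, 60, sepsis_shift=2.5),
        },
        "bt": {
            "pre": VitalSpec(37.5, 1.7, 33, 43, sepsis_shift=0.2),
            "ed": VitalSpec(37.7, 1.5, 33, 43, sepsis_shift=0.2),
        },
        "spo2": {
            "pre": VitalSpec(95, 6, 40, 100, sepsis_shift=-1.5),
            "ed": VitalSpec(96, 5, 40, 100, sepsis_shift=-1.5),
        },
    }


def _default_missingness() -> dict[str, dict[str, float]]:
    # Printed missingness percentages of the study cohort (SpO2 unreported
    # there; 2% is the simulator's choice).
    return {
        "sbp": {"pre": 0.08, "ed": 0.04},
        "dbp": {"pre": 0.09, "ed": 0.05},
        "hr": {"pre": 0.02, "ed": 0.05},
        "rr": {"pre": 0.11, "ed": 0.08},
        "bt": {"pre": 0.08, "ed": 0.04},
        "gcs": {"pre": 0.02, "ed": 0.33},
        "spo2": {"pre": 0.02, "ed": 0.02},
    }


#: exclusion reasons recognised by the cohort builder, in precedence order
EXCLUSION_REASONS = (
    "age_lt_18",
    "no_suspected_infection",
    "trauma",
    "cardiac_arrest",
    "death_on_arrival",
    "transfer_out",
    "insufficient_vitals",
)


@dataclass
class SimConfig:
    """All parameters of the synthetic-cohort generator."""

    n_patients: int = 2407
    sepsis_prev: float = 0.15
    shock_prev: float = 0.06
    mortality_prev: float = 0.09
    stage_correlation: float = 0.6
    vital_params: dict[str, dict[str, VitalSpec]] = field(
        default_factory=_default_vital_params
    )
    #: marginal probability of altered mental status (GCS <= 14) per stage
    ams_marginal: dict[str, float] = field(
        default_factory=lambda: {"pre": 0.47, "ed": 0.45}
    )
    #: additive effect of latent sepsis on the AMS probability
    ams_shift: float = 0.18
    missingness_rates: dict[str, dict[str, float]] = field(
        default_factory=_default_missingness
    )
    missing_mechanism: Literal["mcar", "mar"] = "mcar"
    #: under MAR, multiplier applied to AMS-positive patients' missingness odds
    mar_odds_factor: float = 2.0
    #: probability a latent sepsis case receives an ICU course that satisfies
    #: the surveillance rule (1.0 = the labeller recovers the latent state)
    labeler_sensitivity: float = 1.0
    #: probability a latent non-sepsis patient receives a non-qualifying course
    labeler_specificity: float = 1.0
    #: per-reason rates of injected ineligible records (for flow testing)
    exclusion_rates: dict[str, float] = field(default_factory=dict)
    #: conditional in-hospital death probabilities given (shock, sepsis-only)
    death_given_shock: float = 0.35
    death_given_sepsis: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in ("sepsis_prev", "shock_prev", "mortality_prev",
                     "death_given_shock", "death_given_sepsis", "ams_shift"):
            _check_prob(name, getattr(self, name))
        if not (0.0 <= self.stage_correlation <= 1.0):
            raise ConfigurationError(
                f"stage_correlation must be in [0, 1], got {self.stage_correlation!r}"
            )
        if self.shock_prev > self.sepsis_prev:
            raise ConfigurationError("shock_prev cannot exceed sepsis_prev")
        for stage, p in self.ams_marginal.items():
            _check_prob(f"ams_marginal[{stage}]", p)
        for vital, stages in self.missingness_rates.items():
            for stage, rate in stages.items():
                _check_prob(f"missingness_rates[{vital}][{stage}]", rate)
        for reason, rate in self.exclusion_rates.items():
            if reason not in EXCLUSION_REASONS:
                raise ConfigurationError(f"unknown exclusion reason {reason!r}")
            _check_prob(f"exclusion_rates[{reason}]", rate)
        _check_prob("labeler_sensitivity", self.labeler_sensitivity)
        _check_prob("labeler_specificity", self.labeler_specificity)
        for vital, stages in self.vital_params.items():
            for stage, spec in stages.items():
                spec.validate(f"vital_params[{vital}][{stage}]")

    def ams_prob(self, stage: str, sepsis: bool) -> float:
        """Per-status AMS probability consistent with the marginal target."""
        base = self.ams_marginal[stage] - self.sepsis_prev * self.ams_shift
        p = base + (self.ams_shift if sepsis else 0.0)
        return float(np.clip(p, 0.0, 1.0))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ImputationSpec:
    """Settings of the iterated random-forest (missForest-style) imputer."""

    n_trees: int = 100
    max_iterations: int = 10
    convergence_tol: float = 0.0
    seed: int = 0
    include_outcomes_as_predictors: bool = True
    n_datasets: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.convergence_tol < 0:
            raise ConfigurationError("convergence_tol must be >= 0")
        if self.n_datasets < 1:
            raise ConfigurationError("n_datasets must be >= 1")


@dataclass
class SurveillanceConfig:
    """Thresholds of the clinical surveillance sepsis definition (Rhee et al.).

    Presumed serious infection = blood culture obtained AND >= ``min_antimicrobial_days``
    qualifying antimicrobial days; plus >= 1 acute organ-dysfunction criterion
    within ``window_days`` of the culture day.
    """

    min_antimicrobial_days: int = 4
    window_days: int = 2
    lactate_min: float = 2.0          # mmol/L
    creatinine_fold: float = 2.0      # peak >= fold x baseline, ESRD excluded
    bilirubin_min: float = 2.0        # mg/dL
    bilirubin_fold: float = 2.0
    platelet_max: float = 100.0       # 10^3/uL nadir threshold
    platelet_decline: float = 0.5     # >= 50% fall from baseline >= platelet_baseline_min
    platelet_baseline_min: float = 100.0
    # septic shock (Sepsis-3-consistent default): vasopressor + lactate
    shock_requires_vasopressor: bool = True
    shock_lactate_min: float = 2.0

    def __post_init__(self) -> None:
        if self.min_antimicrobial_days < 1:
            raise ConfigurationError("min_antimicrobial_days must be >= 1")
        if self.window_days < 0:
            raise ConfigurationError("window_days must be >= 0")


#: score columns produced by the scorer, and their admissible cutoff grids
SCORE_CUTOFFS = {
    "qsofa_pre": (1, 2, 3),
    "qsofa_ed": (1, 2, 3),
    "qsofa_combined": (1, 2, 3, 4, 5, 6),
}

OUTCOMES = ("sepsis", "septic_shock", "in_hospital_mortality")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate or read a cohort file)."""

    simulate: SimConfig | None = None
    input_file: str | None = None
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    surveillance: SurveillanceConfig = field(default_factory=SurveillanceConfig)
    outcomes: tuple[str, ...] = OUTCOMES
    cutoffs: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(SCORE_CUTOFFS)
    )
    ci_method: str = "wilson"
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_file is None):
            raise ConfigurationError(
                "exactly one input source (simulate | input_file) must be set"
            )
        if not self.outcomes:
            raise ConfigurationError("outcomes must be nonempty")
        for o in self.outcomes:
            if o not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {o!r}")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a global seed out into ``n`` independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# (de)serialisation


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_to_dict(cfg) -> dict:
    return _to_jsonable(cfg)


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "vital_params" in d:
        d["vital_params"] = {
            v: {s: VitalSpec(**spec) for s, spec in stages.items()}
            for v, stages in d["vital_params"].items()
        }
    return SimConfig(**d)


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    if d.get("simulate") is not None:
        d["simulate"] = sim_config_from_dict(d["simulate"])
    if "imputation" in d:
        d["imputation"] = ImputationSpec(**d["imputation"])
    if "surveillance" in d:
        d["surveillance"] = SurveillanceConfig(**d["surveillance"])
    if "outcomes" in d:
        d["outcomes"] = tuple(d["outcomes"])
    if "cutoffs" in d:
        d["cutoffs"] = {k: tuple(v) for k, v in d["cutoffs"].items()}
    return RunConfig(**d)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    d = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    return run_config_from_dict(d)


def save_config(cfg, path: str | Path) -> None:
    d = config_to_dict(cfg)
    p = Path(path)
    if p.suffix in (".yml", ".yaml"):
        p.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        p.write_text(json.dumps(d, indent=2))
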