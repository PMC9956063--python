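"""Model/Results interface over the screening pipeline.

:class:`QsofaScreeningModel` is constructed from raw per-patient records (a
DataFrame or CSV); ``fit()`` runs the full analysis — cohort construction,
surveillance labelling, random-forest imputation, qSOFA scoring and score
evaluation — and returns a :class:`ScreeningResults` carrying the estimates
(c-statistics with DeLong 95% CIs, per-cutoff accuracy with Wilson CIs,
DeLong comparisons against ED qSOFA, score transitions, added capture),
diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import BT_STAGES_DEFAULT, CohortFlow, build_cohort
from .config import (
    OUTCOMES,
    SCORE_CUTOFFS,
    ImputationSpec,
    SurveillanceConfig,
    config_to_dict,
)
from .errors import DataError
from .evaluate import (
    AccuracyTable,
    TransitionTable,
    accuracy_table,
    added_capture,
    roc_coordinates,
    transition_table,
)
from .impute import fit_impute
from .qsofa import CutoffRule, score_cohort
from .simulate import read_cohort
from .surveillance import label_cohort

SCORES = ("qsofa_ed", "qsofa_pre", "qsofa_combined")


class QsofaScreeningModel:
    """Two-stage qSOFA screening evaluation on a suspected-infection cohort.

    Parameters
    ----------
    records : DataFrame of raw per-patient records (see the column dictionary
        in :mod:`sepsisscreen.simulate`).
    imputation : settings of the random-forest imputer.
    surveillance : thresholds of the surveillance sepsis definition.
    outcomes : outcome labels to evaluate.
    cutoffs : per-score cutoff grids.
    reference_score : score the DeLong comparisons are made against.
    build : apply inclusion/exclusion gates first (disable for pre-built
        cohorts; the flow accounting is then trivial).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        *,
        imputation: ImputationSpec | None = None,
        surveillance: SurveillanceConfig | None = None,
        outcomes: tuple[str, ...] = OUTCOMES,
        cutoffs: dict[str, tuple[int, ...]] | None = None,
        reference_score: str = "qsofa_ed",
        ci_method: str = "wilson",
        build: bool = True,
        bt_stages: tuple[str, ...] = BT_STAGES_DEFAULT,
    ) -> None:
        if not len(records):
            raise DataError("empty record set")
        self.records = records
        self.imputation = imputation or ImputationSpec()
        self.surveillance = surveillance or SurveillanceConfig()
        self.outcomes = tuple(outcomes)
        self.cutoffs = dict(cutoffs or SCORE_CUTOFFS)
        self.reference_score = reference_score
        self.ci_method = ci_method
        self.build = build
        self.bt_stages = bt_stages

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "QsofaScreeningModel":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "QsofaScreeningModel":
        return cls(read_cohort(path), **kwargs)

    def fit(self) -> "ScreeningResults":
        if self.build:
            cohort, flow = build_cohort(self.records, bt_stages=self.bt_stages)
        else:
            cohort, flow = self.records.copy(), CohortFlow(
                n_input=len(self.records), n_eligible=len(self.records)
            )
        if not len(cohort):
            raise DataError("no eligible patients after cohort construction")
        cohort, label_summary = label_cohort(cohort, self.surveillance)
        cohort, imputation_diag = fit_impute(cohort, self.imputation)
        cohort = score_cohort(cohort)

        tables: dict[str, dict[str, AccuracyTable]] = {}
        transitions: dict[str, TransitionTable] = {}
        added: dict[str, dict] = {}
        for outcome in self.outcomes:
            tables[outcome] = {}
            for score in SCORES:
                tables[outcome][score] = accuracy_table(
                    cohort, score, outcome, self.cutoffs.get(score, ()),
                    reference_score=self.reference_score, ci_method=self.ci_method,
                )
            transitions[outcome] = transition_table(cohort, outcome)
            n_pos = int(cohort[outcome].sum())
            if n_pos:
                cnt, frac = added_capture(cohort, outcome)
                added[outcome] = {"count": cnt, "fraction": frac, "n_positive": n_pos}
            else:
                added[outcome] = {"count": 0, "fraction": None, "n_positive": 0}

        return ScreeningResults(
            model=self, cohort=cohort, flow=flow, label_summary=label_summary,
            imputation_diagnostics=imputation_diag, tables=tables,
            transitions=transitions, added_capture=added,
        )


@dataclass
class ScreeningResults:
    """Fitted screening evaluation: estimates, uncertainties and diagnostics."""

    model: QsofaScreeningModel
    cohort: pd.DataFrame
    flow: CohortFlow
    label_summary: dict
    imputation_diagnostics: dict
    tables: dict[str, dict[str, AccuracyTable]]
    transitions: dict[str, TransitionTable]
    added_capture: dict[str, dict]
    manifest: dict = field(default_factory=dict)

    # -- accessors ---------------------------------------------------------

    def auc(self, score: str, outcome: str = "sepsis"):
        return self.tables[outcome][score].auc

    def delong_p(self, score: str, outcome: str = "sepsis"):
        return self.tables[outcome][score].delong_p

    def score_distribution(self) -> pd.DataFrame:
        """Tally of qSOFA totals over the cohort (cohort-characteristics shape)."""
        recs = []
        for score, hi in (("qsofa_pre", 3), ("qsofa_ed", 3), ("qsofa_combined", 6)):
            counts = self.cohort[score].value_counts().reindex(range(hi + 1), fill_value=0)
            for val, cnt in counts.items():
                recs.append({
                    "score": score, "value": int(val), "count": int(cnt),
                    "pct": round(100 * cnt / len(self.cohort), 1),
                })
        return pd.DataFrame(recs)

    def accuracy_frame(self, outcome: str) -> pd.DataFrame:
        return pd.concat(
            [t.to_frame() for t in self.tables[outcome].values()], ignore_index=True
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Two-stage qSOFA screening evaluation",
            "=" * 68,
        ]
        lines += self.flow.log_lines()
        ls = self.label_summary
        lines.append(
            "Outcomes: sepsis {sc} ({sp}%), septic shock {kc} ({kp}%), "
            "in-hospital death {mc} ({mp}%)".format(
                sc=ls["sepsis"]["count"], sp=ls["sepsis"]["pct"],
                kc=ls["septic_shock"]["count"], kp=ls["septic_shock"]["pct"],
                mc=ls["in_hospital_mortality"]["count"],
                mp=ls["in_hospital_mortality"]["pct"],
            )
        )
        imputed = sum(self.imputation_diagnostics["imputed_counts"].values())
        lines.append(
            f"Imputed {imputed} missing vital-sign cells in "
            f"{self.imputation_diagnostics['iterations']} iteration(s)"
        )
        for outcome in self.model.outcomes:
            lines.append("")
            lines.append(f"--- {outcome.replace('_', ' ')} ---")
            lines.append(
                self.accuracy_frame(outcome).to_string(index=False, justify="left")
            )
            ac = self.added_capture[outcome]
            if ac["n_positive"]:
                lines.append(
                    f"added capture (combined >= 3, ED < 2): {ac['count']}/"
                    f"{ac['n_positive']} = {100 * ac['fraction']:.0f}% of "
                    f"{outcome.replace('_', ' ')} patients"
                )
        return "\n".join(lines)

    def _build_manifest(self, seed: int | None = None) -> dict:
        import scipy
        import sklearn
        import statsmodels

        return {
            "package": {"sepsisscreen": __version__},
            "versions": {
                "numpy": np.__version__, "pandas": pd.__version__,
                "scipy": scipy.__version__, "scikit-learn": sklearn.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "seed": seed,
            "imputation": config_to_dict(self.model.imputation),
            "surveillance": config_to_dict(self.model.surveillance),
            "outcomes": list(self.model.outcomes),
            "cutoffs": {k: list(v) for k, v in self.model.cutoffs.items()},
            "ci_method": self.model.ci_method,
            "qsofa_cutoff_rules": {
                "ed": str(CutoffRule("qsofa_ed", 2)),
                "combined": str(CutoffRule("qsofa_combined", 3)),
            },
        }

    def save(self, outdir: str | Path, seed: int | None = None) -> None:
        """Write the report bundle (tables, flow, diagnostics, manifest)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.flow.save(outdir / "cohort_flow.json")
        (outdir / "imputation_diagnostics.json").write_text(
            json.dumps(self.imputation_diagnostics, indent=2)
        )
        (outdir / "label_summary.json").write_text(
            json.dumps(self.label_summary, indent=2)
        )
        self.score_distribution().to_csv(outdir / "score_distribution.csv", index=False)
        for outcome in self.model.outcomes:
            self.accuracy_frame(outcome).to_csv(
                outdir / f"accuracy_{outcome}.csv", index=False
            )
            pd.concat(
                [t.to_long_frame() for t in self.tables[outcome].values()],
                ignore_index=True,
            ).to_csv(outdir / f"accuracy_{outcome}_long.csv", index=False)
            self.transitions[outcome].to_frame().to_csv(
                outdir / f"transitions_{outcome}.csv", index=False
            )
            for score in SCORES:
                roc_coordinates(
                    self.cohort[score], self.cohort[outcome]
                ).to_csv(outdir / f"roc_{outcome}_{score}.csv", index=False)
        (outdir / "added_capture.json").write_text(
            json.dumps(self.added_capture, indent=2)
        )
        manifest = self._build_manifest(seed)
        manifest.update(self.manifest)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (outdir / "summary.txt").write_text(self.summary() + "\n")
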