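"""Model/Results surface for a triage diagnostic-accuracy study.

:class:`PETriageStudy` is constructed from a labelled cohort (CSV,
DataFrame, records, or simulation) together with a triage configuration;
``fit()`` runs the requested rule engines against every patient, scores
them against the imaging reference standard, and returns a
:class:`TriageStudyResults` holding the confusion matrices, the
eight-metric panel per algorithm, all pairwise imaging/missed-diagnosis
differences, and a ``summary()`` table.

Example
-------
>>> from petriage import PETriageStudy
>>> study = PETriageStudy.from_simulation(seed=42)
>>> res = study.fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .accuracy import (ConfusionMatrix, DiagnosticMetrics, PairwiseComparison,
                       build_confusion_matrix, compare_groups, compute_metrics,
                       pairwise_difference, render_report)
from .records import CohortTable, read_cohort
from .rules import ALGORITHMS, TriageConfig, decisions_to_frame, run_all
from .simulate import CohortSimConfig, generate_cohort

__all__ = ["PETriageStudy", "TriageStudyResults"]


class PETriageStudy:
    """Diagnostic-accuracy comparison of PE triage algorithms on one cohort.

    Parameters
    ----------
    cohort
        Labelled cohort (every record needs ``confirmed_pe``).
    config
        Shared thresholds / Wells weights / C-PTP scheme.
    algorithms
        Names to evaluate; default all five.
    """

    def __init__(self, cohort: CohortTable, config: Optional[TriageConfig] = None,
                 algorithms: Optional[Sequence[str]] = None):
        cohort.require_truth()
        self.cohort = cohort
        self.config = config or TriageConfig()
        self.algorithms = list(ALGORITHMS) if algorithms is None else list(algorithms)
        unknown = [a for a in self.algorithms if a not in ALGORITHMS]
        if unknown:
            raise ValueError(f"unknown algorithm(s) {unknown}; valid: {sorted(ALGORITHMS)}")

    @classmethod
    def from_csv(cls, path, config: Optional[TriageConfig] = None,
                 algorithms: Optional[Sequence[str]] = None,
                 d_dimer_in_ug_ml: bool = False) -> "PETriageStudy":
        cohort = read_cohort(path, d_dimer_in_ug_ml=d_dimer_in_ug_ml)
        return cls(cohort, config=config, algorithms=algorithms)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: Optional[TriageConfig] = None,
                       algorithms: Optional[Sequence[str]] = None) -> "PETriageStudy":
        return cls(CohortTable.from_dataframe(df), config=config, algorithms=algorithms)

    @classmethod
    def from_simulation(cls, sim_config: Optional[CohortSimConfig] = None,
                        seed: Optional[int] = None,
                        config: Optional[TriageConfig] = None,
                        algorithms: Optional[Sequence[str]] = None) -> "PETriageStudy":
        cohort = generate_cohort(sim_config or CohortSimConfig(), seed=seed)
        return cls(cohort, config=config, algorithms=algorithms)

    def fit(self, rounding: str = "published") -> "TriageStudyResults":
        """Run the engines, score against the reference standard."""
        decisions = run_all(self.cohort, self.config, self.algorithms)
        truth = {r.patient_id: r.confirmed_pe for r in self.cohort}
        confusion = {name: build_confusion_matrix(list(per.values()), truth)
                     for name, per in decisions.items()}
        metrics = {name: compute_metrics(cm, rounding=rounding, algorithm=name)
                   for name, cm in confusion.items()}
        comparisons = [pairwise_difference(metrics[a], metrics[b], len(self.cohort))
                       for a, b in combinations(self.algorithms, 2)]
        return TriageStudyResults(self, decisions, confusion, metrics,
                                  comparisons, rounding)


class TriageStudyResults:
    """Fitted results: confusion matrices, metric panels, pairwise grid."""

    def __init__(self, model: PETriageStudy, decisions, confusion, metrics,
                 comparisons, rounding: str):
        self.model = model
        self.decisions: Dict[str, Dict[str, object]] = decisions
        self.confusion: Dict[str, ConfusionMatrix] = confusion
        self.metrics: Dict[str, DiagnosticMetrics] = metrics
        self.comparisons: List[PairwiseComparison] = comparisons
        self.rounding = rounding
        self.n = len(model.cohort)
        self.prevalence = sum(bool(r.confirmed_pe) for r in model.cohort) / self.n

    def metrics_frame(self) -> pd.DataFrame:
        """Metric panel as a DataFrame (algorithms x metrics)."""
        return pd.DataFrame([vars(m) for m in self.metrics.values()]).set_index("algorithm")

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])

    def decisions_frame(self) -> pd.DataFrame:
        return decisions_to_frame(self.decisions)

    def group_comparison(self, equal_var: bool = True) -> pd.DataFrame:
        """Baseline-characteristics comparison of PE-absent vs PE-present."""
        return compare_groups(self.model.cohort, equal_var=equal_var)

    def summary(self, fmt: str = "markdown") -> str:
        """Render the metric panel and pairwise grid as a report document."""
        header = {
            "cohort": f"{self.model.cohort.source} (n={self.n}, "
                      f"PE prevalence {100 * self.prevalence:.1f}%)",
            "C-PTP scheme": f"{self.model.config.scheme.name} "
                            f"(low<= {self.model.config.scheme.low_max:g}, "
                            f"moderate<= {self.model.config.scheme.moderate_max:g})",
            "rounding convention": self.rounding,
        }
        return render_report(self.metrics, self.comparisons, fmt=fmt,
                             confusion=self.confusion, header=header)

    def __repr__(self) -> str:
        algs = ", ".join(self.metrics)
        return (f"<TriageStudyResults n={self.n} "
                f"prevalence={100 * self.prevalence:.1f}% algorithms=[{algs}]>")
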