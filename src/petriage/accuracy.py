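"""Diagnostic-test-accuracy evaluation of triage decisions.

The reference standard is imaging-adjudicated PE status; the *positive*
prediction is ``imaging_required`` (PE not excluded), so a false negative
is a missed diagnosis — a patient with confirmed PE whom an algorithm ruled
out without imaging.

The eight-metric panel is sensitivity, specificity, PPV, NPV, positive and
negative likelihood ratios (PLR = sens/(1-spec), NLR = (1-sens)/spec),
Youden index (sens + spec - 1) and diagnostic accuracy ((TP+TN)/N).  Two
rounding conventions are supported:

``"published"`` (default)
    percentages half-up to one decimal; PLR/NLR/Youden computed from
    sensitivity and specificity first rounded to three-decimal
    proportions.  This matches how clinical DTA tables are typically
    assembled from already-rounded percentages.
``"exact"``
    unrounded proportions throughout (use for new analyses).

Undefined ratios (zero denominators) are reported as ``None`` and rendered
"N/A", never thrown.  An engine that sends the entire cohort to imaging
(no rule-outs at all) gets everything but PPV marked N/A by default, since
sensitivity/specificity of an exhaustive test carry no information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .records import BOOLEAN_FIELDS, CohortTable
from .rules import AlgorithmDecision, Verdict
from .wells import WellsWeights, compute_wells_score

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "PairwiseComparison",
    "round_half_up",
    "build_confusion_matrix",
    "compute_metrics",
    "pairwise_difference",
    "chi_square_from_counts",
    "ttest_from_summary",
    "compare_groups",
    "render_report",
]


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (0.5 always away from zero), unlike banker's."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts of decisions against confirmed PE status.

    tp: imaging_required & PE present;  fp: imaging_required & PE absent;
    fn: rule_out & PE present (missed diagnosis);  tn: rule_out & PE absent.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def imaging_count(self) -> int:
        return self.tp + self.fp

    @property
    def missed_count(self) -> int:
        return self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Eight-metric DTA panel; percentages on the 0-100 scale, None = N/A."""

    algorithm: str
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    plr: Optional[float]
    nlr: Optional[float]
    youden: Optional[float]
    accuracy: Optional[float]
    imaging_count: int
    missed_count: Optional[int]
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    """Imaging-burden and missed-diagnosis differences (a minus b)."""

    algorithm_a: str
    algorithm_b: str
    imaging_diff: int
    imaging_diff_pct: float
    missed_diff: Optional[int]
    missed_diff_pct: Optional[float]
    not_applicable_missed: bool


def build_confusion_matrix(
    decisions: Sequence[AlgorithmDecision],
    truth: Mapping[str, bool],
) -> ConfusionMatrix:
    """Count decisions against per-patient truth labels.

    ``truth`` maps patient_id -> confirmed PE status and must cover every
    decision; duplicate decisions for one patient are rejected.
    """
    seen: set[str] = set()
    tp = fp = fn = tn = 0
    for decision in decisions:
        pid = decision.patient_id
        if pid in seen:
            raise ValueError(f"duplicate decision for patient {pid!r}")
        seen.add(pid)
        if pid not in truth or truth[pid] is None:
            raise ValueError(f"missing confirmed_pe truth label for patient {pid!r}")
        positive = decision.verdict is Verdict.IMAGING_REQUIRED
        if positive and truth[pid]:
            tp += 1
        elif positive:
            fp += 1
        elif truth[pid]:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(
    cm: ConfusionMatrix,
    rounding: str = "published",
    algorithm: str = "",
    exhaustive_na: bool = True,
) -> DiagnosticMetrics:
    """Derive the eight-metric panel from a confusion matrix.

    With ``exhaustive_na`` (default), an algorithm with no rule-outs at
    all (fn = tn = 0, i.e. the whole cohort is test-positive) reports only
    PPV, mirroring how such a column is conventionally presented.
    """
    if rounding not in ("published", "exact"):
        raise ValueError(
            f"unknown rounding convention {rounding!r}; use 'published' or 'exact'")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    acc = _ratio(cm.tp + cm.tn, cm.n)

    if rounding == "published":
        sens_r = None if sens is None else round_half_up(sens, 3)
        spec_r = None if spec is None else round_half_up(spec, 3)
    else:
        sens_r, spec_r = sens, spec

    plr = None if sens_r is None or spec_r is None else _ratio(sens_r, 1.0 - spec_r)
    nlr = None if sens_r is None or spec_r is None else _ratio(1.0 - sens_r, spec_r)
    youden = None if sens_r is None or spec_r is None else sens_r + spec_r - 1.0

    def pct(p: Optional[float]) -> Optional[float]:
        if p is None:
            return None
        return round_half_up(p * 100.0, 1) if rounding == "published" else p * 100.0

    def rat(r: Optional[float]) -> Optional[float]:
        if r is None:
            return None
        return round_half_up(r, 3) if rounding == "published" else r

    exhaustive = exhaustive_na and cm.fn == 0 and cm.tn == 0
    return DiagnosticMetrics(
        algorithm=algorithm,
        sensitivity=None if exhaustive else pct(sens),
        specificity=None if exhaustive else pct(spec),
        ppv=pct(ppv),
        npv=None if exhaustive else pct(npv),
        plr=None if exhaustive else rat(plr),
        nlr=None if exhaustive else rat(nlr),
        youden=None if exhaustive else rat(youden),
        accuracy=None if exhaustive else pct(acc),
        imaging_count=cm.imaging_count,
        missed_count=None if exhaustive else cm.missed_count,
        n=cm.n,
    )


def pairwise_difference(
    metrics_a: DiagnosticMetrics,
    metrics_b: DiagnosticMetrics,
    n_total: int,
) -> PairwiseComparison:
    """Imaging and missed-diagnosis differences between two algorithms.

    Percentages are of the full cohort size ``n_total``, half-up to one
    decimal.  The missed comparison is flagged not-applicable when either
    side's missed count is undefined by construction (an exhaustive-imaging
    algorithm defines the reference imaging set and misses nobody by
    design, so the comparison is not meaningful).
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    imaging_diff = metrics_a.imaging_count - metrics_b.imaging_count
    imaging_pct = round_half_up(100.0 * imaging_diff / n_total, 1)
    if metrics_a.missed_count is None or metrics_b.missed_count is None:
        return PairwiseComparison(metrics_a.algorithm, metrics_b.algorithm,
                                  imaging_diff, imaging_pct, None, None, True)
    missed_diff = metrics_a.missed_count - metrics_b.missed_count
    missed_pct = round_half_up(100.0 * missed_diff / n_total, 1)
    return PairwiseComparison(metrics_a.algorithm, metrics_b.algorithm,
                              imaging_diff, imaging_pct, missed_diff, missed_pct, False)


def chi_square_from_counts(a_pos: int, a_n: int, b_pos: int, b_n: int,
                           correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table given per-group positives and sizes.

    No Yates continuity correction by default.  Returns (statistic, p).
    """
    table = [[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]]
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test from summary statistics. Returns (statistic, p)."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


_CONTINUOUS_FIELDS = ("age", "heart_rate", "sao2", "d_dimer", "bode_index")


def compare_groups(cohort: CohortTable, equal_var: bool = True) -> pd.DataFrame:
    """Compare PE-absent vs PE-present groups variable by variable.

    Continuous fields (age, heart rate, SaO2, D-dimer, BODE index, and the
    computed Wells score) get group mean +/- SD and a two-sample t-test;
    boolean items get group counts (%) and a Pearson chi-square (2x2, 1 df,
    no continuity correction).  Output is one row per variable, shaped like
    a standard baseline-characteristics table.
    """
    cohort.require_truth()
    df = cohort.to_dataframe()
    df["wells_score"] = [compute_wells_score(r) for r in cohort]
    neg = df[~df["confirmed_pe"].astype(bool)]
    pos = df[df["confirmed_pe"].astype(bool)]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both PE-absent and PE-present groups must be non-empty")

    rows = []
    for col in _CONTINUOUS_FIELDS + ("wells_score",):
        x, y = neg[col].dropna(), pos[col].dropna()
        if len(x) < 2 or len(y) < 2:
            rows.append({"variable": col, "kind": "continuous",
                         "pe_absent": "NA", "pe_present": "NA",
                         "statistic": None, "p_value": None, "test": "t-test (not computable)"})
            continue
        stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
        rows.append({
            "variable": col, "kind": "continuous",
            "pe_absent": f"{x.mean():.1f} ± {x.std(ddof=1):.1f}",
            "pe_present": f"{y.mean():.1f} ± {y.std(ddof=1):.1f}",
            "statistic": float(stat), "p_value": float(p), "test": "t-test",
        })
    derived_bools = {
        "tachycardia_hr_gt_100": df["heart_rate"] > 100,
        "sao2_le_94": df["sao2"] <= 94,
        "age_lt_50": df["age"] < 50,
    }
    for col in BOOLEAN_FIELDS + tuple(derived_bools):
        series = derived_bools.get(col, df.get(col))
        a_pos = int(series[neg.index].sum())
        b_pos = int(series[pos.index].sum())
        total_pos = a_pos + b_pos
        if total_pos == 0 or total_pos == len(df):
            # item absent (or universal) in both groups: 2x2 is degenerate
            stat, p, test = None, None, "chi-square (not computable)"
        else:
            stat, p = chi_square_from_counts(a_pos, len(neg), b_pos, len(pos))
            test = "chi-square"
        rows.append({
            "variable": col, "kind": "boolean",
            "pe_absent": f"{a_pos} ({100 * a_pos / len(neg):.1f}%)",
            "pe_present": f"{b_pos} ({100 * b_pos / len(pos):.1f}%)",
            "statistic": stat, "p_value": p, "test": test,
        })
    return pd.DataFrame(rows)


_METRIC_ROWS = [
    ("TP", lambda m, c: c.tp), ("FP", lambda m, c: c.fp),
    ("FN", lambda m, c: None if m.missed_count is None else c.fn),
    ("TN", lambda m, c: None if m.missed_count is None else c.tn),
    ("Sensitivity %", lambda m, c: m.sensitivity),
    ("Specificity %", lambda m, c: m.specificity),
    ("PPV %", lambda m, c: m.ppv), ("NPV %", lambda m, c: m.npv),
    ("PLR", lambda m, c: m.plr), ("NLR", lambda m, c: m.nlr),
    ("Youden index", lambda m, c: m.youden),
    ("Diagnostic accuracy %", lambda m, c: m.accuracy),
]


def _fmt(value) -> str:
    if value is None:
        return "N/A"
    if isinstance(value, int):
        return str(value)
    return f"{value:g}"


def render_report(
    metrics: Dict[str, DiagnosticMetrics],
    comparisons: Sequence[PairwiseComparison] = (),
    fmt: str = "markdown",
    confusion: Optional[Dict[str, ConfusionMatrix]] = None,
    header: Optional[Mapping[str, str]] = None,
) -> str:
    """Render the metric panel (and pairwise grid) as markdown, TSV or JSON.

    Output is deterministic and byte-stable for fixed inputs; the header
    records the C-PTP scheme and rounding convention in use.
    """
    if not metrics:
        raise ValueError("at least one algorithm's metrics are required")
    if fmt not in ("markdown", "tsv", "json"):
        raise ValueError(f"unknown format {fmt!r}; use markdown, tsv or json")
    header = dict(header or {})
    names = list(metrics)
    confusion = confusion or {}

    if fmt == "json":
        payload = {
            "header": header,
            "metrics": {
                name: {k: v for k, v in vars(m).items()} for name, m in metrics.items()
            },
            "comparisons": [vars(c) for c in comparisons],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    lines: list[str] = []
    if fmt == "markdown":
        for key, value in header.items():
            lines.append(f"**{key}**: {value}  ")
        if header:
            lines.append("")
        lines.append("| Metric | " + " | ".join(names) + " |")
        lines.append("|" + "---|" * (len(names) + 1))
        for label, getter in _METRIC_ROWS:
            cells = []
            for name in names:
                cm = confusion.get(name)
                if cm is None and label in ("TP", "FP", "FN", "TN"):
                    cells.append("-")
                else:
                    cells.append(_fmt(getter(metrics[name], cm)))
            lines.append(f"| {label} | " + " | ".join(cells) + " |")
        if comparisons:
            lines.append("")
            lines.append("| Difference | Chest imaging no. (%) | Missed diagnoses no. (%) |")
            lines.append("|---|---|---|")
            for c in comparisons:
                img = f"{c.imaging_diff} ({c.imaging_diff_pct:g})"
                mis = "N/A" if c.not_applicable_missed else f"{c.missed_diff} ({c.missed_diff_pct:g})"
                lines.append(f"| {c.algorithm_a} - {c.algorithm_b} | {img} | {mis} |")
    else:  # tsv
        for key, value in header.items():
            lines.append(f"# {key}: {value}")
        lines.append("metric\t" + "\t".join(names))
        for label, getter in _METRIC_ROWS:
            cells = []
            for name in names:
                cm = confusion.get(name)
                if cm is None and label in ("TP", "FP", "FN", "TN"):
                    cells.append("-")
                else:
                    cells.append(_fmt(getter(metrics[name], cm)))
            lines.append(label + "\t" + "\t".join(cells))
        for c in comparisons:
            mis = "N/A" if c.not_applicable_missed else f"{c.missed_diff} ({c.missed_diff_pct:g})"
            lines.append(f"{c.algorithm_a}-{c.algorithm_b}\t"
                         f"{c.imaging_diff} ({c.imaging_diff_pct:g})\t{mis}")
    return "\n".join(lines) + "\n"
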