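"""Synthetic AECOPD cohort generator.

Emulates the marginal structure of a hospital AECOPD cohort screened for
pulmonary embolism: a fixed PE prevalence (exact-count allocation, not a
binomial draw), group-specific D-dimer distributions (moment-matched
log-normal — positive support and the right skew typical of D-dimer),
continuous vitals consistent with target exceedance fractions (HR > 100,
SaO2 <= 94), an age mixture with a pinned under-50 fraction, and
independent-within-group Bernoulli clinical items, except:

* ``unilateral_leg_swelling`` is coupled to ``dvt_signs`` (a conditional
  probability, since leg swelling is part of the DVT picture);
* ``pe_most_likely`` comes from a logistic link on the record's
  Wells-relevant items, with a per-group intercept solved numerically so
  the expected group fraction hits the configured target.

Only marginals are calibrated: the generator makes no claim about the
joint distribution (e.g. D-dimer x Wells correlation), which real cohorts
have and the targets do not constrain.  The Wells score is always computed
from the generated items, never sampled directly, so records are
internally consistent; its group means are therefore advisory only in
:func:`validate_marginals`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .records import CohortTable, PatientRecord

__all__ = ["GroupSpec", "CohortSimConfig", "generate_cohort",
           "validate_marginals", "MarginalCheck", "ValidationReport"]


@dataclass(frozen=True)
class GroupSpec:
    """Target marginals for one truth group (PE-absent or PE-present)."""

    d_dimer_mean: float          # ng/ml
    d_dimer_sd: float            # ng/ml
    age_mean: float = 66.9       # years
    age_sd: float = 18.6
    frac_age_under_50: float = 0.027
    frac_hr_over_100: float = 0.525
    frac_sao2_le_94: float = 0.850
    p_dvt_signs: float = 0.101
    p_recent_immobilization: float = 0.675
    p_recent_surgery: float = 0.104
    p_history_vte: float = 0.089
    p_hemoptysis: float = 0.070
    p_active_cancer: float = 0.155
    p_oral_hormone_use: float = 0.290
    p_recent_trauma: float = 0.05
    p_pe_most_likely: float = 0.585
    p_leg_swelling_given_dvt: float = 0.60
    p_leg_swelling_base: float = 0.05

    def proportions(self) -> Dict[str, float]:
        return {k: v for k, v in vars(self).items()
                if k.startswith(("p_", "frac_"))}


# Table-2-style defaults: PE-absent (n=948) vs PE-present (n=210) marginals.
_PE_ABSENT = GroupSpec(d_dimer_mean=1191.0, d_dimer_sd=676.0)
_PE_PRESENT = GroupSpec(
    d_dimer_mean=3118.0, d_dimer_sd=1635.0,
    age_mean=68.1, age_sd=20.3, frac_age_under_50=0.024,
    frac_hr_over_100=0.514, frac_sao2_le_94=0.895,
    p_dvt_signs=0.314, p_recent_immobilization=0.886, p_recent_surgery=0.214,
    p_history_vte=0.100, p_hemoptysis=0.057, p_active_cancer=0.257,
    p_oral_hormone_use=0.371, p_pe_most_likely=0.843,
)

#: Fixed item weights of the pe_most_likely logistic link (log-odds scale).
_PE_LIKELY_BETAS = {
    "dvt_signs": 1.0,
    "recent_immobilization": 0.5,
    "recent_surgery": 0.5,
    "history_vte": 0.5,
    "active_cancer": 0.5,
}

_AGE_LO, _AGE_HI = 18.0, 100.0
_HR_NOISE_SD = 15.0   # beats/min
_SAO2_NOISE_SD = 3.0  # percent


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort size, prevalence and per-group target marginals."""

    n_total: int = 1158
    prevalence: float = 210.0 / 1158.0
    pe_absent: GroupSpec = field(default_factory=lambda: _PE_ABSENT)
    pe_present: GroupSpec = field(default_factory=lambda: _PE_PRESENT)
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        for spec in (self.pe_absent, self.pe_present):
            if spec.d_dimer_sd <= 0 or spec.age_sd <= 0:
                raise ValueError("standard deviations must be positive")
            for name, p in spec.proportions().items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name} must lie in [0, 1], got {p}")


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("log-normal moment matching needs mean > 0 and sd > 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    if hi <= lo:
        raise ValueError("infeasible truncation bounds")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_ages(rng: np.random.Generator, spec: GroupSpec, size: int) -> np.ndarray:
    """Two-component age mixture pinning the under-50 fraction.

    A plain truncated normal at the configured mean/sd puts more mass
    under 50 than the target fraction, so membership of the under-50
    stratum is drawn first and each stratum is a truncated normal.
    """
    under = rng.random(size) < spec.frac_age_under_50
    ages = np.empty(size)
    n_under = int(under.sum())
    if n_under:
        ages[under] = _truncnorm(rng, spec.age_mean, spec.age_sd, _AGE_LO, 50.0 - 1e-9, n_under)
    if size - n_under:
        ages[~under] = _truncnorm(rng, spec.age_mean, spec.age_sd, 50.0, _AGE_HI,
                                  size - n_under)
    return np.floor(ages).astype(int)


def _exceedance_mean(threshold: float, frac_above: float, sd: float) -> float:
    # mean of a normal with P(X > threshold) = frac_above
    return threshold - sd * stats.norm.ppf(1.0 - frac_above)


def _solve_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean(sigmoid(b0 + lin)) = target."""
    if target <= 0.0:
        return -math.inf
    if target >= 1.0:
        return math.inf

    def gap(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + lin))))) - target

    return optimize.brentq(gap, -30.0, 30.0, xtol=1e-10)


def _generate_group(rng: np.random.Generator, spec: GroupSpec, size: int,
                    confirmed: bool, id_prefix: str) -> List[PatientRecord]:
    if size == 0:
        return []
    ages = _sample_ages(rng, spec, size)
    mu, sigma = _lognormal_params(spec.d_dimer_mean, spec.d_dimer_sd)
    d_dimer = np.round(rng.lognormal(mu, sigma, size), 1)
    # vitals are rounded to integers, so the exceedance is solved at the
    # half-integer boundary (rounded HR > 100 iff continuous HR >= 100.5)
    hr_mean = _exceedance_mean(100.5, spec.frac_hr_over_100, _HR_NOISE_SD)
    heart_rate = np.round(np.clip(rng.normal(hr_mean, _HR_NOISE_SD, size), 30.0, 220.0), 0)
    # SaO2 target is a *non*-exceedance (P <= 94), hence 1 - frac above 94.5
    sao2_mean = _exceedance_mean(94.5, 1.0 - spec.frac_sao2_le_94, _SAO2_NOISE_SD)
    sao2 = np.round(np.clip(rng.normal(sao2_mean, _SAO2_NOISE_SD, size), 40.0, 100.0), 0)

    bools = {
        name: rng.random(size) < getattr(spec, f"p_{name}")
        for name in ("dvt_signs", "recent_immobilization", "recent_surgery",
                     "history_vte", "hemoptysis", "active_cancer",
                     "oral_hormone_use", "recent_trauma")
    }
    swell_p = np.where(bools["dvt_signs"], spec.p_leg_swelling_given_dvt,
                       spec.p_leg_swelling_base)
    bools["unilateral_leg_swelling"] = rng.random(size) < swell_p

    lin = sum(beta * bools[name].astype(float) for name, beta in _PE_LIKELY_BETAS.items())
    b0 = _solve_intercept(np.asarray(lin), spec.p_pe_most_likely)
    if math.isinf(b0):
        bools["pe_most_likely"] = np.full(size, b0 > 0)
    else:
        probs = 1.0 / (1.0 + np.exp(-(b0 + lin)))
        bools["pe_most_likely"] = rng.random(size) < probs

    records = []
    for i in range(size):
        records.append(PatientRecord(
            patient_id=f"{id_prefix}{i + 1:04d}",
            age=int(ages[i]),
            heart_rate=float(heart_rate[i]),
            sao2=float(sao2[i]),
            d_dimer=float(d_dimer[i]),
            confirmed_pe=confirmed,
            **{name: bool(values[i]) for name, values in bools.items()},
        ))
    return records


def generate_cohort(config: CohortSimConfig = CohortSimConfig(),
                    seed: Optional[int] = None) -> CohortTable:
    """Draw a synthetic cohort; fully reproducible given config and seed.

    The PE-positive count is allocated exactly as round(n x prevalence);
    record ids are PE-absent "N...", PE-present "P...".  An explicit
    ``seed`` overrides ``config.seed``.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_pos = round(config.n_total * config.prevalence)
    n_neg = config.n_total - n_pos
    records: List[PatientRecord] = []
    records += _generate_group(rng, config.pe_absent, n_neg, False, "N")
    records += _generate_group(rng, config.pe_present, n_pos, True, "P")
    return CohortTable(records, source=f"synthetic(seed={seed})")


@dataclass(frozen=True)
class MarginalCheck:
    group: str
    name: str
    target: float
    observed: float
    passed: bool
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    checks: List[MarginalCheck]
    alpha: float

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> List[MarginalCheck]:
        return [c for c in self.checks if not c.passed]


def _sd_standard_error(mean: float, sd: float, n: int) -> float:
    """SE of the sample SD under the moment-matched log-normal law.

    Uses Var(s^2) ~ (kappa_excess + 2) sigma^4 / n and the delta method;
    the normal-theory sd/sqrt(2n) would be far too tight for a
    right-skewed, heavy-tailed D-dimer distribution.
    """
    mu, sigma = _lognormal_params(mean, sd)
    excess = float(stats.lognorm.stats(sigma, scale=math.exp(mu), moments="k"))
    return sd * math.sqrt((excess + 2.0) / (4.0 * n))


def validate_marginals(cohort: CohortTable, config: CohortSimConfig = CohortSimConfig(),
                       alpha: float = 0.001) -> ValidationReport:
    """Check generated marginals against the configured targets.

    Proportions use an exact two-sided binomial test (pass iff p >= alpha);
    D-dimer mean and SD use z-intervals at level alpha (SD standard error
    from the log-normal fourth moment).  Wells-score means are reported
    nowhere here: they are a consequence of the item marginals, not a
    target.  Overall pass iff every individual check passes.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    cohort.require_truth()
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    checks: List[MarginalCheck] = []
    groups = {
        "pe_absent": ([r for r in cohort if not r.confirmed_pe], config.pe_absent),
        "pe_present": ([r for r in cohort if r.confirmed_pe], config.pe_present),
    }
    for gname, (records, spec) in groups.items():
        n = len(records)
        if n == 0:
            raise ValueError(f"empty group {gname!r}")
        derived = {
            "frac_hr_over_100": sum(r.heart_rate > 100 for r in records),
            "frac_sao2_le_94": sum(r.sao2 <= 94 for r in records),
            "frac_age_under_50": sum(r.age < 50 for r in records),
        }
        for pname, target in spec.proportions().items():
            if pname in ("p_leg_swelling_given_dvt", "p_leg_swelling_base"):
                continue  # conditional parameters, not group marginals
            if pname in derived:
                count = derived[pname]
            else:
                count = sum(getattr(r, pname[2:]) for r in records)
            pval = stats.binomtest(count, n, target).pvalue
            checks.append(MarginalCheck(
                gname, pname, target, count / n, bool(pval >= alpha),
                f"binomial exact p={pval:.4g} (count {count}/{n})"))
        values = np.array([r.d_dimer for r in records], dtype=float)
        obs_mean, obs_sd = float(values.mean()), float(values.std(ddof=1))
        se_mean = spec.d_dimer_sd / math.sqrt(n)
        checks.append(MarginalCheck(
            gname, "d_dimer_mean", spec.d_dimer_mean, obs_mean,
            bool(abs(obs_mean - spec.d_dimer_mean) <= z * se_mean),
            f"z-interval half-width {z * se_mean:.1f} ng/ml"))
        se_sd = _sd_standard_error(spec.d_dimer_mean, spec.d_dimer_sd, n)
        checks.append(MarginalCheck(
            gname, "d_dimer_sd", spec.d_dimer_sd, obs_sd,
            bool(abs(obs_sd - spec.d_dimer_sd) <= z * se_sd),
            f"z-interval half-width {z * se_sd:.1f} ng/ml"))
    return ValidationReport(checks=checks, alpha=alpha)
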