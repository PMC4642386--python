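"""Effect estimation for two-arm adherence comparisons.

Implements the full comparative layer: crude adherence rates, unadjusted
risk ratios with Katz log-method confidence intervals and Wald p-values,
covariate-adjusted risk ratios via a modified Poisson model (log-link GLM on
the binary outcome with a robust sandwich variance), the four-level
baseline->follow-up adherence transition analysis with conditional pairwise
risk ratios, absolute risk difference with number needed to treat, and
baseline-characteristics comparison tests.

The Katz log method puts the CI on the log scale:

    log RR +/- z * sqrt(1/a - 1/n1 + 1/c - 1/n2)

with z = 1.96 and no continuity correction; a zero numerator cell yields a
finite point estimate of 0 or an infinite one, with CI and p flagged
non-finite rather than corrected.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .cohort import CohortMember, cohort_to_frame
from .records import Group

__all__ = [
    "TwoByTwo",
    "TransitionLevel",
    "TransitionTable",
    "EffectEstimate",
    "adherence_rate",
    "unadjusted_rr",
    "adjusted_rr",
    "transition_classify",
    "transition_rr",
    "adjusted_transition_rr",
    "risk_difference_and_nnt",
    "baseline_table",
]

logger = logging.getLogger("rxadhere.effects")

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TwoByTwo:
    """Counts behind an unadjusted risk ratio.

    ``a`` of ``n1`` intervention patients and ``c`` of ``n2`` control
    patients have the outcome.
    """

    a: int
    n1: int
    c: int
    n2: int

    def __post_init__(self):
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n2):
            raise ValueError(f"invalid 2x2 counts {self}")

    def swapped(self) -> "TwoByTwo":
        return TwoByTwo(a=self.c, n1=self.n2, c=self.a, n2=self.n1)


class TransitionLevel(enum.Enum):
    """Four-level baseline -> follow-up adherence outcome."""

    NONADHERENT_TO_ADHERENT = "nonadherent_to_adherent"
    ADHERENT_TO_ADHERENT = "adherent_to_adherent"
    NONADHERENT_TO_NONADHERENT = "nonadherent_to_nonadherent"
    ADHERENT_TO_NONADHERENT = "adherent_to_nonadherent"

    @classmethod
    def of(cls, baseline_adherent: bool, followup_adherent: bool
           ) -> "TransitionLevel":
        if baseline_adherent:
            return (cls.ADHERENT_TO_ADHERENT if followup_adherent
                    else cls.ADHERENT_TO_NONADHERENT)
        return (cls.NONADHERENT_TO_ADHERENT if followup_adherent
                else cls.NONADHERENT_TO_NONADHERENT)


#: Reference level for all conditional pairwise transition contrasts.
REFERENCE_LEVEL = TransitionLevel.ADHERENT_TO_NONADHERENT


@dataclass(frozen=True)
class TransitionTable:
    """Per-group counts of the four transition levels."""

    intervention: Mapping[TransitionLevel, int]
    control: Mapping[TransitionLevel, int]

    def counts(self, group: Group) -> Mapping[TransitionLevel, int]:
        return (self.intervention if group is Group.INTERVENTION
                else self.control)

    def group_total(self, group: Group) -> int:
        return sum(self.counts(group).values())


@dataclass(frozen=True)
class EffectEstimate:
    """A comparative result: point estimate, CI, p, and how it was obtained."""

    measure: str  # "RR" | "RD" | "NNT"
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    p: float | None = None
    method: str = ""
    adjusted: bool = False
    comparison: str = ""

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "method": self.method,
            "adjusted": self.adjusted,
            "comparison": self.comparison,
        }


def adherence_rate(flags: Sequence[bool]) -> tuple[int, int, float]:
    """(adherent count, n, proportion) for one arm and period."""
    flags = list(flags)
    if not flags:
        raise ValueError("adherence_rate requires a nonempty cohort")
    k = sum(bool(f) for f in flags)
    return k, len(flags), k / len(flags)


def unadjusted_rr(t: TwoByTwo, comparison: str = "") -> EffectEstimate:
    """Crude risk ratio with Katz log-method 95% CI and Wald p.

    With a zero cell in either numerator the CI and p are returned
    non-finite (NaN) and the point estimate is 0, inf, or NaN as the ratio
    dictates; no continuity correction is applied.
    """
    p1 = t.a / t.n1
    p2 = t.c / t.n2
    if t.a == 0 and t.c == 0:
        est = math.nan
    elif t.c == 0:
        est = math.inf
    else:
        est = p1 / p2
    if t.a == 0 or t.c == 0:
        logger.info("zero cell in %s; CI/p non-finite", t)
        return EffectEstimate("RR", est, math.nan, math.nan, None,
                              method="katz_log", comparison=comparison)
    se = math.sqrt(1 / t.a - 1 / t.n1 + 1 / t.c - 1 / t.n2)
    log_rr = math.log(est)
    lo, hi = math.exp(log_rr - Z_95 * se), math.exp(log_rr + Z_95 * se)
    p = 2 * stats.norm.sf(abs(log_rr) / se) if se > 0 else (1.0 if est == 1 else 0.0)
    return EffectEstimate("RR", est, lo, hi, float(p),
                          method="katz_log", comparison=comparison)


def _design_matrix(frame: pd.DataFrame, covariates: Sequence[str],
                   outcome: str) -> tuple[pd.DataFrame, pd.Series, int]:
    cols = ["intervention", *covariates]
    sub = frame[[outcome, *cols]].copy()
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.info("excluded %d member(s) with missing covariates from "
                    "adjusted model", n_dropped)
    X = sm.add_constant(sub[cols].astype(float), has_constant="add")
    y = sub[outcome].astype(float)
    return X, y, n_dropped


def _fit_modified_poisson(X: pd.DataFrame, y: pd.Series):
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.loc[:, X.nunique() > 1]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"columns: {list(X.columns)}; check collinearity among "
            f"{list(corr.columns)}"
        )
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(cov_type="HC0", maxiter=100)
    if not res.converged:
        raise RuntimeError(
            f"modified Poisson IRLS failed to converge after "
            f"{res.fit_history['iteration']} iterations; "
            f"deviance={res.deviance:.4g}"
        )
    return res


def adjusted_rr(
    cohort: Sequence[CohortMember] | pd.DataFrame,
    covariates: Sequence[str] = (),
    comparison: str = "",
    method_tag: str = "modified_poisson_robust",
    outcome: str = "followup_adherent",
) -> EffectEstimate:
    """Covariate-adjusted risk ratio, intervention vs control.

    A log-link Poisson GLM on the binary adherence outcome (follow-up by
    default) with an HC0 sandwich covariance ("modified Poisson") estimates
    the RR directly: exp of the intervention coefficient.  Members with a
    missing covariate are excluded (count logged).  With no covariates the
    estimate equals the crude risk ratio exactly (saturated one-factor
    model).
    """
    frame = (cohort if isinstance(cohort, pd.DataFrame)
             else cohort_to_frame(cohort))
    X, y, _ = _design_matrix(frame, covariates, outcome)
    res = _fit_modified_poisson(X, y)
    beta = res.params["intervention"]
    se = res.bse["intervention"]
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    return EffectEstimate(
        "RR",
        float(math.exp(beta)),
        float(math.exp(beta - Z_95 * se)),
        float(math.exp(beta + Z_95 * se)),
        float(p),
        method=method_tag,
        adjusted=True,
        comparison=comparison,
    )


def transition_classify(cohort: Sequence[CohortMember]) -> TransitionTable:
    """Cross-classify every member into exactly one of the four levels."""
    counts = {
        g: {lvl: 0 for lvl in TransitionLevel}
        for g in (Group.INTERVENTION, Group.CONTROL)
    }
    for m in cohort:
        lvl = TransitionLevel.of(m.baseline_adherent, m.followup_adherent)
        counts[m.group][lvl] += 1
    return TransitionTable(
        intervention=counts[Group.INTERVENTION],
        control=counts[Group.CONTROL],
    )


def transition_rr(
    table: TransitionTable,
    level: TransitionLevel,
    reference: TransitionLevel = REFERENCE_LEVEL,
    comparison: str = "",
) -> EffectEstimate:
    """Conditional pairwise risk ratio for ``level`` against ``reference``.

    Within each arm, members outside {level, reference} are set aside and
    the risk of ``level`` among the remainder is formed; the ratio of those
    two conditional risks (intervention / control) is returned with a Katz
    CI, exactly as :func:`unadjusted_rr` of the restricted 2x2.
    """
    if level is reference:
        raise ValueError("level must differ from the reference level")
    ai = table.intervention[level]
    ri = table.intervention[reference]
    ac = table.control[level]
    rc = table.control[reference]
    est = unadjusted_rr(
        TwoByTwo(a=ai, n1=ai + ri, c=ac, n2=ac + rc),
        comparison=comparison or f"{level.value} vs {reference.value}",
    )
    return EffectEstimate(
        "RR", est.estimate, est.ci_low, est.ci_high, est.p,
        method="conditional_pairwise", comparison=est.comparison,
    )


def adjusted_transition_rr(
    cohort: Sequence[CohortMember] | pd.DataFrame,
    level: TransitionLevel,
    reference: TransitionLevel = REFERENCE_LEVEL,
    covariates: Sequence[str] = (),
    comparison: str = "",
) -> EffectEstimate:
    """Covariate-adjusted conditional pairwise transition RR.

    Restricts the cohort to members in {level, reference} and fits the same
    robust log-link estimator as :func:`adjusted_rr` with the indicator of
    ``level`` as the outcome.
    """
    if level is reference:
        raise ValueError("level must differ from the reference level")
    frame = (cohort if isinstance(cohort, pd.DataFrame)
             else cohort_to_frame(cohort))
    lvl = frame.apply(
        lambda r: TransitionLevel.of(
            r["baseline_adherent"], r["followup_adherent"]
        ),
        axis=1,
    ) if len(frame) else pd.Series(dtype=object)
    keep = lvl.isin([level, reference])
    sub = frame[keep].copy()
    sub["followup_adherent"] = (lvl[keep] == level).astype(float)
    est = adjusted_rr(
        sub, covariates,
        comparison=comparison or f"{level.value} vs {reference.value}",
        method_tag="modified_poisson_robust_conditional",
    )
    return est


def risk_difference_and_nnt(
    t: TwoByTwo, comparison: str = ""
) -> tuple[EffectEstimate, EffectEstimate]:
    """Absolute risk difference (Wald CI) and number needed to treat.

    NNT is ``round(1 / RD)`` computed from the unrounded RD and is reported
    only for RD > 0; otherwise it is flagged undefined (infinite estimate).
    """
    p1 = t.a / t.n1
    p2 = t.c / t.n2
    rd = p1 - p2
    se = math.sqrt(p1 * (1 - p1) / t.n1 + p2 * (1 - p2) / t.n2)
    lo, hi = rd - Z_95 * se, rd + Z_95 * se
    p = 2 * stats.norm.sf(abs(rd) / se) if se > 0 else None
    rd_est = EffectEstimate("RD", rd, lo, hi,
                            None if p is None else float(p),
                            method="wald", comparison=comparison)
    if rd > 0:
        nnt = EffectEstimate("NNT", float(round(1.0 / rd)),
                             method="reciprocal_rd", comparison=comparison)
    else:
        nnt = EffectEstimate("NNT", math.inf, method="reciprocal_rd",
                             comparison=comparison)
    return rd_est, nnt


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of how one baseline variable is summarized and tested.

    ``kind`` is ``"continuous_symmetric"`` (two-sample t test, mean/SD),
    ``"continuous_asymmetric"`` (Kruskal-Wallis, median/IQR) or
    ``"categorical"`` (Pearson chi-square on counts, n/%).
    """

    name: str
    kind: str

    def __post_init__(self):
        if self.kind not in (
            "continuous_symmetric", "continuous_asymmetric", "categorical"
        ):
            raise ValueError(f"unknown variable kind {self.kind!r}")


def baseline_table(
    frame: pd.DataFrame,
    specs: Sequence[VariableSpec],
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-variable two-group summaries and two-sided p-values.

    ``frame`` must carry ``group_col`` with values "intervention"/"control".
    Chi-square uses no continuity correction (matching the uncorrected
    Pearson statistic); a categorical variable with an all-zero column is
    flagged invalid (p = NaN).
    """
    gi = frame[frame[group_col] == "intervention"]
    gc = frame[frame[group_col] == "control"]
    rows = []
    for spec in specs:
        xi = gi[spec.name].dropna()
        xc = gc[spec.name].dropna()
        if spec.kind == "continuous_symmetric":
            p = float(stats.ttest_ind(xi, xc, equal_var=True).pvalue)
            s1 = f"{xi.mean():.1f} ({xi.std(ddof=1):.1f})"
            s2 = f"{xc.mean():.1f} ({xc.std(ddof=1):.1f})"
        elif spec.kind == "continuous_asymmetric":
            p = float(stats.kruskal(xi, xc).pvalue)
            s1 = (f"{xi.median():.1f} "
                  f"({xi.quantile(.25):.1f}-{xi.quantile(.75):.1f})")
            s2 = (f"{xc.median():.1f} "
                  f"({xc.quantile(.25):.1f}-{xc.quantile(.75):.1f})")
        else:
            ki, kc = int(xi.sum()), int(xc.sum())
            tab = np.array(
                [[ki, len(xi) - ki], [kc, len(xc) - kc]], dtype=float
            )
            if (tab.sum(axis=0) == 0).any():
                logger.warning("all-zero column for %s; chi-square invalid",
                               spec.name)
                p = math.nan
            else:
                p = float(
                    stats.chi2_contingency(tab, correction=False)[1]
                )
            s1 = f"{ki} ({100 * ki / len(xi):.1f})"
            s2 = f"{kc} ({100 * kc / len(xc):.1f})"
        rows.append(
            {"variable": spec.name, "kind": spec.kind,
             "intervention": s1, "control": s2, "p": p}
        )
    return pd.DataFrame(rows)
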