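"""The normalized class-enrichment statistic and its GC regression.

For a class with mean relative abundance A in one condition and B in
another, the enrichment is

    e = (A - B) / (A + B),

a symmetric, bounded contrast: 0 when the class is equally proportional in
both conditions, +1 / -1 when it is present in only one of them. Its
standard deviation is propagated from the replicate standard deviations
dA, dB by the first-order delta method,

    de = 2 sqrt(B^2 dA^2 + A^2 dB^2) / (A + B)^2,

which follows from the gradient (df/dA, df/dB) = (2B, -2A)/(A+B)^2.

For each unordered pair of conditions, the per-class enrichments are
regressed on the abundance-weighted class GC content by ordinary least
squares; the report carries adjusted R^2, the slope t value and two-sided
p-value, significance stars (* / ** / *** at p < 0.05 / 0.01 / 0.001), and
residual diagnostics (Shapiro-Wilk normality, Breusch-Pagan
homoscedasticity) whose failure flags the row as not meeting assumptions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests

from .class_profiles import ConditionProfile
from .gc_content import ClassGc
from .io_formats import UNCLASSIFIED

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    class_label: str
    condition_a: tuple[str, float]
    condition_b: tuple[str, float]
    a_mean: float
    b_mean: float
    a_sd: float
    b_sd: float
    enrichment: float
    enrichment_sd: float
    defined: bool


@dataclass
class RegressionReport:
    condition_a: tuple[str, float]
    condition_b: tuple[str, float]
    n_classes: int
    slope: float
    intercept: float
    adjusted_r2: float
    t_value: float
    p_value: float
    significance: str
    assumptions_ok: bool
    normality_p: float
    homoscedasticity_p: float


def enrichment(a: float, b: float) -> float:
    """Normalized enrichment (a - b) / (a + b); NaN when a + b = 0."""
    if a < 0 or b < 0:
        raise ValueError("abundances must be non-negative")
    if a + b == 0:
        return math.nan
    return (a - b) / (a + b)


def enrichment_sd(a: float, b: float, da: float, db: float) -> float:
    """Delta-method SD of the enrichment statistic; NaN when a + b = 0."""
    if a < 0 or b < 0:
        raise ValueError("abundances must be non-negative")
    if da < 0 or db < 0:
        raise ValueError("standard deviations must be non-negative")
    if a + b == 0:
        return math.nan
    return 2.0 * math.sqrt(b * b * da * da + a * a * db * db) / (a + b) ** 2


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pairwise_enrichment(profiles: list[ConditionProfile]) -> list[EnrichmentRecord]:
    """One enrichment record per (class, unordered condition pair).

    Pair orientation is fixed by the condition ordering (enzyme name, then
    temperature ascending): within a pair, A is the earlier condition.
    "Unclassified" pools unrelated taxa and is excluded.
    """
    by_cond: dict[tuple[str, float], dict[str, ConditionProfile]] = {}
    for p in profiles:
        by_cond.setdefault(p.condition, {})[p.class_label] = p
    conditions = sorted(by_cond)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions for pairwise enrichment")
    classes = sorted({p.class_label for p in profiles if p.class_label != UNCLASSIFIED})
    records: list[EnrichmentRecord] = []
    for cond_a, cond_b in itertools.combinations(conditions, 2):
        for cls in classes:
            pa = by_cond[cond_a].get(cls)
            pb = by_cond[cond_b].get(cls)
            a, da = (pa.mean_rel_abund, pa.sd_rel_abund) if pa else (0.0, 0.0)
            b, db = (pb.mean_rel_abund, pb.sd_rel_abund) if pb else (0.0, 0.0)
            e = enrichment(a, b)
            records.append(
                EnrichmentRecord(
                    cls, cond_a, cond_b, a, b, da, db,
                    e, enrichment_sd(a, b, da, db), not math.isnan(e),
                )
            )
    return records


def _diagnostics(resid: np.ndarray, exog: np.ndarray) -> tuple[float, float]:
    # Both tests are undefined on numerically constant residuals (the exact
    # collinear limit); treat that as "no evidence against" either assumption.
    if np.ptp(resid) < 1e-10:
        return 1.0, 1.0
    norm_p = float(stats.shapiro(resid).pvalue)
    bp_p = float(het_breuschpagan(resid, exog)[1])
    return norm_p, bp_p


def fit_gc_regression(records: list[EnrichmentRecord],
                      gc: list[ClassGc]) -> RegressionReport:
    """OLS of class enrichment on weighted class GC for one condition pair."""
    pairs = {(r.condition_a, r.condition_b) for r in records}
    if len(pairs) != 1:
        raise ValueError(f"records span {len(pairs)} condition pairs; expected exactly 1")
    (cond_a, cond_b) = next(iter(pairs))
    gc_map = {g.class_label: g.weighted_gc for g in gc}
    pts = [
        (gc_map[r.class_label], r.enrichment)
        for r in records
        if r.defined and r.class_label in gc_map and r.class_label != UNCLASSIFIED
    ]
    dropped = [r.class_label for r in records if not (r.defined and r.class_label in gc_map)]
    if dropped:
        log.info("fit_gc_regression %s vs %s: excluded classes %s", cond_a, cond_b, dropped)
    if len(pts) < 3:
        raise ValueError(f"only {len(pts)} usable classes; need >= 3 for regression")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate covariate: zero GC variance across classes")
    exog = sm.add_constant(x)
    fit = sm.OLS(y, exog).fit()
    norm_p, bp_p = _diagnostics(np.asarray(fit.resid), exog)
    p_value = float(fit.pvalues[1])
    return RegressionReport(
        condition_a=cond_a,
        condition_b=cond_b,
        n_classes=len(pts),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        adjusted_r2=float(fit.rsquared_adj),
        t_value=float(fit.tvalues[1]),
        p_value=p_value,
        significance=significance_stars(p_value),
        assumptions_ok=bool(norm_p >= 0.05 and bp_p >= 0.05),
        normality_p=norm_p,
        homoscedasticity_p=bp_p,
    )


def fit_all_regressions(records: list[EnrichmentRecord], gc: list[ClassGc],
                        holm: bool = False) -> list[RegressionReport]:
    """Fit the GC regression for every condition pair present in ``records``.

    With ``holm`` the p-values (and stars) are Holm step-down adjusted across
    the pairs; the default reports raw per-pair p-values.
    """
    by_pair: dict[tuple, list[EnrichmentRecord]] = {}
    for r in records:
        by_pair.setdefault((r.condition_a, r.condition_b), []).append(r)
    reports = [fit_gc_regression(v, gc) for v in by_pair.values()]
    if holm and reports:
        adjusted = holm_adjust([r.p_value for r in reports])
        for rep, p in zip(reports, adjusted):
            rep.p_value = p
            rep.significance = significance_stars(p)
    return reports


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    if not p_values:
        return []
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p_values, method="holm")[1])


def _cond_txt(cond: tuple[str, float]) -> str:
    return f"{cond[0]} {cond[1]:g}C"


def enrichment_frame(records: list[EnrichmentRecord],
                     gc: list[ClassGc] | None = None) -> pd.DataFrame:
    gc_map = {g.class_label: g.weighted_gc for g in gc} if gc else {}
    return pd.DataFrame(
        {
            "class": [r.class_label for r in records],
            "condition_a": [_cond_txt(r.condition_a) for r in records],
            "condition_b": [_cond_txt(r.condition_b) for r in records],
            "a_mean": [r.a_mean for r in records],
            "b_mean": [r.b_mean for r in records],
            "enrichment": [r.enrichment for r in records],
            "enrichment_sd": [r.enrichment_sd for r in records],
            "weighted_gc": [gc_map.get(r.class_label, np.nan) for r in records],
            "defined": [r.defined for r in records],
        }
    )


def regressions_frame(reports: list[RegressionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition_a": [_cond_txt(r.condition_a) for r in reports],
            "condition_b": [_cond_txt(r.condition_b) for r in reports],
            "n_classes": [r.n_classes for r in reports],
            "slope": [r.slope for r in reports],
            "intercept": [r.intercept for r in reports],
            "adjusted_r2": [r.adjusted_r2 for r in reports],
            "t_value": [r.t_value for r in reports],
            "p_value": [r.p_value for r in reports],
            "significance": [r.significance for r in reports],
            "assumptions_ok": [r.assumptions_ok for r in reports],
            "caveat": ["" if r.assumptions_ok else "•" for r in reports],
            "normality_p": [r.normality_p for r in reports],
            "homoscedasticity_p": [r.homoscedasticity_p for r in reports],
        }
    )
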