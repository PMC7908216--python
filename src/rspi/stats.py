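"""Cohort-level evaluation: 2x2 diagnostics, ROC, logistic regression, tests.

The diagnostic question throughout is whether a high RSPI (score at or above
the cutoff) predicts volumetric response to resynchronization therapy.  The
module provides the 2x2 table statistics with a Wald CI on the log odds
ratio, an empirical ROC over the integer score range with a Youden-optimal
cutoff, univariate logistic regression (whose odds ratio for a binary
predictor must coincide with the 2x2 cross-product ratio), and thin wrappers
for the nonparametric and categorical tests used on such cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .model import InputError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TwoByTwo:
    """Counts with test = high score, condition = responder."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("2x2 counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_cohort(cls, scores: Sequence[float], labels: Sequence[bool],
                    cutoff: float) -> "TwoByTwo":
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=bool)
        if s.shape != y.shape:
            raise InputError("scores and labels must align")
        pos = s >= cutoff
        return cls(tp=int(np.sum(pos & y)), fp=int(np.sum(pos & ~y)),
                   fn=int(np.sum(~pos & y)), tn=int(np.sum(~pos & ~y)))


@dataclass(frozen=True)
class DiagnosticSummary:
    """2x2-derived diagnostics; undefined entries are ``None``."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    odds_ratio: Optional[float]          # may be math.inf
    or_ci: Optional[tuple[float, float]]
    auc: Optional[float] = None
    optimal_cutoff: Optional[int] = None


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def diagnostics(table: TwoByTwo, haldane: bool = False) -> DiagnosticSummary:
    """Sensitivity/specificity/predictive values and Wald-CI odds ratio.

    With a zero cell the odds ratio is 0 or infinite and its CI undefined,
    unless ``haldane`` adds the 0.5 continuity correction to every cell.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    a, b, c, d = (x + 0.5 for x in (tp, fp, fn, tn)) if haldane \
        else (float(tp), float(fp), float(fn), float(tn))

    if haldane or min(tp, fp, fn, tn) > 0:
        or_ = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci = (or_ * math.exp(-Z_95 * se), or_ * math.exp(Z_95 * se))
    elif fp * fn == 0 and tp * tn > 0:
        or_, ci = math.inf, None
    elif tp * tn == 0 and fp * fn > 0:
        or_, ci = 0.0, None
    else:
        or_, ci = None, None

    return DiagnosticSummary(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        odds_ratio=or_,
        or_ci=ci,
    )


@dataclass(frozen=True)
class RocResult:
    auc: float
    optimal_cutoff: int
    points: tuple[tuple[int, float, float], ...]  # (threshold, fpr, tpr)


def roc(scores: Sequence[float], labels: Sequence[bool],
        thresholds: Sequence[int] = range(0, 14)) -> RocResult:
    """Empirical ROC over integer cutoffs (positive when score >= cutoff).

    The AUC is the trapezoid area of the empirical curve, identical to the
    probability that a random responder outscores a random non-responder
    (ties counting one half).  The optimal cutoff maximizes Youden's
    J = sensitivity + specificity - 1; ties resolve to the larger cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise InputError("ROC needs both responders and non-responders")

    points = []
    best_j, best_cut = -math.inf, None
    for cut in thresholds:
        pos = s >= cut
        tpr = float(np.sum(pos & y)) / n1
        fpr = float(np.sum(pos & ~y)) / n0
        points.append((int(cut), fpr, tpr))
        j = tpr - fpr
        if j >= best_j - 1e-12:  # ties -> larger cutoff (thresholds ascend)
            if j > best_j + 1e-12 or best_cut is None or cut > best_cut:
                best_j, best_cut = max(best_j, j), int(cut)

    order = sorted(points, key=lambda p: (p[1], p[2]))
    fprs = [0.0] + [p[1] for p in order] + [1.0]
    tprs = [0.0] + [p[2] for p in order] + [1.0]
    auc = float(np.trapezoid(tprs, fprs))
    return RocResult(auc=auc, optimal_cutoff=best_cut, points=tuple(points))


@dataclass(frozen=True)
class LogisticFit:
    beta: Optional[float]
    se: Optional[float]
    odds_ratio: Optional[float]
    or_ci: Optional[tuple[float, float]]
    p_wald: Optional[float]
    estimable: bool
    note: str = ""


def logistic_univariate(x: Sequence[float], y: Sequence[bool]) -> LogisticFit:
    """Maximum-likelihood fit of ``logit P(y=1) = alpha + beta * x``.

    Separated or degenerate data (a constant predictor, or for a binary
    predictor an empty 2x2 cell) are flagged rather than estimated.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise InputError("x and y must align")
    if len(np.unique(yv)) < 2:
        raise InputError("outcome must contain both classes")
    if len(np.unique(xv)) < 2:
        return LogisticFit(None, None, None, None, None, False,
                           note="constant predictor")
    levels = np.unique(xv)
    if len(levels) == 2:
        cells = [np.sum((xv == a) & (yv == b))
                 for a in levels for b in (0.0, 1.0)]
        if min(cells) == 0:
            return LogisticFit(None, None, None, None, None, False,
                               note="empty cell (separation)")

    X = sm.add_constant(xv)
    try:
        fit = sm.Logit(yv, X).fit(disp=0, method="newton",
                                  maxiter=200, tol=1e-10)
    except Exception as exc:  # perfect separation raises inside statsmodels
        return LogisticFit(None, None, None, None, None, False, note=str(exc))
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e4:
        return LogisticFit(None, None, None, None, None, False,
                           note="quasi-separation (diverging SE)")
    or_ = math.exp(beta)
    ci = (math.exp(beta - Z_95 * se), math.exp(beta + Z_95 * se))
    p = 2 * sps.norm.sf(abs(beta / se))
    return LogisticFit(beta=beta, se=se, odds_ratio=or_, or_ci=ci,
                       p_wald=float(p), estimable=True)


# ---------------------------------------------------------------------------
# Nonparametric / categorical group tests

def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null when both groups are small."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise InputError("empty group")
    small = min(a.size, b.size) <= 10
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if small and not ties else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(before: Sequence[float],
                    after: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank on paired data; identical pairs give p = 1."""
    x = np.asarray(before, float)
    y = np.asarray(after, float)
    if x.size == 0 or x.shape != y.shape:
        raise InputError("paired samples must align and be non-empty")
    diff = y - x
    if np.all(diff == 0):
        return 0.0, 1.0
    n_nonzero = int(np.sum(diff != 0))
    method = "exact" if (n_nonzero <= 10
                         and len(np.unique(np.abs(diff[diff != 0])))
                         == n_nonzero) else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True,
                       method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square on an unpaired contingency table."""
    tab = np.asarray(table, dtype=float)
    if tab.sum() == 0:
        raise InputError("empty contingency table")
    stat, p, _, _ = sps.chi2_contingency(tab)
    return float(stat), float(p)


def mcnemar_paired(b: int, c: int, exact: Optional[bool] = None) -> tuple[float, float]:
    """McNemar test from the discordant-pair counts of a paired 2x2.

    ``b``/``c`` count the two kinds of discordant pairs (e.g. pattern lost
    vs gained after therapy).  Exact binomial by default when the discordant
    total is below 25.  Zero discordant pairs give p = 1.
    """
    if b < 0 or c < 0:
        raise InputError("discordant counts must be non-negative")
    if b + c == 0:
        return 0.0, 1.0
    use_exact = (b + c < 25) if exact is None else exact
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=use_exact, correction=True)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p."""
    res = sps.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def group_tests(cohort: pd.DataFrame,
                continuous: Sequence[str] = (),
                categorical: Sequence[str] = (),
                paired: Sequence[tuple[str, str]] = (),
                outcome: str = "responder") -> dict:
    """Standard between-group and pre/post comparisons on a patient table.

    ``continuous`` columns are compared responder vs non-responder by
    Mann-Whitney U; ``categorical`` (0/1) columns by chi-square; ``paired``
    (baseline, follow-up) column pairs by Wilcoxon signed-rank for numeric
    data or McNemar for binary data; Spearman rho between each continuous
    column and percent LVESV reduction is reported when available.
    """
    if outcome not in cohort.columns:
        raise InputError(f"cohort lacks outcome column {outcome!r}")
    y = cohort[outcome].astype(bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise InputError("both outcome groups must be non-empty")
    report: dict = {"n_responders": int(y.sum()),
                    "n_nonresponders": int((~y).sum())}

    for col in continuous:
        u, p = mann_whitney(cohort.loc[y, col], cohort.loc[~y, col])
        entry = {"test": "mann-whitney", "U": u, "p": p}
        if "delta_lvesv_pct" in cohort.columns:
            rho, p_rho = spearman(cohort[col], cohort["delta_lvesv_pct"])
            entry.update(rho_vs_delta_lvesv=rho, rho_p=p_rho)
        report[col] = entry

    for col in categorical:
        tab = pd.crosstab(cohort[col].astype(int), y).reindex(
            index=[0, 1], columns=[False, True], fill_value=0)
        stat, p = chi_square(tab.to_numpy())
        report[col] = {"test": "chi-square", "statistic": stat, "p": p}

    for base_col, fu_col in paired:
        base, fu = cohort[base_col], cohort[fu_col]
        if set(pd.unique(pd.concat([base, fu]))) <= {0, 1, True, False}:
            b = int(((base.astype(int) == 1) & (fu.astype(int) == 0)).sum())
            c = int(((base.astype(int) == 0) & (fu.astype(int) == 1)).sum())
            stat, p = mcnemar_paired(b, c)
            report[f"{base_col}->{fu_col}"] = {
                "test": "mcnemar", "discordant": b + c, "statistic": stat,
                "p": p}
        else:
            stat, p = wilcoxon_paired(base, fu)
            report[f"{base_col}->{fu_col}"] = {
                "test": "wilcoxon", "statistic": stat, "p": p}
    return report
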