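"""Diagnostic-accuracy statistics for screening-test evaluation.

ROC/AUC with the DeLong nonparametric variance and paired AUC comparison,
the Youden-optimal operating point, exact McNemar and Fisher tests,
Pearson chi-square, Clopper-Pearson exact binomial intervals, and
Bonferroni / Benjamini-Hochberg multiplicity adjustment.

Score orientation convention: a higher screening score means a more normal
response. ROC analysis treats the pathologic class as positive, so scores
are negated internally; the orientation is stored explicitly on results so
an AUC can never silently flip.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


class ComparisonMethod(str, enum.Enum):
    DELONG = "delong"
    MCNEMAR_EXACT = "mcnemar_exact"
    FISHER_EXACT = "fisher_exact"


class AdjustMethod(str, enum.Enum):
    BONFERRONI = "bonferroni"
    BH = "bh"


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    ci: tuple[float, float]
    higher_is_normal: bool = True
    # DeLong structural components, kept for paired comparison
    _v_pathologic: np.ndarray = field(default=None, repr=False)
    _v_normal: np.ndarray = field(default=None, repr=False)


@dataclass
class PairedComparison:
    delta: float
    statistic: float
    p: float
    method: ComparisonMethod
    n: int


@dataclass
class MultiplicityResult:
    raw: list[float]
    method: AdjustMethod
    adjusted: list[float]
    significant: list[bool]
    q: float


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, pathologic: np.ndarray):
    """DeLong structural components on the pathologic-positive orientation.

    Returns (auc, V10 over pathologic subjects, V01 over normal subjects)
    where AUC = P(score_path "ranks as more pathologic" than score_normal),
    ties counted one half.
    """
    x = scores[pathologic]   # already oriented: larger = more pathologic
    y = scores[~pathologic]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    combined = np.concatenate([x, y])
    r_all = _midrank(combined)
    r_x = _midrank(x)
    r_y = _midrank(y)
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    auc = v10.mean()
    return float(auc), v10, v01


def roc_auc(scores, labels, higher_is_normal: bool = True,
            level: float = 0.95) -> ROCResult:
    """Empirical ROC and AUC with DeLong standard error.

    Parameters
    ----------
    scores
        Screening scores, one per subject.
    labels
        Boolean, True = pathologic (the positive class for sensitivity).
    higher_is_normal
        If True (default), larger scores mean a more normal response and a
        subject is called pathologic when the score falls at or below the
        threshold (ties classified pathologic — the fail-safe direction).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have identical shape")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    oriented = -scores if higher_is_normal else scores
    auc, v10, v01 = _delong_components(oriented, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2)
    ci = (float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1)))

    thresholds = np.unique(scores)
    path_scores = scores[labels]
    norm_scores = scores[~labels]
    if higher_is_normal:
        sens = np.array([(path_scores <= t).mean() for t in thresholds])
        spec = np.array([(norm_scores > t).mean() for t in thresholds])
    else:
        sens = np.array([(path_scores >= t).mean() for t in thresholds])
        spec = np.array([(norm_scores < t).mean() for t in thresholds])
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=auc, auc_se=se, ci=ci,
                     higher_is_normal=higher_is_normal,
                     _v_pathologic=v10, _v_normal=v01)


def delong_compare(scores_a, scores_b, labels,
                   higher_is_normal: bool = True) -> PairedComparison:
    """Paired DeLong comparison of two AUCs measured on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not scores_a.shape == scores_b.shape == labels.shape:
        raise ValueError("paired inputs must have identical shape")
    sign = -1.0 if higher_is_normal else 1.0
    auc_a, v10_a, v01_a = _delong_components(sign * scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(sign * scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    delta = auc_a - auc_b
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return PairedComparison(delta=float(delta), statistic=float(z), p=p,
                            method=ComparisonMethod.DELONG, n=len(labels))


def optimal_point(roc: ROCResult) -> tuple[float, float, float]:
    """Threshold maximising the Youden index J = sens + spec - 1.

    Ties are broken toward higher sensitivity (missing a pathologic case is
    the costlier error in screening), then toward higher specificity.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    order = np.lexsort((roc.specificity, roc.sensitivity, j))
    best = order[-1]
    return (float(roc.thresholds[best]), float(roc.sensitivity[best]),
            float(roc.specificity[best]))


# ---------------------------------------------------------------------------
# Exact tests and intervals


def mcnemar_exact(b: int, c: int) -> PairedComparison:
    """Two-sided exact McNemar test from the discordant-pair counts.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    with no discordant pairs p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        p = 1.0
    else:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
    return PairedComparison(delta=float(b - c), statistic=float(min(b, c)),
                            p=p, method=ComparisonMethod.MCNEMAR_EXACT, n=n)


def fisher_exact(table: ContingencyTable | np.ndarray) -> PairedComparison:
    """Two-sided Fisher exact test on a 2x2 table (probability-mass rule)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact needs a 2x2 table")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        warnings.warn("degenerate margins: Fisher test is uninformative")
        return PairedComparison(delta=0.0, statistic=np.nan, p=1.0,
                                method=ComparisonMethod.FISHER_EXACT,
                                n=int(counts.sum()))
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    return PairedComparison(delta=float(counts[0, 0] / max(counts[0].sum(), 1)
                                        - counts[1, 0] / max(counts[1].sum(), 1)),
                            statistic=float(odds), p=float(p),
                            method=ComparisonMethod.FISHER_EXACT,
                            n=int(counts.sum()))


def pearson_chi2(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c table."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.sum() == 0:
        raise ValueError("empty table")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def proportion_ci(successes: int, n: int,
                  level: float = 0.95) -> tuple[float, float, float]:
    """Clopper-Pearson exact two-sided interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    low, high = proportion_confint(successes, n, alpha=1 - level, method="beta")
    return successes / n, float(low), float(high)


def adjust_pvalues(pvals, method: AdjustMethod | str = AdjustMethod.BH,
                   q: float = 0.05) -> MultiplicityResult:
    """Bonferroni or Benjamini-Hochberg adjustment with decisions at q."""
    pvals = list(pvals)
    if not pvals:
        raise ValueError("empty p-value list")
    if any(not 0 <= p <= 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    method = AdjustMethod(method)
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method.value]
    reject, adjusted, *_ = multipletests(pvals, alpha=q, method=sm_method)
    return MultiplicityResult(raw=pvals, method=method,
                              adjusted=[float(p) for p in adjusted],
                              significant=[bool(r) for r in reject], q=q)


# ---------------------------------------------------------------------------
# Whole-table screening evaluation


def evaluate_screening(frame: pd.DataFrame, score_columns: list[str],
                       group_column: str = "group",
                       control_group: str = "control",
                       pathologic_groups: tuple[str, ...] = ("amblyopia",
                                                             "amblyogenic"),
                       q: float = 0.05) -> dict[str, pd.DataFrame]:
    """Per-test, per-group diagnostic accuracy report.

    For each score column and each study group versus the control group:
    AUC with DeLong CI, the Youden-optimal threshold, and sensitivity /
    specificity with Clopper-Pearson intervals. Also returns the pairwise
    DeLong matrix and exact-McNemar matrix over score columns (on the joint
    pathologic group) with BH-adjusted conclusions.
    """
    groups = [g for g in frame[group_column].unique() if g != control_group]
    joint = list(pathologic_groups)
    auc_rows, point_rows = [], []
    for col in score_columns:
        for grp_name, members in [*((g, [g]) for g in groups),
                                  ("+".join(joint), joint)]:
            sub = frame[frame[group_column].isin(members + [control_group])]
            y = sub[group_column].isin(members).to_numpy()
            if not y.any() or y.all():
                auc_rows.append({"test": col, "group": grp_name,
                                 "auc": np.nan, "note": "group missing"})
                continue
            roc = roc_auc(sub[col].to_numpy(), y)
            thr, sens, spec = optimal_point(roc)
            npos, nneg = int(y.sum()), int((~y).sum())
            _, s_lo, s_hi = proportion_ci(round(sens * npos), npos)
            _, p_lo, p_hi = proportion_ci(round(spec * nneg), nneg)
            auc_rows.append({"test": col, "group": grp_name,
                             "auc": round(roc.auc, 3),
                             "ci_low": round(roc.ci[0], 3),
                             "ci_high": round(roc.ci[1], 3),
                             "n": len(sub), "note": ""})
            point_rows.append({"test": col, "group": grp_name,
                               "threshold": thr,
                               "sensitivity": round(sens, 2),
                               "sens_ci_low": round(s_lo, 2),
                               "sens_ci_high": round(s_hi, 2),
                               "specificity": round(spec, 2),
                               "spec_ci_low": round(p_lo, 2),
                               "spec_ci_high": round(p_hi, 2)})

    sub = frame[frame[group_column].isin(joint + [control_group])]
    y = sub[group_column].isin(joint).to_numpy()
    k = len(score_columns)
    delong = np.ones((k, k))
    mcnemar_p = np.ones((k, k))
    decisions = {}
    for col in score_columns:
        roc = roc_auc(sub[col].to_numpy(), y)
        thr, _, _ = optimal_point(roc)
        decisions[col] = (sub[col].to_numpy() <= thr)  # called pathologic
    raw_pairs = []
    for i, a in enumerate(score_columns):
        for j, b in enumerate(score_columns):
            if j <= i:
                continue
            cmp_ = delong_compare(sub[a].to_numpy(), sub[b].to_numpy(), y)
            delong[i, j] = delong[j, i] = cmp_.p
            bb = int((decisions[a] & ~decisions[b] & y).sum())
            cc = int((~decisions[a] & decisions[b] & y).sum())
            mc = mcnemar_exact(bb, cc)
            mcnemar_p[i, j] = mcnemar_p[j, i] = mc.p
            raw_pairs.append(((a, b), cmp_.p))
    adj = adjust_pvalues([p for _, p in raw_pairs], AdjustMethod.BH, q=q) \
        if raw_pairs else None
    out = {
        "auc": pd.DataFrame(auc_rows),
        "optimal_points": pd.DataFrame(point_rows),
        "delong_pairwise": pd.DataFrame(delong, index=score_columns,
                                        columns=score_columns),
        "mcnemar_pairwise": pd.DataFrame(mcnemar_p, index=score_columns,
                                         columns=score_columns),
    }
    if adj is not None:
        out["delong_adjusted"] = pd.DataFrame({
            "pair": ["/".join(p) for p, _ in raw_pairs],
            "raw_p": adj.raw, "adjusted_p": adj.adjusted,
            "significant": adj.significant})
    return out
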