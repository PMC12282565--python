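"""Diagnostic-accuracy and group-comparison statistics.

Everything the evaluation pipeline reports is computed here: 2x2 confusion
tables with sensitivity/specificity/PPV/NPV and binomial CIs, tie-aware
Mann-Whitney ROC/AUROC with stratified-bootstrap comparison, odds ratios,
Pearson correlations, chi-square/Fisher/t/ANOVA group tests, logistic
regression by iteratively reweighted least squares, and the two-proportion
z-test power formula.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DiagnosticsError",
    "DegenerateDataError",
    "CIMethod",
    "BinaryConfusion",
    "ProportionCI",
    "DiagnosticPanel",
    "ROCCurve",
    "OddsRatioResult",
    "CorrelationResult",
    "GroupTest",
    "GroupTestResult",
    "LogisticFit",
    "AUCComparison",
    "confusion_from_threshold",
    "proportion_ci",
    "diagnostic_metrics",
    "auroc_mann_whitney",
    "auroc_bootstrap_compare",
    "odds_ratio",
    "pearson_correlation",
    "group_comparison",
    "logistic_irls",
    "two_proportion_power",
]


class DiagnosticsError(ValueError):
    """Invalid input to a diagnostics operation."""


class DegenerateDataError(DiagnosticsError):
    """Data admit no defined answer (single-class outcome, empty margin, ...)."""


class CIMethod(str, enum.Enum):
    CLOPPER_PEARSON = "clopper_pearson"
    WILSON = "wilson"


@dataclass(frozen=True)
class BinaryConfusion:
    """Counts of a binary test against a binary condition."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DiagnosticsError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def condition_positives(self) -> int:
        return self.tp + self.fn

    @property
    def condition_negatives(self) -> int:
        return self.fp + self.tn

    def as_table(self) -> np.ndarray:
        """2x2 array [[tp, fp], [fn, tn]]."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    lo: float
    hi: float
    method: CIMethod
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.lo - 1e-12 <= self.estimate <= self.hi + 1e-12):
            raise DiagnosticsError("CI must bracket the point estimate")


@dataclass(frozen=True)
class DiagnosticPanel:
    """Sensitivity/specificity/PPV/NPV panel for one thresholded test.

    A metric with a zero denominator is ``None`` (undefined), never silently 0.
    ``auc_binary`` is the AUROC of the *dichotomized* test,
    (sensitivity + specificity) / 2.
    """

    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]

    @property
    def auc_binary(self) -> Optional[float]:
        if self.sensitivity is None or self.specificity is None:
            return None
        return (self.sensitivity.estimate + self.specificity.estimate) / 2.0


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray  # descending score cut points
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise DiagnosticsError(f"auc {self.auc} outside [0, 1]")


@dataclass(frozen=True)
class OddsRatioResult:
    or_estimate: float
    lo: float
    hi: float
    level: float = 0.95
    continuity_corrected: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_two_sided: float


@dataclass(frozen=True)
class AUCComparison:
    """Paired bootstrap comparison of two scores on the same patients."""

    auc_a: float
    auc_b: float
    delta: float  # auc_a - auc_b
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    delta_ci: tuple[float, float]
    n_boot: int
    seed: int


class GroupTest(str, enum.Enum):
    CHI_SQUARE = "chi_square"
    FISHER_EXACT = "fisher_exact"
    WELCH_T = "welch_t"
    ONE_WAY_ANOVA = "one_way_anova"


@dataclass(frozen=True)
class GroupTestResult:
    test_used: GroupTest
    statistic: float
    p_value: float
    fell_back_to_fisher: bool = False


@dataclass(frozen=True)
class LogisticFit:
    coef: np.ndarray  # includes intercept at index 0
    se: np.ndarray
    converged: bool
    iterations: int
    log_likelihood: float
    names: tuple[str, ...] = ()
    level: float = 0.95

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def or_ci(self) -> np.ndarray:
        """(k, 2) array of Wald odds-ratio confidence bounds."""
        z = stats.norm.ppf(0.5 + self.level / 2.0)
        with np.errstate(over="ignore"):  # huge SEs -> inf bound, not an error
            return np.exp(
                np.column_stack([self.coef - z * self.se, self.coef + z * self.se])
            )


# ---------------------------------------------------------------------------
# confusion tables and threshold metrics


def confusion_from_threshold(
    scores: Sequence[float],
    outcome: Sequence[bool],
    cutoff: float,
    *,
    strict: bool = False,
) -> BinaryConfusion:
    """Dichotomize ``scores`` at ``cutoff`` and cross-tabulate against ``outcome``.

    Test-positive means ``score >= cutoff`` (or ``> cutoff`` when
    ``strict=True``, for rules stated as strict inequalities such as
    systolic SI > 0.80).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if s.ndim != 1 or s.shape != y.shape:
        raise DiagnosticsError("scores and outcome must be equal-length 1-d vectors")
    if s.size == 0:
        raise DiagnosticsError("empty input")
    if np.isnan(s).any():
        raise DiagnosticsError("scores contain missing values")
    pred = s > cutoff if strict else s >= cutoff
    return BinaryConfusion(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
        tn=int(np.sum(~pred & ~y)),
    )


def proportion_ci(
    k: int,
    n: int,
    method: CIMethod | str = CIMethod.CLOPPER_PEARSON,
    level: float = 0.95,
) -> ProportionCI:
    """Binomial proportion with a Clopper-Pearson (exact) or Wilson CI."""
    method = CIMethod(method)
    if n <= 0 or not (0 <= k <= n):
        raise DiagnosticsError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    p = k / n
    alpha = 1.0 - level
    if method is CIMethod.CLOPPER_PEARSON:
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    else:
        z = float(stats.norm.ppf(1 - alpha / 2))
        denom = 1 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = max(0.0, center - half), min(1.0, center + half)
    return ProportionCI(p, lo, hi, method, level)


def diagnostic_metrics(
    confusion: BinaryConfusion,
    ci_method: CIMethod | str = CIMethod.CLOPPER_PEARSON,
    level: float = 0.95,
) -> DiagnosticPanel:
    """Sensitivity, specificity, PPV and NPV with binomial CIs.

    Requires at least one condition-positive and one condition-negative;
    predictive values with a zero denominator come back as ``None``.
    """
    if confusion.condition_positives == 0 or confusion.condition_negatives == 0:
        raise DegenerateDataError(
            "need at least one condition-positive and one condition-negative"
        )

    def _ci(k: int, n: int) -> Optional[ProportionCI]:
        return None if n == 0 else proportion_ci(k, n, ci_method, level)

    return DiagnosticPanel(
        sensitivity=_ci(confusion.tp, confusion.tp + confusion.fn),
        specificity=_ci(confusion.tn, confusion.tn + confusion.fp),
        ppv=_ci(confusion.tp, confusion.tp + confusion.fp),
        npv=_ci(confusion.tn, confusion.tn + confusion.fn),
    )


# ---------------------------------------------------------------------------
# ROC / AUROC


def _auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    # Mann-Whitney estimator via midranks; exactly handles ties:
    # AUC = [#(pos > neg) + 0.5 * #(pos == neg)] / (n_pos * n_neg)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = stats.rankdata(scores)  # midranks
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc_mann_whitney(
    scores: Sequence[float], outcome: Sequence[bool]
) -> ROCCurve:
    """Tie-aware ROC curve and AUROC for an ordinal score.

    The area equals the Mann-Whitney probability that a random case outscores
    a random control, counting ties as 1/2.  Operating points are generated by
    sweeping thresholds through the distinct score values in descending order
    (test-positive means score >= threshold), with (0,0) and (1,1) endpoints.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if s.ndim != 1 or s.shape != y.shape or s.size == 0:
        raise DiagnosticsError("scores and outcome must be equal-length 1-d vectors")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("outcome has a single class; AUROC undefined")

    uniq = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in uniq:
        pred = s >= t
        tpr.append(float(np.sum(pred & y)) / n_pos)
        fpr.append(float(np.sum(pred & ~y)) / n_neg)
    # final point is (1,1) by construction (lowest threshold includes all)
    thresholds = np.concatenate([[np.inf], uniq])
    return ROCCurve(
        thresholds=thresholds,
        fpr=np.array(fpr),
        tpr=np.array(tpr),
        auc=_auc_rank(s, y),
    )


def auroc_bootstrap_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcome: Sequence[bool],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> AUCComparison:
    """Compare two scores on the same patients by stratified bootstrap.

    Cases and controls are resampled separately (preserving both class sizes);
    each replicate recomputes both AUROCs on the same resampled patients so
    the difference accounts for their pairing.  Percentile intervals.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if not (a.shape == b.shape == y.shape) or a.ndim != 1:
        raise DiagnosticsError("score vectors and outcome must be aligned 1-d vectors")
    if n_boot < 1:
        raise DiagnosticsError("n_boot must be >= 1")
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise DegenerateDataError("outcome has a single class; AUROC undefined")

    auc_a = _auc_rank(a, y)
    auc_b = _auc_rank(b, y)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 2))
    for i in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
        )
        yy = y[idx]
        boot[i, 0] = _auc_rank(a[idx], yy)
        boot[i, 1] = _auc_rank(b[idx], yy)
    alpha = 1.0 - level
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    ci_a = tuple(np.percentile(boot[:, 0], qs))
    ci_b = tuple(np.percentile(boot[:, 1], qs))
    delta_ci = tuple(np.percentile(boot[:, 0] - boot[:, 1], qs))
    return AUCComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        delta=auc_a - auc_b,
        ci_a=ci_a,
        ci_b=ci_b,
        delta_ci=delta_ci,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# association measures


def odds_ratio(confusion: BinaryConfusion, level: float = 0.95) -> OddsRatioResult:
    """Odds ratio with a Woolf log-scale CI.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction (flagged in
    the result); a zero row or column margin leaves the OR undefined.
    """
    a, b, c, d = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise DegenerateDataError("odds ratio undefined: empty table margin")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_est = (a * d) / (b * c)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        or_estimate=or_est,
        lo=math.exp(math.log(or_est) - z * se_log),
        hi=math.exp(math.log(or_est) + z * se_log),
        level=level,
        continuity_corrected=corrected,
    )


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    Pairs with a missing value on either side are dropped (pairwise deletion);
    at least 3 complete pairs are required and both vectors must vary.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DiagnosticsError("x and y must be equal-length 1-d vectors")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 3:
        raise DegenerateDataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("correlation undefined: zero variance")
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(r), n=n, p_two_sided=float(p))


def group_comparison(
    data,
    test: GroupTest | str,
    *,
    auto_fisher: bool = True,
) -> GroupTestResult:
    """Compare groups with a chi-square, Fisher exact, Welch t or one-way ANOVA.

    ``data`` is a contingency table (2-d array) for the count tests, or a
    sequence of numeric sample vectors for the mean tests.  A 2x2 chi-square
    request falls back to Fisher's exact test when any expected cell count is
    below 5 (flagged in the result); larger tables keep the chi-square.
    """
    test = GroupTest(test)
    if test in (GroupTest.CHI_SQUARE, GroupTest.FISHER_EXACT):
        table = np.asarray(data, dtype=float)
        if table.ndim != 2 or table.min() < 0:
            raise DiagnosticsError("contingency table must be a non-negative 2-d array")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise DegenerateDataError("contingency table has an empty row or column")
        if test is GroupTest.FISHER_EXACT:
            if table.shape != (2, 2):
                raise DiagnosticsError("Fisher exact test requires a 2x2 table")
            orr, p = stats.fisher_exact(table)
            return GroupTestResult(GroupTest.FISHER_EXACT, float(orr), float(p))
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if auto_fisher and table.shape == (2, 2) and (expected < 5).any():
            orr, p = stats.fisher_exact(table)
            return GroupTestResult(
                GroupTest.FISHER_EXACT, float(orr), float(p), fell_back_to_fisher=True
            )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupTestResult(GroupTest.CHI_SQUARE, float(chi2), float(p))

    samples = [np.asarray(g, dtype=float) for g in data]
    samples = [g[~np.isnan(g)] for g in samples]
    if any(g.size < 2 for g in samples):
        raise DiagnosticsError("each group needs >= 2 numeric observations")
    if test is GroupTest.WELCH_T:
        if len(samples) != 2:
            raise DiagnosticsError("Welch t-test requires exactly 2 groups")
        t, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        return GroupTestResult(GroupTest.WELCH_T, float(t), float(p))
    if len(samples) < 2:
        raise DiagnosticsError("ANOVA requires >= 2 groups")
    f, p = stats.f_oneway(*samples)
    return GroupTestResult(GroupTest.ONE_WAY_ANOVA, float(f), float(p))


# ---------------------------------------------------------------------------
# logistic regression (IRLS)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: sum y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_irls(
    design,
    outcome,
    *,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares.

    ``design`` is an (n, p) matrix of predictors; an intercept column is
    prepended automatically.  Wald standard errors come from the inverse
    Fisher information at the solution.  Perfect separation (coefficients
    diverging) and rank-deficient designs raise explicit errors.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(outcome).size == X.shape[1]:
        X = X.T
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise DiagnosticsError("design rows must match outcome length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DiagnosticsError("outcome must be binary 0/1")
    Xd = np.column_stack([np.ones(y.size), X])
    n, p = Xd.shape
    if n <= p:
        raise DiagnosticsError(f"need more observations ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(Xd) < p:
        raise DiagnosticsError("design matrix is rank deficient")
    if y.min() == y.max():
        raise DegenerateDataError("outcome has a single class")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.clip(w, 1e-10, None)
        z = eta + (y - mu) / w
        WX = Xd * w[:, None]
        try:
            beta_new = np.linalg.solve(Xd.T @ WX, Xd.T @ (w * z))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise DiagnosticsError("IRLS normal equations are singular") from exc
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        # diverging fit: fitted log-odds walking off to +/- inf while the
        # classes are perfectly ordered by the linear predictor
        eta_new = Xd @ beta
        if np.max(np.abs(beta)) > 1e3 or (
            np.max(np.abs(eta_new)) > 30.0
            and (eta_new[y == 1].min() if (y == 1).any() else np.inf)
            > (eta_new[y == 0].max() if (y == 0).any() else -np.inf)
        ):
            raise DegenerateDataError(
                "coefficients diverging: data are (quasi-)perfectly separated"
            )
        if step < tol:
            converged = True
            break

    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]))
    name_tuple = ("intercept",) + tuple(
        names if names is not None else (f"x{j}" for j in range(1, p))
    )
    if len(name_tuple) != p:
        raise DiagnosticsError("names length must match number of predictors")
    return LogisticFit(
        coef=beta,
        se=np.sqrt(np.diag(cov)),
        converged=converged,
        iterations=it,
        log_likelihood=_log_likelihood(eta, y),
        names=name_tuple,
    )


# ---------------------------------------------------------------------------
# power


def two_proportion_power(
    p1: float, p2: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Power of the two-sided two-proportion z-test.

    Normal approximation with the pooled SE under the null and the unpooled
    SE under the alternative; both rejection tails are counted.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise DiagnosticsError("proportions must lie in [0, 1]")
    if n1 < 2 or n2 < 2:
        raise DiagnosticsError("need n1, n2 >= 2")
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se1 == 0:
        return 1.0 if p1 != p2 else alpha
    z = float(stats.norm.ppf(1 - alpha / 2))
    d = p1 - p2
    upper = stats.norm.cdf((d - z * se0) / se1)
    lower = stats.norm.cdf((-d - z * se0) / se1)
    return float(upper + lower)
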