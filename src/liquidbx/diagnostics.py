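"""Cutoff-based biomarker diagnostics.

Evaluates a continuous marker (plasma cfDNA level in ng/uL, serum CA19-9 in
U/mL, CEA in ng/mL, ...) for discriminating a case group from a control
group under the convention that higher values indicate disease:

* empirical ROC curve with trapezoidal AUC and a Hanley–McNeil 95% CI,
* Youden-index-optimal cutoff (J = sensitivity + specificity - 1) with its
  realized 2x2 table and positive likelihood ratio,
* crude odds ratios from 2x2 tables (Woolf log-normal CI, Haldane–Anscombe
  0.5 correction when a cell is empty),
* maximum-likelihood logistic regression (Newton/IRLS) for crude and
  covariate-adjusted odds ratios,
* rank-based group comparisons (Mann–Whitney U, Kruskal–Wallis, Dunn's
  post hoc with tie correction) and Spearman correlation,
* positive detection rates at clinical cutoffs.

Positivity at a cutoff c is value > c (strictly greater). Candidate cutoffs
are midpoints between consecutive distinct observed values plus sentinels
below the minimum and above the maximum, so every achievable empirical
operating point is visited. The empirical AUC equals the Mann–Whitney
U-statistic U/(n1*n0) with ties counted 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .concordance import ConfusionTable

_Z975 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class LabeledValues:
    """One biomarker's measurements with case/control labels.

    ``direction`` is fixed to "higher_is_case": larger values are treated
    as evidence for the case group.
    """

    values: np.ndarray
    labels: np.ndarray  # boolean, True = case
    direction: str = "higher_is_case"

    def __init__(self, values: Sequence[float], labels: Sequence, direction: str = "higher_is_case"):
        values = np.asarray(values, dtype=float)
        labels = np.asarray(
            [bool(l) if isinstance(l, (bool, np.bool_, int)) else l == "case" for l in labels]
        )
        if values.size == 0 or values.size != labels.size:
            raise ValueError("values and labels must be non-empty and parallel")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if direction != "higher_is_case":
            raise ValueError("only higher_is_case is supported")
        self.values = values
        self.labels = labels
        self.direction = direction

    @property
    def cases(self) -> np.ndarray:
        return self.values[self.labels]

    @property
    def controls(self) -> np.ndarray:
        return self.values[~self.labels]


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    sens_points: np.ndarray
    spec_points: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    n_case: int
    n_control: int
    degenerate: bool = False


@dataclass
class CutoffReport:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    positive_lr: Optional[float]
    table: ConfusionTable


@dataclass
class OrResult:
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    adjusted: bool = False
    covariates: list[str] = field(default_factory=list)
    haldane_corrected: bool = False
    degenerate: bool = False


@dataclass
class LogisticFit:
    names: list[str]  # intercept first
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray  # exp(coef), intercept included for uniformity
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iterations: int
    separation_detected: bool = False


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values, plus sentinels below
    the minimum and above the maximum; returned descending."""
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    lo = distinct[0] - 1.0
    hi = distinct[-1] + 1.0
    return np.concatenate(([hi], mids[::-1], [lo]))


def empirical_roc(data: LabeledValues) -> RocCurve:
    """Empirical ROC curve, trapezoidal AUC and Hanley–McNeil 95% CI."""
    cases, controls = data.cases, data.controls
    n1, n0 = cases.size, controls.size
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs at least one case and one control")

    thr = _candidate_thresholds(data.values)
    # positivity is value > threshold
    sens = np.array([(cases > t).mean() for t in thr])
    spec = np.array([(controls <= t).mean() for t in thr])

    # trapezoid over (FPR, TPR); thr descending => FPR ascending
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    degenerate = np.unique(data.values).size == 1
    if degenerate:
        auc = 0.5

    se = _hanley_mcneil_se(auc, n1, n0)
    lo = min(max(auc - _Z975 * se, 0.0), 1.0)
    hi = min(max(auc + _Z975 * se, 0.0), 1.0)
    return RocCurve(
        thresholds=thr,
        sens_points=sens,
        spec_points=spec,
        auc=auc,
        auc_ci_low=min(lo, auc),
        auc_ci_high=max(hi, auc),
        n_case=n1,
        n_control=n0,
        degenerate=degenerate,
    )


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc * auc)
        + (n0 - 1) * (q2 - auc * auc)
    ) / (n1 * n0)
    return math.sqrt(max(var, 0.0))


def auc_mann_whitney(cases: Sequence[float], controls: Sequence[float]) -> float:
    """AUC as the normalized Mann–Whitney U statistic (ties count 1/2)."""
    cases = np.asarray(cases, float)
    controls = np.asarray(controls, float)
    gt = (cases[:, None] > controls[None, :]).sum()
    eq = (cases[:, None] == controls[None, :]).sum()
    return float((gt + 0.5 * eq) / (cases.size * controls.size))


def youden_cutoff(curve: RocCurve, data: LabeledValues) -> CutoffReport:
    """Youden-optimal operating point.

    Maximizes J = sensitivity + specificity - 1 over the curve's candidate
    thresholds; ties in J are broken toward the lowest cutoff (which
    maximizes sensitivity at equal J). The realized 2x2 at the chosen
    cutoff is returned with cases on the reference-positive axis.
    """
    j = curve.sens_points + curve.spec_points - 1.0
    best_j = j.max()
    # thresholds are descending; the last argmax is the lowest cutoff
    idx = np.flatnonzero(np.isclose(j, best_j, atol=1e-12))[-1]
    cutoff = float(curve.thresholds[idx])

    cases, controls = data.cases, data.controls
    tp = int((cases > cutoff).sum())
    fn = cases.size - tp
    tn = int((controls <= cutoff).sum())
    fp = controls.size - tn
    table = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn,
                           orientation="reference=case,test=marker")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr = sens / (1.0 - spec) if spec < 1.0 else None
    return CutoffReport(
        cutoff=cutoff,
        youden_j=sens + spec - 1.0,
        sensitivity=sens,
        specificity=spec,
        positive_lr=lr,
        table=table,
    )


def reconstruct_two_by_two(
    sens: float, spec: float, n_case: int, n_control: int
) -> ConfusionTable:
    """Recover the integer 2x2 behind printed sensitivity/specificity.

    tp = round(sens * n_case) must land within 0.51 of an integer (likewise
    tn), otherwise the printed fractions are inconsistent with the sample
    sizes and a ValueError names the offending margin.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sens and spec must be fractions in [0,1]")
    tp_f, tn_f = sens * n_case, spec * n_control
    tp, tn = round(tp_f), round(tn_f)
    if abs(tp_f - tp) > 0.51:
        raise ValueError(f"sensitivity {sens} inconsistent with n_case {n_case}")
    if abs(tn_f - tn) > 0.51:
        raise ValueError(f"specificity {spec} inconsistent with n_control {n_control}")
    return ConfusionTable(
        tp=tp, fp=n_control - tn, fn=n_case - tp, tn=tn,
        orientation="reference=case,test=marker",
    )


def crude_odds_ratio(table: ConfusionTable) -> OrResult:
    """Cross-product odds ratio with Woolf 95% CI.

    OR = (tp*tn)/(fp*fn). When any cell is 0, the Haldane–Anscombe
    correction (+0.5 to every cell) is applied and flagged. If both cells
    of a diagonal are zero even after correction the OR is degenerate and
    reported missing.
    """
    if table.n == 0:
        raise ValueError("odds ratio needs n > 0")
    a, b, c, d = table.tp, table.fp, table.fn, table.tn
    corrected = False
    if min(a, b, c, d) == 0:
        if (a == 0 and d == 0) or (b == 0 and c == 0):
            return OrResult(None, None, None, None, degenerate=True)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return OrResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - _Z975 * se),
        ci_high=math.exp(log_or + _Z975 * se),
        p_value=float(p),
        haldane_corrected=corrected,
    )


def fit_logistic(
    outcome: Sequence[int],
    predictors: np.ndarray | Sequence[Sequence[float]],
    names: Optional[Sequence[str]] = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton / IRLS.

    ``predictors`` is an (n, p) matrix without the intercept column (an
    intercept is always prepended; pass an (n, 0) matrix for an
    intercept-only model). Convergence is declared when the maximum
    absolute score (gradient) falls below ``tol``. Complete separation is
    detected as diverging coefficients with a perfectly classifying linear
    score and is reported via ``separation_detected`` rather than silently
    returned as a converged fit.
    """
    y = np.asarray(outcome, dtype=float)
    X0 = np.asarray(predictors, dtype=float)
    if X0.ndim == 1:
        X0 = X0[:, None]
    n = y.size
    if n < 10:
        raise ValueError("logistic fit needs n >= 10")
    if X0.shape[0] != n:
        raise ValueError("outcome and predictors have different lengths")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be binary 0/1")
    for j in range(X0.shape[1]):
        if np.ptp(X0[:, j]) == 0:
            raise ValueError(f"predictor column {j} is constant")
    X = np.column_stack([np.ones(n), X0])
    p_dim = X.shape[1]
    if np.linalg.matrix_rank(X) < p_dim:
        raise ValueError("singular design matrix (collinear columns)")
    if names is None:
        names = [f"x{j}" for j in range(X0.shape[1])]
    all_names = ["intercept"] + list(names)

    beta = np.zeros(p_dim)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            # linear score running away: check for perfect classification
            pred = (X @ beta) > 0
            if np.all(pred == (y == 1)):
                separation = True
                break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    # complete separation saturates every fitted probability at the correct
    # label, which can zero the score before the coefficients visibly diverge
    if (
        X0.shape[1] > 0
        and np.all((mu > 0.5) == (y == 1))
        and np.all(np.minimum(mu, 1.0 - mu) < 1e-4)
    ):
        separation = True
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p_dim, np.nan)
    with np.errstate(over="ignore"):
        ors = np.exp(beta)
        lo = np.exp(beta - _Z975 * se)
        hi = np.exp(beta + _Z975 * se)
    zvals = np.divide(beta, se, out=np.full(p_dim, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    return LogisticFit(
        names=all_names,
        coefficients=beta,
        standard_errors=se,
        odds_ratios=ors,
        ci_low=lo,
        ci_high=hi,
        p_values=pvals,
        converged=converged and not separation,
        n_iterations=it,
        separation_detected=separation,
    )


def rank_tests(
    groups: Sequence[Sequence[float]], mode: str = "kruskal_wallis"
) -> tuple[float, float]:
    """Tie-corrected rank-based comparison of group locations.

    ``mode="mann_whitney"`` (exactly two groups): two-sided Mann–Whitney U;
    the exact null distribution is enumerated for small samples without
    ties (n1 + n2 <= 12), otherwise the tie-corrected normal approximation
    is used. ``mode="kruskal_wallis"``: H referred to chi-square with k-1
    degrees of freedom. Returns (statistic, p).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if mode == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        a, b = arrays
        small = a.size + b.size <= 12
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if mode == "kruskal_wallis":
        if len(arrays) < 2:
            raise ValueError("kruskal_wallis requires >= 2 groups")
        res = stats.kruskal(*arrays)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def dunn_posthoc(groups: Sequence[Sequence[float]]) -> list[dict]:
    """Dunn's post hoc pairwise z tests on pooled ranks, with tie correction.

    For groups i, j the statistic is
    z = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )
    with T = sum(t^3 - t) over tie groups. Both unadjusted and Bonferroni-
    adjusted two-sided p-values are reported (adjustment by the number of
    pairs). When the pooled variance is zero (all observations tied) z = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 3:
        raise ValueError("dunn_posthoc requires >= 3 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_core = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    means, sizes = [], []
    start = 0
    for a in arrays:
        means.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size

    n_pairs = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            denom = var_core * (1.0 / sizes[i] + 1.0 / sizes[j])
            z = (means[i] - means[j]) / math.sqrt(denom) if denom > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            out.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "z": z,
                    "p_unadjusted": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                }
            )
    return out


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[Optional[float], Optional[float]]:
    """Spearman rank correlation over complete pairs; (rho, p).

    Pairs with a missing member (NaN) are dropped; a constant vector yields
    (None, None). p is the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be parallel")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def detection_rates(
    marker_values: dict[str, Sequence[Optional[float]]],
    thresholds: dict[str, float],
    strict: bool = False,
) -> dict[str, Optional[float]]:
    """Positive detection rate per marker among evaluable subjects.

    ``marker_values[name]`` holds one value per subject, with None/NaN for
    subjects not measured; those are excluded from the denominator. A
    subject is positive when its value exceeds (``strict=True``: strictly;
    default: >=) the marker's threshold. Count-valued markers (e.g. number
    of retained ctDNA mutations, threshold 1) work identically. Markers
    with an empty evaluable set report None.
    """
    rates: dict[str, Optional[float]] = {}
    for name, vals in marker_values.items():
        if name not in thresholds:
            raise ValueError(f"no threshold supplied for marker {name!r}")
        arr = np.array(
            [np.nan if v is None else float(v) for v in vals], dtype=float
        )
        evaluable = np.isfinite(arr)
        n_eval = int(evaluable.sum())
        if n_eval == 0:
            rates[name] = None
            continue
        t = thresholds[name]
        pos = (arr[evaluable] > t) if strict else (arr[evaluable] >= t)
        rates[name] = float(pos.sum() / n_eval)
    return rates
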