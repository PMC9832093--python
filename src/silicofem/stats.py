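"""Cohort comparison and stratification statistics.

Machinery used to compare the synthetic cohort with its source: a
univariate two-component Gaussian-mixture fit by (non-Bayesian)
expectation-maximisation, an equal-error-rate ROC threshold, the
two-sample Kolmogorov–Smirnov test, and a battery of normality tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Gmm2Fit",
    "fit_gmm2_em",
    "gaussian_loglik",
    "bic",
    "roc_equal_error_threshold",
    "ks_two_sample",
    "NormalityResult",
    "normality_suite",
    "StratificationReport",
    "stratify",
]


# ---------------------------------------------------------------------------
# two-component Gaussian mixture via EM


@dataclass
class Gmm2Fit:
    """Parameters of a univariate 2-component Gaussian mixture.

    Components are sorted so ``mu1 <= mu2``; ``weight`` is the mixing
    proportion of the lower-mean component.
    """

    weight: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def loglikelihood(self, x: np.ndarray) -> float:
        return float(np.sum(self._log_density(np.asarray(x, dtype=float))))

    def _log_density(self, x: np.ndarray) -> np.ndarray:
        a = np.log(self.weight) + sps.norm.logpdf(x, self.mu1, self.sigma1)
        b = np.log1p(-self.weight) + sps.norm.logpdf(x, self.mu2, self.sigma2)
        return np.logaddexp(a, b)


def fit_gmm2_em(
    values: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> Gmm2Fit:
    """Fit a 2-component Gaussian mixture by expectation-maximisation.

    Initialisation splits the sample at its median (lower half initialises
    the first component, upper half the second, equal weights), which is
    deterministic — ``seed`` is accepted for interface uniformity but
    unused.  Variances are floored at 1e-6 times the sample variance.
    Iteration stops when the log-likelihood gain drops below ``tol`` or
    after ``max_iter`` steps; the log-likelihood is non-decreasing along
    the way (EM guarantee).
    """
    del seed
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4 or np.unique(x).size < 2:
        raise ValueError("need at least 4 values with at least 2 distinct")
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # ties at the median
        lo, hi = np.sort(x)[: x.size // 2], np.sort(x)[x.size // 2 :]
    floor = 1e-6 * np.var(x)
    w = 0.5
    mu = np.array([lo.mean(), hi.mean()])
    var = np.maximum(np.array([lo.var(), hi.var()]), floor)

    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_a = np.log(w) + sps.norm.logpdf(x, mu[0], np.sqrt(var[0]))
        log_b = np.log1p(-w) + sps.norm.logpdf(x, mu[1], np.sqrt(var[1]))
        log_norm = np.logaddexp(log_a, log_b)
        ll = float(np.sum(log_norm))
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        gamma = np.exp(log_a - log_norm)  # responsibility of component 1
        n1 = gamma.sum()
        n2 = x.size - n1
        w = float(np.clip(n1 / x.size, 1e-10, 1 - 1e-10))
        mu = np.array(
            [np.sum(gamma * x) / n1, np.sum((1 - gamma) * x) / n2]
        )
        var = np.array(
            [
                np.sum(gamma * (x - mu[0]) ** 2) / n1,
                np.sum((1 - gamma) * (x - mu[1]) ** 2) / n2,
            ]
        )
        var = np.maximum(var, floor)

    if mu[0] > mu[1]:
        mu = mu[::-1]
        var = var[::-1]
        w = 1.0 - w
    return Gmm2Fit(
        weight=float(w),
        mu1=float(mu[0]),
        mu2=float(mu[1]),
        sigma1=float(np.sqrt(var[0])),
        sigma2=float(np.sqrt(var[1])),
        loglik=trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


def gaussian_loglik(values: np.ndarray) -> float:
    """Log-likelihood of the single-Gaussian MLE fit (bimodality baseline)."""
    x = np.asarray(values, dtype=float)
    return float(np.sum(sps.norm.logpdf(x, x.mean(), max(x.std(), 1e-12))))


def bic(loglik: float, n_params: int, n: int) -> float:
    return n_params * np.log(n) - 2.0 * loglik


# ---------------------------------------------------------------------------
# ROC equal-error-rate threshold


def roc_equal_error_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Threshold minimising |FPR − FNR| for the rule "positive iff score > t".

    Candidate thresholds are midpoints between consecutive sorted unique
    scores (plus one below the minimum and one above the maximum); ties in
    the error gap break toward the lower threshold.  Returns
    ``(threshold, sensitivity, specificity)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    pos, neg = s[y], s[~y]
    best = None
    for t in candidates:
        sens = float(np.mean(pos > t))
        spec = float(np.mean(neg <= t))
        gap = abs((1.0 - spec) - (1.0 - sens))
        if best is None or gap < best[0] - 1e-15:
            best = (gap, t, sens, spec)
    _, t, sens, spec = best
    return float(t), sens, spec


# ---------------------------------------------------------------------------
# distribution tests


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D statistic with asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class NormalityResult:
    name: str
    statistic: float | None
    p_value: float | None
    available: bool
    note: str = ""


def _anderson_darling_p(a2: float, n: int) -> float:
    """p-value approximation for the Anderson–Darling normality statistic
    (case with estimated mean and variance, D'Agostino–Stephens adjustment)."""
    a = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a >= 0.6:
        return float(np.exp(1.2937 - 5.709 * a + 0.0186 * a * a))
    if a >= 0.34:
        return float(np.exp(0.9177 - 4.279 * a - 1.38 * a * a))
    if a > 0.2:
        return float(1.0 - np.exp(-8.318 + 42.796 * a - 59.938 * a * a))
    return float(1.0 - np.exp(-13.436 + 101.14 * a - 223.73 * a * a))


def normality_suite(values: np.ndarray) -> dict[str, NormalityResult]:
    """Shapiro–Wilk, D'Agostino K² and Anderson–Darling normality tests.

    Tests whose validity range excludes the sample (or a degenerate
    constant sample) are marked unavailable rather than raising.  The
    ``non_gaussian`` entry flags any available p-value below 0.05.
    """
    x = np.asarray(values, dtype=float).ravel()
    results: dict[str, NormalityResult] = {}
    degenerate = x.size < 3 or np.ptp(x) == 0.0

    if degenerate:
        for name in ("shapiro", "dagostino", "anderson"):
            results[name] = NormalityResult(name, None, None, False,
                                            "degenerate or too-small sample")
    else:
        stat, p = sps.shapiro(x)
        results["shapiro"] = NormalityResult("shapiro", float(stat), float(p), True)
        if x.size >= 20:
            stat, p = sps.normaltest(x)
            results["dagostino"] = NormalityResult(
                "dagostino", float(stat), float(p), True
            )
        else:
            results["dagostino"] = NormalityResult(
                "dagostino", None, None, False, "n < 20"
            )
        try:
            ad = sps.anderson(x, dist="norm", method="interpolate")
            ad_p = float(ad.pvalue)
        except TypeError:  # scipy < 1.17: no p-value from anderson()
            ad = sps.anderson(x, dist="norm")
            ad_p = _anderson_darling_p(float(ad.statistic), x.size)
        results["anderson"] = NormalityResult(
            "anderson", float(ad.statistic), ad_p, True,
        )

    ps = [r.p_value for r in results.values() if r.available]
    results["non_gaussian"] = NormalityResult(
        "non_gaussian",
        None,
        None,
        bool(ps),
        "True" if any(p < 0.05 for p in ps) else "False",
    )
    return results


# ---------------------------------------------------------------------------
# stratification


@dataclass
class StratificationReport:
    threshold: float
    n: int
    n_above: int
    fraction_above: float
    sensitivity: float | None = None
    specificity: float | None = None


def stratify(
    cohort_table: pd.DataFrame, threshold: float, label_column: str = "label"
) -> StratificationReport:
    """Classify subjects as fractured iff ``arf0 > threshold``.

    Ties (arf0 == threshold) classify as non-fractured.  When true labels
    are present, achieved sensitivity/specificity are reported too.
    """
    if "arf0" not in cohort_table.columns:
        raise ValueError("cohort table lacks the 'arf0' column")
    arf = cohort_table["arf0"].to_numpy(dtype=float)
    above = arf > threshold
    report = StratificationReport(
        threshold=float(threshold),
        n=len(arf),
        n_above=int(above.sum()),
        fraction_above=float(above.mean()) if len(arf) else 0.0,
    )
    if label_column in cohort_table.columns:
        labels = cohort_table[label_column].astype(str).to_numpy()
        pos = labels == "fractured"
        neg = labels == "non-fractured"
        if pos.any() and neg.any():
            report.sensitivity = float(above[pos].mean())
            report.specificity = float((~above[neg]).mean())
    return report
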