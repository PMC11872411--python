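"""Decision statistics: ROC/Youden thresholds with bootstrap CIs,
contingency evaluation with Fisher's exact test, rank-sum comparisons and
noncentral-t power calculations.

The ROC machinery works on per-subject scores.  The operating threshold is
the Youden-index maximiser (sensitivity + specificity − 1) over all distinct
cuts, reported as the midpoint between adjacent observed scores; exact ties
in the index are resolved by a uniform random choice among the maximisers
under a caller-supplied seed, mirroring the "random best policy" convention
of common ROC software.  Confidence intervals are percentile bootstrap over
subject resampling, stratified by class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCThresholdResult", "ContingencySummary", "roc_with_youden",
    "auc_score", "contingency_eval", "fisher_exact_2x2",
    "wilcoxon_rank_sum", "power_at", "required_sample_size",
]


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class ROCThresholdResult:
    points: np.ndarray          # (n_cuts, 2) of (fpr, tpr), (0,0) .. (1,1)
    thresholds: np.ndarray      # cut value per ROC point
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    ci_95: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    tie_policy: str = "random"

    def summary_row(self) -> dict:
        row = {"auc": self.auc, "threshold": self.youden_threshold,
               "sensitivity": self.sensitivity,
               "specificity": self.specificity, "accuracy": self.accuracy}
        for k, (lo, hi) in self.ci_95.items():
            row[f"{k}_ci_low"], row[f"{k}_ci_high"] = lo, hi
        return row


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> None:
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def _candidate_cuts(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores plus open end cuts.

    A subject is called positive when its score is strictly above the cut,
    so the lowest cut calls everybody positive and the highest nobody.
    """
    u = np.unique(scores)
    if len(u) == 1:
        pad = max(abs(u[0]), 1.0) * 0.5 or 0.5
        return np.array([u[0] - pad, u[0] + pad])
    mids = (u[:-1] + u[1:]) / 2.0
    step = np.median(np.diff(u)) / 2.0
    return np.concatenate([[u[0] - step], mids, [u[-1] + step]])


def _roc_arrays(scores: np.ndarray, labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cuts = _candidate_cuts(scores)
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    above = scores[None, :] > cuts[:, None]
    tpr = (above & pos).sum(axis=1) / n_pos
    fpr = (above & ~pos).sum(axis=1) / n_neg
    order = np.lexsort((tpr, fpr))  # ascending fpr then tpr -> (0,0)..(1,1)
    return fpr[order], tpr[order], cuts[order]


def auc_score(scores, labels) -> float:
    """Trapezoidal AUC; equals the tie-corrected Mann–Whitney statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(scores, labels)
    fpr, tpr, _ = _roc_arrays(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def _youden_point(fpr, tpr, cuts, rng) -> tuple[float, float, float]:
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    pick = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
    return float(cuts[pick]), float(tpr[pick]), float(1.0 - fpr[pick])


def roc_with_youden(scores, labels, n_boot: int = 2000,
                    seed: int = 0) -> ROCThresholdResult:
    """Empirical ROC over all distinct cuts with a Youden operating point.

    Percentile bootstrap CIs (class-stratified subject resampling) are
    produced for the AUC, threshold, sensitivity, specificity and accuracy.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(scores, labels)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)

    fpr, tpr, cuts = _roc_arrays(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    thr, sens, spec = _youden_point(fpr, tpr, cuts, rng)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)

    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    stats_boot = {k: np.empty(n_boot) for k in
                  ("auc", "threshold", "sensitivity", "specificity",
                   "accuracy")}
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(pos_idx, size=len(pos_idx), replace=True),
            rng.choice(neg_idx, size=len(neg_idx), replace=True)])
        s_b, l_b = scores[take], labels[take]
        fpr_b, tpr_b, cuts_b = _roc_arrays(s_b, l_b)
        thr_b, sens_b, spec_b = _youden_point(fpr_b, tpr_b, cuts_b, rng)
        stats_boot["auc"][b] = np.trapezoid(tpr_b, fpr_b)
        stats_boot["threshold"][b] = thr_b
        stats_boot["sensitivity"][b] = sens_b
        stats_boot["specificity"][b] = spec_b
        stats_boot["accuracy"][b] = (sens_b * len(pos_idx)
                                     + spec_b * len(neg_idx)) / len(labels)
    point = {"auc": auc, "threshold": thr, "sensitivity": sens,
             "specificity": spec, "accuracy": acc}
    ci = {}
    for k, arr in stats_boot.items():
        lo, hi = np.percentile(arr, [2.5, 97.5])
        # percentile intervals are widened, if needed, to cover the
        # point estimate (relevant only in tiny or degenerate samples)
        ci[k] = (float(min(lo, point[k])), float(max(hi, point[k])))
    return ROCThresholdResult(
        points=np.column_stack([fpr, tpr]), thresholds=cuts, auc=auc,
        youden_threshold=thr, sensitivity=sens, specificity=spec,
        accuracy=acc, ci_95=ci, n_boot=n_boot, tie_policy="random")


# ---------------------------------------------------------------------------
# Contingency evaluation
# ---------------------------------------------------------------------------

@dataclass
class ContingencySummary:
    """2×2 split of subjects at a score threshold against a binary event.

    ``table`` rows are (above threshold, at-or-below threshold), columns are
    (event, no event).  The threshold value itself falls in the lower row,
    matching the convention that the boundary is low risk.
    """

    table: np.ndarray
    threshold: float
    fractions: dict[str, tuple[int, int]]
    fisher_p: float

    @property
    def above_event_fraction(self) -> float:
        num, den = self.fractions["above_event"]
        return num / den if den else float("nan")

    @property
    def below_event_fraction(self) -> float:
        num, den = self.fractions["below_event"]
        return num / den if den else float("nan")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: total probability of tables (at the same
    margins) whose point hypergeometric probability does not exceed the
    observed one."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def contingency_eval(scores, events, threshold: float) -> ContingencySummary:
    """Split subjects at ``threshold`` (strictly above = high) and cross
    with the binary event; report exact fractions and Fisher's p."""
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events).astype(bool)
    if scores.size == 0:
        raise ValueError("no records to evaluate")
    if scores.shape != events.shape:
        raise ValueError("scores and events must align")
    above = scores > threshold
    a = int((above & events).sum())
    b = int((above & ~events).sum())
    c = int((~above & events).sum())
    d = int((~above & ~events).sum())
    table = np.array([[a, b], [c, d]])
    fractions = {
        "above_event": (a, a + b),
        "below_event": (c, c + d),
        "above_no_event": (b, a + b),
        "below_no_event": (d, c + d),
    }
    return ContingencySummary(table=table, threshold=float(threshold),
                              fractions=fractions,
                              fisher_p=fisher_exact_2x2(table))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    statistic: float      # rank sum W of the first sample (midranks)
    u_statistic: float
    p_value: float
    mode: str             # "exact" or "normal"
    median_difference: float


EXACT_LIMIT = 12


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    Exact null enumeration of all rank splits when ``len(x)+len(y) <= 12``
    (or ``mode='exact'``); otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    if mode == "auto":
        mode = "exact" if m + n <= EXACT_LIMIT else "normal"
    med_diff = float(np.median(x) - np.median(y))

    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[:m].sum())
    u = w - m * (m + 1) / 2.0

    if mode == "exact":
        mu = m * ranks.sum() / (m + n)
        dev = abs(w - mu)
        hits = total = 0
        for idx in combinations(range(m + n), m):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                hits += 1
        p = hits / total
    elif mode == "normal":
        # tie-corrected normal approximation on U, continuity-corrected
        mu_u = m * n / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()
                    / ((m + n) * (m + n - 1.0)))
        var_u = m * n / 12.0 * (m + n + 1.0 - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (abs(u - mu_u) - 0.5) / math.sqrt(var_u)
            p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RankSumResult(statistic=w, u_statistic=float(u),
                         p_value=float(min(p, 1.0)), mode=mode,
                         median_difference=med_diff)


# ---------------------------------------------------------------------------
# Power / sample size (one-sample / paired t formulation)
# ---------------------------------------------------------------------------

def power_at(n: float, d: float, alpha: float = 0.05) -> float:
    """Achieved power of a two-sided one-sample t test.

    ``P(|T'| > t_{1-α/2, n-1})`` with ``T'`` noncentral t at noncentrality
    ``d·√n``.  ``n`` may be non-integral (used by the continuous solve in
    :func:`required_sample_size`).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if n < 2:
        raise ValueError("n must be at least 2")
    df = n - 1
    nc = d * math.sqrt(n)
    tc = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))


def required_sample_size(d: float, alpha: float = 0.05,
                         power: float = 0.8) -> tuple[int, float]:
    """Smallest integer n with ``power_at(n) >= power``; also returns the
    un-rounded continuous solution."""
    if not (0 < power < 1):
        raise ValueError("power must be in (0, 1)")
    hi = 4.0
    while power_at(hi, d, alpha) < power:
        hi *= 2
        if hi > 1e7:
            raise ValueError("required sample size out of range")
    from scipy.optimize import brentq
    lo = 2.0
    if power_at(lo, d, alpha) >= power:
        unrounded = 2.0
    else:
        unrounded = float(brentq(lambda n: power_at(n, d, alpha) - power,
                                 lo, hi, xtol=1e-8))
    n_int = max(2, math.ceil(unrounded - 1e-9))
    while power_at(n_int, d, alpha) < power:  # guard rounding edge cases
        n_int += 1
    return n_int, unrounded
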