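"""Evaluation arithmetic for technician-vs-classifier comparisons.

Covers the full reporting surface of a counting experiment: the 4x4
confusion matrix between technician (truth) and classifier categories, its
per-category sensitivities and positive predictive values, the discordance
matrix, a chi-square comparison of two raters' concordance against a common
reference, the Mann-Whitney separation of confidence between concordant and
discordant wells, and maximum-likelihood estimation of the Poisson occupancy
rate lambda from categorized (right-censored at ">2") counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import optimize, stats as sp_stats

from .synth import CATEGORY_LABELS

N_CATEGORIES = 4


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 counts; rows = technician (truth), columns = classifier."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CATEGORIES, N_CATEGORIES):
            raise ValueError("confusion matrix must be 4x4")
        if (c < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))


@dataclass(frozen=True)
class CategoryRates:
    """Sensitivities, PPVs and overall concordance derived from a matrix.

    Rates for categories with a zero marginal are NaN and flagged in the
    corresponding ``*_defined`` mask rather than reported as 0.
    """

    sensitivity: np.ndarray
    ppv: np.ndarray
    overall_concordance: float
    sensitivity_defined: np.ndarray
    ppv_defined: np.ndarray


@dataclass(frozen=True)
class PoissonOccupancyFit:
    """Censored-Poisson occupancy fit from (n0, n1, n2, n_gt2)."""

    lambda_hat: float
    log_likelihood: float
    counts: Tuple[int, int, int, int]


def confusion_matrix(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    """Assemble the 4x4 matrix; entry (i, j) counts truth i predicted j."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    for name, a in (("truth", t), ("predicted", p)):
        if a.size and (a.min() < 0 or a.max() >= N_CATEGORIES):
            bad = a[(a < 0) | (a >= N_CATEGORIES)][0]
            raise ValueError(f"invalid {name} category value {bad}")
    counts = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def category_rates(cm: ConfusionMatrix) -> CategoryRates:
    """Per-truth sensitivity, per-prediction PPV, and overall concordance."""
    if cm.n == 0:
        raise ValueError("confusion matrix is all zeros")
    diag = np.diag(cm.counts).astype(float)
    rows = cm.row_totals.astype(float)
    cols = cm.col_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(rows > 0, diag / rows, np.nan)
        ppv = np.where(cols > 0, diag / cols, np.nan)
    return CategoryRates(
        sensitivity=sens,
        ppv=ppv,
        overall_concordance=cm.trace / cm.n,
        sensitivity_defined=rows > 0,
        ppv_defined=cols > 0,
    )


def discordance_matrix(cm: ConfusionMatrix):
    """Off-diagonal counts with row/column totals and the overall total.

    Returns ``(off_diagonal, row_totals, col_totals, total)`` where the
    diagonal of ``off_diagonal`` is zero and ``total = n - trace``.
    """
    off = cm.counts.copy()
    np.fill_diagonal(off, 0)
    return off, off.sum(axis=1), off.sum(axis=0), int(off.sum())


def expected_poisson_proportions(lam: float) -> np.ndarray:
    """(P(0), P(1), P(2), P(>2)) under Poisson(lambda); sums to 1."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = sp_stats.poisson.pmf([0, 1, 2], lam)
    return np.append(p, max(0.0, 1.0 - p.sum()))


def _censored_loglik(lam: float, counts: np.ndarray) -> float:
    probs = expected_poisson_proportions(lam)
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(np.maximum(probs[mask], 1e-300))))


def fit_poisson_occupancy(n0: int, n1: int, n2: int, n_gt2: int) -> PoissonOccupancyFit:
    """ML estimate of the occupancy rate from categorized well counts.

    The ">2" class is right-censored: its cell probability is
    1 - P(0) - P(1) - P(2).  The multinomial likelihood is maximized
    numerically to |d lambda| < 1e-7.  With every well empty the MLE is
    exactly 0.
    """
    counts = np.array([n0, n1, n2, n_gt2], dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total < 1:
        raise ValueError("need at least one well")
    if counts[0] == total:
        return PoissonOccupancyFit(0.0, 0.0, tuple(int(c) for c in counts))
    # the censored MLE is bracketed well inside (0, upper): the uncensored
    # sample mean (counting gt2 as 3) overestimates lambda only mildly
    upper = max(1e-3, 3.0 * float(counts @ np.array([0, 1, 2, 3])) / total + 1.0)
    res = optimize.minimize_scalar(
        lambda lam: -_censored_loglik(lam, counts),
        bounds=(1e-12, upper),
        method="bounded",
        options={"xatol": 1e-9},
    )
    lam = float(res.x)
    return PoissonOccupancyFit(lam, _censored_loglik(lam, counts),
                               tuple(int(c) for c in counts))


def compare_concordance_chi2(table, correction: bool = False) -> Tuple[float, float]:
    """Pearson chi-square on a 2x2 concordant/discordant x rater-pair table.

    ``table`` is [[concordant_A, concordant_B], [discordant_A, discordant_B]]
    (any consistent 2x2 orientation gives the same statistic).  Yates
    continuity correction is off by default; enable with ``correction``.
    Returns ``(statistic, two-sided p)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    stat, p, _, _ = sp_stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def confidence_separation_test(h_concordant, h_discordant,
                               log_transform: bool = True) -> Tuple[float, float]:
    """Mann-Whitney U comparing confidence of concordant vs discordant wells.

    Applied to log-transformed highest outputs (the log is monotone, so the
    rank statistic is unchanged; it only matches how the distributions are
    usually displayed).  Exact enumeration for small tie-free samples,
    normal approximation with tie correction otherwise.  Returns
    ``(U, two-sided p)`` with U for the concordant group.
    """
    a = np.asarray(h_concordant, dtype=float)
    b = np.asarray(h_discordant, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("h values must be positive for the log transform")
        a, b = np.log(a), np.log(b)
    small = max(a.size, b.size) <= 8 and np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if small else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rates_report(cm: ConfusionMatrix) -> dict:
    """JSON-ready summary of a confusion matrix (used by the CLI)."""
    r = category_rates(cm)
    off, row_t, col_t, total = discordance_matrix(cm)
    return {
        "n": cm.n,
        "confusion": cm.counts.tolist(),
        "row_totals": cm.row_totals.tolist(),
        "col_totals": cm.col_totals.tolist(),
        "overall_concordance": r.overall_concordance,
        "sensitivity": {
            CATEGORY_LABELS[i]: (None if not r.sensitivity_defined[i] else float(r.sensitivity[i]))
            for i in range(N_CATEGORIES)
        },
        "ppv": {
            CATEGORY_LABELS[i]: (None if not r.ppv_defined[i] else float(r.ppv[i]))
            for i in range(N_CATEGORIES)
        },
        "discordant_total": total,
        "discordance_matrix": off.tolist(),
    }
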