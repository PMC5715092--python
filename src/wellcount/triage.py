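"""Confidence triage of ambiguous wells ("enhanced system").

The classifier's confidence for well ``s`` is its highest posterior output
``h(s)``.  Wells with ``h(s) < t`` form the *ambiguous set*; the rest are
retained.  Two policies quantify the benefit of routing ambiguous wells away
from the automated call:

* ``resolve_by_human`` — ambiguous wells go to visual inspection and are
  assumed correct afterwards, so the concordance rate becomes
  (concordant retained + ambiguous) / total;
* ``exclude`` — ambiguous wells are dropped, so the rate becomes
  concordant retained / retained.

Because misclassified wells concentrate at low ``h``, a small ambiguous
proportion (1-5%) buys a disproportionate accuracy gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

POLICIES = ("resolve_by_human", "exclude")


@dataclass(frozen=True)
class TriageConfig:
    """Either a fixed threshold ``t`` or a target ambiguous proportion ``p``.

    Exactly one of the two must be given.  ``t`` lives in (0.25, 1] for a
    4-way softmax (the maximum posterior is at least 1/4); ``p`` in [0, 1).
    """

    threshold: Optional[float] = None
    target_ambiguous_proportion: Optional[float] = None
    policy: str = "resolve_by_human"

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.target_ambiguous_proportion is None):
            raise ValueError("specify exactly one of threshold / target proportion")
        if self.threshold is not None and not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        p = self.target_ambiguous_proportion
        if p is not None and not 0.0 <= p < 1.0:
            raise ValueError("target ambiguous proportion must lie in [0, 1)")
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}")


@dataclass(frozen=True)
class TriageResult:
    """Partition of wells into ambiguous and retained at threshold ``t``."""

    threshold: float
    ambiguous: np.ndarray  # indices
    retained: np.ndarray  # indices
    ambiguous_proportion: float
    concordance: Optional[float] = None
    policy: Optional[str] = None


def _as_h(predictions) -> np.ndarray:
    """Accept PredictionResult sequences or bare arrays of h values."""
    if len(predictions) and hasattr(predictions[0], "highest_output"):
        return np.array([p.highest_output for p in predictions], dtype=float)
    return np.asarray(predictions, dtype=float)


def flag_ambiguous(predictions, t: float) -> TriageResult:
    """Split wells into ambiguous (h(s) < t, strict) and retained (h(s) >= t)."""
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold t must lie in (0, 1]")
    h = _as_h(predictions)
    amb = np.flatnonzero(h < t)
    ret = np.flatnonzero(h >= t)
    return TriageResult(t, amb, ret, len(amb) / len(h) if len(h) else 0.0)


def threshold_for_proportion(predictions, p: float) -> Tuple[float, float]:
    """Largest observed-h threshold whose ambiguous fraction does not exceed p.

    Returns ``(t, realized_fraction)``.  The threshold is taken from the
    observed h values (an empirical quantile); with ties the realized
    fraction may undershoot ``p`` but never overshoots — the ambiguous set is
    the human workload, so the target is treated as a cap.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("target proportion must lie in [0, 1)")
    h = _as_h(predictions)
    if h.size == 0:
        raise ValueError("no predictions given")
    values = np.sort(np.unique(h))
    n = h.size
    best_t, best_frac = values[0], 0.0  # t = min h: nothing strictly below
    for t in values:
        frac = np.count_nonzero(h < t) / n
        if frac <= p:
            best_t, best_frac = float(t), float(frac)
        else:
            break
    return best_t, best_frac


def concordance_with_triage(predictions, truth, t: float,
                            policy: str = "resolve_by_human") -> TriageResult:
    """Concordance rate after triaging at threshold ``t`` under ``policy``.

    ``predictions`` provides predicted categories and h values (sequences of
    PredictionResult, or a tuple ``(predicted, h)`` of arrays); ``truth`` is
    the per-well true category.  At ``t <= min h`` both policies reduce to
    the raw concordance rate.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    if isinstance(predictions, tuple):
        pred, h = (np.asarray(a) for a in predictions)
    else:
        pred = np.array([p.predicted_category for p in predictions])
        h = _as_h(predictions)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("predictions and truth length mismatch")
    res = flag_ambiguous(h, t)
    concordant_ret = int((pred[res.retained] == truth[res.retained]).sum())
    if policy == "resolve_by_human":
        rate = (concordant_ret + len(res.ambiguous)) / len(truth)
    else:
        rate = concordant_ret / len(res.retained) if len(res.retained) else np.nan
    return TriageResult(res.threshold, res.ambiguous, res.retained,
                        res.ambiguous_proportion, rate, policy)


def concordance_curve(predictions, truth, proportions: Iterable[float],
                      policy: str = "resolve_by_human") -> List[Tuple[float, float]]:
    """(realized ambiguous proportion, concordance rate) along a target grid.

    Under the resolve policy the curve is monotone non-decreasing in the
    proportion: raising the threshold only moves wells from the automated
    call to (assumed-correct) human review.
    """
    if isinstance(predictions, tuple):
        h: Sequence = predictions[1]
    else:
        h = predictions
    points = []
    for p in proportions:
        t, realized = threshold_for_proportion(h, p)
        res = concordance_with_triage(predictions, truth, t, policy)
        points.append((realized, res.concordance))
    return points
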