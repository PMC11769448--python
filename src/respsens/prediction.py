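"""Threshold calls, run concordance, panel accuracy and per-marker t-tests.

The prediction model generalizes the human Cell Line Activation Test
(h-CLAT): a marker is called positive when its rMFI meets or exceeds a
criterion threshold (CD86 ≥ 150%, CD54 ≥ 200%; for the TSLPr candidate
marker three tentative thresholds of 120/150/200% are swept), two
concordant runs settle a prediction and a discordant pair triggers a third
run decided by majority. Panel accuracy scores the calls against known
chemical classes, excluding non-evaluable conditions from the denominator.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Mapping, Sequence

from scipy import stats

from .types import (
    AccuracyReport,
    Criterion,
    RmfiResult,
    RunPrediction,
    SignificanceResult,
    ThresholdCall,
)

#: Default criterion set: h-CLAT thresholds plus the tentative TSLPr sweep.
DEFAULT_CRITERIA = {"CD86": (150.0,), "CD54": (200.0,), "TSLPr": (120.0, 150.0, 200.0)}


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (78.5 → 79)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def threshold_call(
    rmfi: RmfiResult, criterion: Criterion, chemical: str, dose_tier: str
) -> ThresholdCall:
    """Apply one ≥-threshold criterion to an rMFI result.

    Non-evaluable results (low flow viability or a degenerate denominator)
    produce "n/a" regardless of the stored value; the boundary is inclusive,
    so an rMFI exactly at the threshold is called "+".
    """
    if criterion.marker != rmfi.marker:
        raise ValueError(f"criterion marker {criterion.marker!r} != result marker {rmfi.marker!r}")
    if not rmfi.evaluable:
        call = "n/a"
    else:
        call = "+" if rmfi.rmfi >= criterion.threshold else "-"
    return ThresholdCall(
        chemical=chemical,
        dose_tier=dose_tier,
        marker=criterion.marker,
        threshold=criterion.threshold,
        call=call,
    )


def majority_prediction(chemical: str, calls: Sequence[str]) -> RunPrediction:
    """Combine 2–3 independent run calls into a final prediction.

    Two concordant runs settle the call; a discordant pair is indeterminate
    (a third run is needed); with three runs the majority decides.
    """
    if not all(c in ("+", "-") for c in calls):
        raise ValueError("run calls must be '+' or '-'")
    if len(calls) == 2:
        final = calls[0] if calls[0] == calls[1] else "indeterminate"
    elif len(calls) == 3:
        final = Counter(calls).most_common(1)[0][0]
    else:
        raise ValueError(f"expected 2 or 3 run calls, got {len(calls)}")
    return RunPrediction(chemical=chemical, calls=tuple(calls), final=final)


def panel_accuracy(
    calls: Sequence[ThresholdCall], truth: Mapping[str, bool]
) -> AccuracyReport:
    """Score one tier × criterion call set against known chemical classes.

    ``truth`` maps each chemical to whether it is a respiratory sensitizer:
    the correct call for a respiratory sensitizer is "+", for every other
    chemical (skin sensitizers and non-sensitizers alike) "−". Calls of
    "n/a" are dropped from the denominator. Accuracy is reported as an
    integer percentage, rounded half away from zero.
    """
    if not calls:
        raise ValueError("no calls to score")
    tiers = {c.dose_tier for c in calls}
    thresholds = {c.threshold for c in calls}
    if len(tiers) != 1 or len(thresholds) != 1:
        raise ValueError("panel_accuracy scores one dose tier and one threshold at a time")

    evaluable = [c for c in calls if c.call != "n/a"]
    if not evaluable:
        raise ValueError("zero evaluable calls; accuracy undefined")
    n_correct = sum(
        1 for c in evaluable if c.call == ("+" if truth[c.chemical] else "-")
    )
    return AccuracyReport(
        dose_tier=tiers.pop(),
        threshold=thresholds.pop(),
        n_evaluable=len(evaluable),
        n_correct=n_correct,
        accuracy=round_half_away(100.0 * n_correct / len(evaluable)),
        calls=tuple(calls),
    )


def marker_significance(rmfi_replicates: Sequence[float], null: float = 100.0) -> SignificanceResult:
    """One-sample t-test of biological-replicate rMFIs against the vehicle level.

    The null mean is 100% (no induction relative to vehicle). Stars follow
    the usual convention: "*" for p ≤ 0.05, "**" for p ≤ 0.01. Replicates
    with zero variance make the statistic undefined and are flagged rather
    than forced.
    """
    vals = list(map(float, rmfi_replicates))
    if len(vals) < 2:
        raise ValueError("need at least two replicates")
    df = len(vals) - 1
    if len(set(vals)) == 1:
        return SignificanceResult(t=None, df=df, p=None, stars="", zero_variance=True)
    res = stats.ttest_1samp(vals, popmean=null)
    p = float(res.pvalue)
    stars = "**" if p <= 0.01 else "*" if p <= 0.05 else ""
    return SignificanceResult(t=float(res.statistic), df=df, p=p, stars=stars)
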