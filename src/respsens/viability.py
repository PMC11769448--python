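"""Viability normalization, dose-response assembly and CV75 dose selection.

The assay reads resorufin fluorescence from three compartments of the
coculture (apical A549+MΦ-THP-1, endothelial EA.hy926, dendritic DC-THP-1).
Relative viability is the blank-corrected sample signal as a percentage of
the blank-corrected vehicle control:

    viability = 100 · (F_sample − F_blank) / (F_vehicle − F_blank)

The whole-test-system curve is the unweighted mean of the three compartment
curves at each dose. The CV75 — the dose leaving 75% residual viability —
is estimated by log-linear interpolation between the bracketing points:

    log10 CV75 = [(75 − c)·log10 b − (75 − a)·log10 d] / (a − c)

with a the minimum viability above 75% (at dose b) and c the maximum
viability below 75% (at dose d). Exposure doses for the sensitization
readout are CV75 and CV75/2; when the curve never drops below 75% the
maximum tested dose stands in for the CV75.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .errors import DegenerateControlError, DoseRangeError, StructuralError
from .types import (
    AVERAGE_CURVE,
    COMPARTMENTS,
    Cv75Bracket,
    Cv75Result,
    DoseResponsePoint,
    ExposurePlan,
    WellReading,
)

log = logging.getLogger(__name__)

VIABILITY_TARGET = 75.0  # % residual viability defining the CV75


def relative_viability(sample: float, blank: float, vehicle: float) -> float:
    """Blank-corrected viability (%) of a sample well relative to the vehicle.

    Not clamped: noisy wells may legitimately exceed 100% or fall below 0%.

    Raises
    ------
    DegenerateControlError
        If the vehicle-control signal does not exceed the blank, which makes
        the normalization denominator non-positive.
    """
    if not vehicle > blank:
        raise DegenerateControlError(
            f"vehicle-control fluorescence ({vehicle}) must exceed blank ({blank})"
        )
    return 100.0 * (sample - blank) / (vehicle - blank)


def build_dose_response(readings: Iterable[WellReading]) -> Dict[str, List[DoseResponsePoint]]:
    """Assemble per-compartment viability curves plus the averaged test-system curve.

    Blank and vehicle controls are matched within each compartment; replicate
    viabilities are averaged per dose. All three compartments must be present
    on a shared dose grid; the fourth curve (:data:`~respsens.types.AVERAGE_CURVE`)
    is their unweighted arithmetic mean at each dose.
    """
    by_comp: Dict[str, List[WellReading]] = defaultdict(list)
    for r in readings:
        by_comp[r.compartment].append(r)

    missing = [c for c in COMPARTMENTS if c not in by_comp]
    if missing:
        raise StructuralError(f"missing compartment(s): {', '.join(missing)}")

    curves: Dict[str, List[DoseResponsePoint]] = {}
    grids: Dict[str, tuple] = {}
    for comp in COMPARTMENTS:
        wells = by_comp[comp]
        blanks = [w.raw_fluorescence for w in wells if w.role == "blank"]
        vehicles = [w.raw_fluorescence for w in wells if w.role == "vehicle_control"]
        if not blanks or not vehicles:
            raise StructuralError(f"compartment {comp!r} lacks blank or vehicle controls")
        blank = float(np.mean(blanks))
        vehicle = float(np.mean(vehicles))

        per_dose: Dict[float, List[float]] = defaultdict(list)
        for w in wells:
            if w.role == "sample":
                per_dose[w.dose].append(relative_viability(w.raw_fluorescence, blank, vehicle))
        if not per_dose:
            raise StructuralError(f"compartment {comp!r} has no sample wells")
        doses = tuple(sorted(per_dose))
        curves[comp] = [
            DoseResponsePoint(dose=d, viability=float(np.mean(per_dose[d])), curve_id=comp)
            for d in doses
        ]
        grids[comp] = doses

    grid = grids[COMPARTMENTS[0]]
    if any(grids[c] != grid for c in COMPARTMENTS[1:]):
        raise StructuralError(f"compartments measured on different dose grids: {grids}")

    curves[AVERAGE_CURVE] = [
        DoseResponsePoint(
            dose=d,
            viability=float(np.mean([curves[c][i].viability for c in COMPARTMENTS])),
            curve_id=AVERAGE_CURVE,
        )
        for i, d in enumerate(grid)
    ]
    return curves


def compute_cv75(curve: Sequence[DoseResponsePoint]) -> Cv75Result:
    """Estimate the CV75 of one dose-response curve by log-linear interpolation.

    Anchor selection follows the printed definitions globally: ``a`` is the
    minimum viability among points above 75% and ``c`` the maximum among
    points below 75%, even on non-monotone curves (a warning is logged when
    the resulting bracket is not a pair of adjacent doses). A point at
    exactly 75% short-circuits to its own dose. A curve that never drops
    below 75% yields ``fallback=True`` with no CV75.

    Raises
    ------
    DoseRangeError
        If no point lies above 75% — the crossing cannot be bracketed and
        the dose range must be extended downward.
    """
    pts = sorted(curve, key=lambda p: p.dose)
    if len(pts) < 2:
        raise ValueError("need at least two dose-response points")
    curve_id = pts[0].curve_id

    exact = [p for p in pts if p.viability == VIABILITY_TARGET]
    if exact:
        return Cv75Result(cv75=exact[0].dose, bracket=None, fallback=False, curve_id=curve_id)

    above = [p for p in pts if p.viability > VIABILITY_TARGET]
    below = [p for p in pts if p.viability < VIABILITY_TARGET]
    if not above:
        raise DoseRangeError(
            f"curve {curve_id!r}: all viabilities below {VIABILITY_TARGET}%; "
            "extend the dose range downward to bracket the crossing"
        )
    if not below:
        return Cv75Result(cv75=None, bracket=None, fallback=True, curve_id=curve_id)

    a = min(p.viability for p in above)
    # tie-breaks pick the anchor nearest the crossing on a decreasing curve
    b = max(p.dose for p in above if p.viability == a)
    c = max(p.viability for p in below)
    d = min(p.dose for p in below if p.viability == c)

    idx = {p.dose: i for i, p in enumerate(pts)}
    if abs(idx[b] - idx[d]) != 1:
        log.warning(
            "curve %r is non-monotone around 75%%: bracket doses %g and %g are not adjacent",
            curve_id, b, d,
        )

    log_cv75 = ((VIABILITY_TARGET - c) * math.log10(b) - (VIABILITY_TARGET - a) * math.log10(d)) / (a - c)
    return Cv75Result(
        cv75=10.0 ** log_cv75,
        bracket=Cv75Bracket(a=a, b=b, c=c, d=d),
        fallback=False,
        curve_id=curve_id,
    )


def select_exposure_doses(result: Cv75Result, max_tested_dose: float) -> ExposurePlan:
    """Derive the (high, low) exposure doses from a CV75 estimate.

    The high dose is the CV75 and the low dose exactly half of it. For a
    non-cytotoxic chemical (``fallback=True``) the highest dose applied in
    the dose-response experiment is used instead, again halved for the low
    tier. A CV75 above the tested range still yields a plan but warns that
    the bracket was extrapolated.
    """
    if not max_tested_dose > 0:
        raise ValueError("max_tested_dose must be positive")
    if result.fallback:
        return ExposurePlan(
            high_dose=max_tested_dose, low_dose=max_tested_dose / 2.0, source="max_dose_fallback"
        )
    if result.cv75 > max_tested_dose:
        warnings.warn(
            f"CV75 ({result.cv75:g} µg/cm²) exceeds the maximum tested dose "
            f"({max_tested_dose:g} µg/cm²); exposure plan is extrapolated",
            stacklevel=2,
        )
    return ExposurePlan(high_dose=result.cv75, low_dose=result.cv75 / 2.0, source="cv75")
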