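"""Flow-cytometry reduction: dead-cell gating, geometric MFIs, relative MFI.

Surface-marker induction on the dendritic-like THP-1 cells is expressed as
an isotype-corrected relative geometric mean fluorescence intensity,

    rMFI = 100 · (MFI_sample − MFI_isotype,sample)
               / (MFI_vehicle − MFI_isotype,vehicle)

computed on viable events only. Events positive for the dead-cell stain
(SYTOX-type nucleic-acid dye) are removed first; a condition whose viable
fraction falls strictly below the 75% gate is marked non-evaluable, since
membrane-compromised cells stain diffusely and corrupt the marker signal.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import GatingError
from .types import MarkerMeasurement, RmfiResult

log = logging.getLogger(__name__)

DEFAULT_VIABILITY_GATE = 75.0  # % viable events required for evaluability


def gate_viable(
    events: pd.DataFrame,
    dead_col: str = "dead",
    dead_stain_col: Optional[str] = None,
    dead_stain_cutoff: Optional[float] = None,
) -> Tuple[pd.DataFrame, float]:
    """Remove dead events and report the viable fraction.

    By default events are gated on a boolean ``dead`` flag. When raw
    dead-stain intensities are supplied instead (``dead_stain_col`` plus a
    global ``dead_stain_cutoff``), events strictly above the cutoff are
    treated as dead.

    Returns the viable subset and viable/total as a fraction in [0, 1].
    Raises :class:`~respsens.errors.GatingError` when no viable event remains.
    """
    if len(events) == 0:
        raise GatingError("no events to gate")
    if dead_stain_col is not None:
        if dead_stain_cutoff is None:
            raise ValueError("dead_stain_cutoff required when gating on raw intensities")
        dead = events[dead_stain_col].to_numpy() > dead_stain_cutoff
    else:
        dead = events[dead_col].to_numpy().astype(bool)
    viable = events.loc[~dead]
    fraction = len(viable) / len(events)
    if len(viable) == 0:
        raise GatingError("all events are dead; no viable population to analyse")
    return viable, fraction


def geometric_mfi(values: Sequence[float]) -> float:
    """Geometric mean fluorescence intensity, exp(mean(log x)).

    All intensities must be strictly positive; callers working from
    baseline-subtracted instrument exports should drop non-positive events
    first (see :func:`drop_nonpositive`).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take the geometric mean of zero events")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive intensities")
    return float(np.exp(np.mean(np.log(arr))))


def drop_nonpositive(values: Sequence[float], label: str = "") -> np.ndarray:
    """Drop non-positive event intensities, logging how many were removed.

    Baseline subtraction on some instruments produces zero or negative
    intensities for which a geometric mean is undefined.
    """
    arr = np.asarray(values, dtype=float)
    bad = int(np.count_nonzero(arr <= 0))
    if bad:
        log.warning("dropping %d non-positive event intensities %s", bad, label)
    return arr[arr > 0]


def compute_rmfi(m: MarkerMeasurement) -> RmfiResult:
    """Isotype-corrected relative MFI (%) of a condition against its vehicle.

    A non-positive denominator (vehicle MFI not exceeding its isotype
    control) makes the ratio meaningless: the result is returned
    non-evaluable with reason ``degenerate_denominator``. Negative rMFIs
    (sample below its isotype control) are returned unclamped with a warning.
    """
    denom = m.mfi_vehicle - m.mfi_isotype_vehicle
    if denom <= 0:
        return RmfiResult(
            marker=m.marker, rmfi=None, evaluable=False, exclusion_reason="degenerate_denominator"
        )
    rmfi = 100.0 * (m.mfi_sample - m.mfi_isotype_sample) / denom
    if rmfi < 0:
        warnings.warn(
            f"{m.marker}: sample MFI below its isotype control (rMFI {rmfi:.1f}%)",
            stacklevel=2,
        )
    return RmfiResult(marker=m.marker, rmfi=rmfi, evaluable=True, exclusion_reason=None)


def apply_viability_gate(
    r: RmfiResult, viable_fraction: float, gate: float = DEFAULT_VIABILITY_GATE
) -> RmfiResult:
    """Mark a result non-evaluable when flow viability is strictly below the gate.

    The boundary is inclusive: a condition at exactly the gate (75% by
    default) remains evaluable; only strictly lower viability excludes it.
    """
    if not 0 < gate <= 100:
        raise ValueError("gate must lie in (0, 100]")
    if viable_fraction * 100.0 < gate:
        return RmfiResult(
            marker=r.marker, rmfi=r.rmfi, evaluable=False, exclusion_reason="low_viability"
        )
    return r


def rmfi_from_events(
    sample_events: pd.DataFrame,
    vehicle_events: pd.DataFrame,
    marker: str,
    gate: float = DEFAULT_VIABILITY_GATE,
    fluorescence_col: str = "fluorescence",
    tube_col: str = "tube",
    **gate_kwargs,
) -> Tuple[RmfiResult, float]:
    """Full event-level reduction for one marker and condition.

    Expects stained and isotype tubes in each event table (``tube`` column
    with values ``stained``/``isotype``). Tables carrying a ``marker``
    column are subset to the requested marker first. Both tubes are
    viability-gated with the same rule; the condition's viable fraction is
    taken from the stained tube. Returns the gated :class:`RmfiResult` and
    that viable fraction.
    """
    if "marker" in sample_events.columns:
        sample_events = sample_events.loc[sample_events["marker"] == marker]
    if "marker" in vehicle_events.columns:
        vehicle_events = vehicle_events.loc[vehicle_events["marker"] == marker]

    def _tube_mfi(events: pd.DataFrame, tube: str) -> Tuple[float, float, int]:
        sub = events.loc[events[tube_col] == tube]
        if len(sub) == 0:
            raise GatingError(f"no {tube!r} events for marker {marker!r}")
        viable, fraction = gate_viable(sub, **gate_kwargs)
        vals = drop_nonpositive(viable[fluorescence_col], label=f"({marker}/{tube})")
        return geometric_mfi(vals), fraction, len(sub)

    mfi_sample, frac_sample, n_events = _tube_mfi(sample_events, "stained")
    mfi_iso_sample, _, _ = _tube_mfi(sample_events, "isotype")
    mfi_vehicle, _, _ = _tube_mfi(vehicle_events, "stained")
    mfi_iso_vehicle, _, _ = _tube_mfi(vehicle_events, "isotype")

    m = MarkerMeasurement(
        marker=marker,
        mfi_sample=mfi_sample,
        mfi_isotype_sample=mfi_iso_sample,
        mfi_vehicle=mfi_vehicle,
        mfi_isotype_vehicle=mfi_iso_vehicle,
        viable_fraction=frac_sample,
        n_events=n_events,
    )
    result = apply_viability_gate(compute_rmfi(m), frac_sample, gate=gate)
    return result, frac_sample
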