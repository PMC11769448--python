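"""Core record types shared across the pipeline stages.

The assay couples three readouts on an air-liquid-interface alveolar
coculture: resazurin viability per cell compartment, flow-cytometric surface
markers (CD86, CD54, TSLPr) on dendritic-like THP-1 cells, and a
threshold-based prediction model. Records here are plain frozen dataclasses;
validated configuration objects live in :mod:`respsens.synthetic` and
:mod:`respsens.pipeline` as pydantic models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Optional

#: Cell compartments of the tetraculture whose viability is read separately.
COMPARTMENTS = ("apical", "endothelial", "dendritic")

#: Identifier for the averaged whole-test-system dose-response curve.
AVERAGE_CURVE = "ali_average"

MARKERS = ("CD86", "CD54", "TSLPr")

ROLES = ("sample", "vehicle_control", "blank")

#: Exposure tiers derived from the CV75: half of it and the CV75 itself.
TIERS = ("half_cv75", "cv75")


@dataclass(frozen=True)
class WellReading:
    """One resorufin fluorescence measurement from a viability plate."""

    compartment: str
    role: str  # sample | vehicle_control | blank
    raw_fluorescence: float
    dose: Optional[float] = None  # µg/cm²; None for control/blank wells
    replicate_id: str = "r1"
    chemical: str = "sample"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "sample":
            if self.dose is None or not self.dose > 0:
                raise ValueError("sample wells need a positive dose")
        elif self.dose is not None:
            raise ValueError(f"{self.role} wells carry no dose")
        if not math.isfinite(self.raw_fluorescence):
            raise ValueError("raw_fluorescence must be finite")


@dataclass(frozen=True)
class DoseResponsePoint:
    """Mean relative viability (%) at one dose on one curve."""

    dose: float  # µg/cm², > 0
    viability: float  # %, may exceed 100 with noise; never clamped
    curve_id: str  # compartment name or AVERAGE_CURVE

    def __post_init__(self):
        if not self.dose > 0:
            raise ValueError("dose must be positive")


@dataclass(frozen=True)
class Cv75Bracket:
    """Interpolation anchors: viability a (>75) at dose b, c (<75) at dose d."""

    a: float
    b: float
    c: float
    d: float


@dataclass(frozen=True)
class Cv75Result:
    """Estimated CV75 (dose at 75% residual viability) for one curve.

    ``fallback`` is True exactly when the curve never drops below 75%, in
    which case no CV75 exists and dose selection falls back to the maximum
    tested dose.
    """

    cv75: Optional[float]
    bracket: Optional[Cv75Bracket]
    fallback: bool
    curve_id: str

    def __post_init__(self):
        if self.fallback != (self.cv75 is None):
            raise ValueError("fallback=True exactly when cv75 is None")


@dataclass(frozen=True)
class ExposurePlan:
    """High/low exposure doses for the sensitization readout."""

    high_dose: float
    low_dose: float
    source: str  # "cv75" | "max_dose_fallback"

    def __post_init__(self):
        if self.source not in ("cv75", "max_dose_fallback"):
            raise ValueError(f"unknown plan source {self.source!r}")


@dataclass(frozen=True)
class MarkerMeasurement:
    """Geometric MFIs needed to form one isotype-corrected relative MFI."""

    marker: str
    mfi_sample: float
    mfi_isotype_sample: float
    mfi_vehicle: float
    mfi_isotype_vehicle: float
    viable_fraction: float
    n_events: int = 0

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        for name in ("mfi_sample", "mfi_isotype_sample", "mfi_vehicle", "mfi_isotype_vehicle"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.viable_fraction <= 1.0:
            raise ValueError("viable_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class RmfiResult:
    """Isotype-corrected relative MFI (%) with its evaluability status."""

    marker: str
    rmfi: Optional[float]
    evaluable: bool
    exclusion_reason: Optional[str] = None  # low_viability | degenerate_denominator

    def __post_init__(self):
        if not self.evaluable and self.exclusion_reason is None:
            raise ValueError("non-evaluable results need an exclusion_reason")


@dataclass(frozen=True)
class Criterion:
    """Positivity rule: call '+' when rMFI ≥ threshold (%)."""

    marker: str
    threshold: float

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if not self.threshold > 100:
            raise ValueError("threshold must exceed 100%")


@dataclass(frozen=True)
class ThresholdCall:
    """A single +/−/n/a call for one chemical, tier, marker and threshold."""

    chemical: str
    dose_tier: str
    marker: str
    threshold: float
    call: str  # "+" | "-" | "n/a"

    def __post_init__(self):
        if self.dose_tier not in TIERS:
            raise ValueError(f"unknown dose tier {self.dose_tier!r}")
        if self.call not in ("+", "-", "n/a"):
            raise ValueError(f"unknown call {self.call!r}")


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy of one criterion over a chemical panel at one dose tier."""

    dose_tier: str
    threshold: float
    n_evaluable: int
    n_correct: int
    accuracy: int  # %, rounded half away from zero
    calls: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class RunPrediction:
    """Final prediction combined over 2–3 independent runs."""

    chemical: str
    calls: tuple
    final: str  # "+" | "-" | "indeterminate"


@dataclass(frozen=True)
class SignificanceResult:
    """One-sample t-test of replicate rMFIs against the vehicle level (100%)."""

    t: Optional[float]
    df: int
    p: Optional[float]
    stars: str  # "", "*", "**"
    zero_variance: bool = False
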