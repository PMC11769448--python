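"""Synthetic assay-data generator with known ground truth.

Emulates the two raw readouts of the air-liquid-interface sensitization
assay so every downstream stage has a parameter-recovery surface:

* **Viability plates** — each compartment follows a log-logistic decay in
  dose, anchored so the noise-free curve crosses 75% viability exactly at a
  configured true CV75 (or stays flat at the top level for a non-cytotoxic
  chemical). Gaussian noise is added on the viability scale, truncated at
  zero, and mapped back to resorufin fluorescence between the configured
  blank and vehicle levels.
* **Flow conditions** — event fluorescence is lognormal (the standard model
  for cytometry intensities), with stained-tube geometric means placed at
  isotype + multiplier·(baseline − isotype) so the expected rMFI is exactly
  100·multiplier. Dead events are Bernoulli with a configurable fraction and
  carry an elevated dead-stain intensity.

All randomness flows through numpy Generators seeded from the configs; a
panel spawns per-chemical substreams from one master seed and records them
in its metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError
from .types import COMPARTMENTS, MARKERS, TIERS, WellReading

DEAD_STAIN_VIABLE_GM = 80.0  # a.u., dead-stain geometric mean of intact cells
DEAD_STAIN_DEAD_GM = 8000.0  # a.u., of membrane-compromised cells
DEAD_STAIN_CUTOFF = 1000.0  # global gate separating the two populations
DEAD_STAIN_CV = 0.5


class CompartmentResponse(BaseModel):
    """Noise-free log-logistic viability response of one cell compartment."""

    model_config = ConfigDict(frozen=True)

    top: float = Field(default=100.0, gt=75.0, description="plateau viability (%)")
    hill_slope: float = Field(default=1.2, gt=0.0)
    true_cv75: Optional[float] = Field(
        default=None, gt=0.0, description="dose (µg/cm²) of the 75% crossing; None = non-cytotoxic"
    )

    def viability(self, dose: float) -> float:
        """Expected viability (%) at a dose; flat at `top` when non-cytotoxic."""
        if self.true_cv75 is None:
            return self.top
        # EC50 chosen so top / (1 + (cv75/ec50)^h) == 75 exactly
        ec50 = self.true_cv75 / (self.top / 75.0 - 1.0) ** (1.0 / self.hill_slope)
        return self.top / (1.0 + (dose / ec50) ** self.hill_slope)


class ViabilitySimConfig(BaseModel):
    """Configuration of a simulated viability plate for one chemical."""

    model_config = ConfigDict(frozen=True)

    doses: Tuple[float, ...]
    responses: Dict[str, CompartmentResponse] = Field(
        default_factory=lambda: {c: CompartmentResponse() for c in COMPARTMENTS}
    )
    noise_sd: float = Field(default=1.0, ge=0.0, description="% viability")
    n_replicates: int = Field(default=3, ge=1)
    blank_level: float = Field(default=100.0, gt=0.0)
    vehicle_level: float = Field(default=1100.0, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if len(self.doses) < 2:
            raise ConfigurationError("need at least two doses")
        if any(d <= 0 for d in self.doses):
            raise ConfigurationError("doses must be strictly positive")
        if any(b >= a for b, a in zip(self.doses, self.doses[1:])):
            raise ConfigurationError("doses must be strictly ascending")
        if self.vehicle_level <= self.blank_level:
            raise ConfigurationError("vehicle_level must exceed blank_level")
        if set(self.responses) != set(COMPARTMENTS):
            raise ConfigurationError(f"responses must cover exactly {COMPARTMENTS}")
        return self


class FlowSimConfig(BaseModel):
    """Configuration of one simulated flow-cytometry condition."""

    model_config = ConfigDict(frozen=True)

    n_events: int = Field(default=10_000, ge=1)
    baseline_mfi: Dict[str, float] = Field(
        default_factory=lambda: {"CD86": 1200.0, "CD54": 1500.0, "TSLPr": 800.0}
    )
    isotype_mfi: Dict[str, float] = Field(
        default_factory=lambda: {"CD86": 200.0, "CD54": 250.0, "TSLPr": 150.0}
    )
    induction_multiplier: Dict[str, float] = Field(
        default_factory=lambda: {m: 1.0 for m in MARKERS}
    )
    lognormal_cv: float = Field(default=0.25, gt=0.0)
    dead_fraction: float = 0.05
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ConfigurationError("dead_fraction must lie in [0, 1]")
        for m in MARKERS:
            base = self.baseline_mfi.get(m)
            iso = self.isotype_mfi.get(m)
            mult = self.induction_multiplier.get(m)
            if base is None or iso is None or mult is None:
                raise ConfigurationError(f"marker {m} missing from a per-marker field")
            if base <= 0 or iso <= 0:
                raise ConfigurationError("MFIs must be positive")
            if iso > base:
                raise ConfigurationError(f"isotype MFI must not exceed baseline ({m})")
            if mult < 0:
                raise ConfigurationError("induction_multiplier must be ≥ 0")
        return self

    def expected_rmfi(self, marker: str) -> float:
        """Closed-form expectation of the pipeline's rMFI estimate (%)."""
        return 100.0 * self.induction_multiplier[marker]


def simulate_viability_plate(config: ViabilitySimConfig, chemical: str = "sample") -> List[WellReading]:
    """Generate blank, vehicle-control and sample wells for one plate.

    Controls carry the exact configured fluorescence levels; sample wells
    get Gaussian noise on the viability scale (truncated at 0) before the
    viability is mapped back to fluorescence, so at ``noise_sd=0`` the
    normalization round-trips exactly to the configured response.
    """
    rng = np.random.default_rng(config.seed)
    span = config.vehicle_level - config.blank_level
    wells: List[WellReading] = []
    for comp in COMPARTMENTS:
        for rep in range(1, config.n_replicates + 1):
            wells.append(WellReading(compartment=comp, role="blank",
                                     raw_fluorescence=config.blank_level,
                                     replicate_id=f"r{rep}", chemical=chemical))
            wells.append(WellReading(compartment=comp, role="vehicle_control",
                                     raw_fluorescence=config.vehicle_level,
                                     replicate_id=f"r{rep}", chemical=chemical))
        resp = config.responses[comp]
        for dose in config.doses:
            v_true = resp.viability(dose)
            for rep in range(1, config.n_replicates + 1):
                v = v_true + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
                v = max(v, 0.0)
                wells.append(WellReading(
                    compartment=comp, role="sample",
                    raw_fluorescence=config.blank_level + span * v / 100.0,
                    dose=float(dose), replicate_id=f"r{rep}", chemical=chemical,
                ))
    return wells


@dataclass(frozen=True)
class FlowConditionData:
    """Simulated events for one condition plus the generative truth."""

    condition_id: str
    events: pd.DataFrame  # columns: condition_id, tube, marker, fluorescence, dead, dead_stain
    expected_rmfi: Dict[str, float]
    expected_viable_fraction: float


def _lognormal(rng: np.random.Generator, geo_mean: float, cv: float, n: int) -> np.ndarray:
    sigma = math.sqrt(math.log1p(cv * cv))
    return geo_mean * np.exp(sigma * rng.standard_normal(n))


def simulate_flow_condition(config: FlowSimConfig, condition_id: str = "sample") -> FlowConditionData:
    """Generate stained and isotype tubes for every marker of one condition."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for marker in MARKERS:
        iso = config.isotype_mfi[marker]
        stained_gm = iso + config.induction_multiplier[marker] * (config.baseline_mfi[marker] - iso)
        for tube, gm in (("stained", stained_gm), ("isotype", iso)):
            n = config.n_events
            fluor = _lognormal(rng, gm, config.lognormal_cv, n)
            dead = rng.random(n) < config.dead_fraction
            stain = np.where(
                dead,
                _lognormal(rng, DEAD_STAIN_DEAD_GM, DEAD_STAIN_CV, n),
                _lognormal(rng, DEAD_STAIN_VIABLE_GM, DEAD_STAIN_CV, n),
            )
            frames.append(pd.DataFrame({
                "condition_id": condition_id,
                "tube": tube,
                "marker": marker,
                "fluorescence": fluor,
                "dead": dead.astype(int),
                "dead_stain": stain,
            }))
    return FlowConditionData(
        condition_id=condition_id,
        events=pd.concat(frames, ignore_index=True),
        expected_rmfi={m: config.expected_rmfi(m) for m in MARKERS},
        expected_viable_fraction=1.0 - config.dead_fraction,
    )


class PanelChemical(BaseModel):
    """One chemical of a synthetic study panel with its ground-truth class."""

    model_config = ConfigDict(frozen=True)

    name: str
    respiratory_sensitizer: bool = False
    viability: ViabilitySimConfig
    flow_by_tier: Dict[str, FlowSimConfig]
    vehicle_flow: Optional[FlowSimConfig] = None

    @model_validator(mode="after")
    def _check(self):
        if set(self.flow_by_tier) != set(TIERS):
            raise ConfigurationError(f"flow_by_tier must cover exactly {TIERS}")
        return self


@dataclass(frozen=True)
class PanelBundle:
    """Full synthetic study: raw tables, metadata and generative truth."""

    wells: pd.DataFrame
    events: pd.DataFrame
    panel: List[dict]  # chemical metadata incl. condition ids and truth class
    truth: dict  # per chemical: true CV75s, expected rMFIs, substream seeds
    seed: int = 0


def _condition_id(chemical: str, tier: str) -> str:
    return f"{chemical}:{tier}"


def simulate_panel(chemicals: List[PanelChemical], seed: int = 0) -> PanelBundle:
    """Simulate a whole chemical panel from one master seed.

    Each chemical gets an independent substream (numpy ``SeedSequence.spawn``)
    from which its plate seed, per-tier flow seeds and vehicle-condition seed
    are drawn; the derived seeds are recorded in the truth sidecar. Per
    chemical the bundle holds a viability plate, one flow condition per dose
    tier, and a shared vehicle flow condition (induction 1 by construction
    unless overridden).
    """
    if not chemicals:
        raise ConfigurationError("panel must contain at least one chemical")
    names = [c.name for c in chemicals]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate chemical IDs in panel")

    master = np.random.SeedSequence(seed)
    substreams = master.spawn(len(chemicals))

    well_frames, event_frames, panel_meta, truth = [], [], [], {}
    for chem, ss in zip(chemicals, substreams):
        sub_seeds = [int(s) % (2**31) for s in ss.generate_state(4)]
        plate_seed, half_seed, cv75_seed, vehicle_seed = sub_seeds

        vconfig = chem.viability.model_copy(update={"seed": plate_seed})
        wells = simulate_viability_plate(vconfig, chemical=chem.name)
        well_frames.append(wells_to_frame(wells))

        tier_seeds = {"half_cv75": half_seed, "cv75": cv75_seed}
        conditions, expected = {}, {}
        for tier in TIERS:
            fconfig = chem.flow_by_tier[tier].model_copy(update={"seed": tier_seeds[tier]})
            cond = simulate_flow_condition(fconfig, _condition_id(chem.name, tier))
            event_frames.append(cond.events)
            conditions[tier] = cond.condition_id
            expected[tier] = {
                "rmfi": cond.expected_rmfi,
                "viable_fraction": cond.expected_viable_fraction,
            }

        base_vehicle = chem.vehicle_flow or chem.flow_by_tier["cv75"].model_copy(
            update={"induction_multiplier": {m: 1.0 for m in MARKERS}, "dead_fraction": 0.02}
        )
        vehicle = simulate_flow_condition(
            base_vehicle.model_copy(update={"seed": vehicle_seed}),
            _condition_id(chem.name, "vehicle"),
        )
        event_frames.append(vehicle.events)

        panel_meta.append({
            "chemical": chem.name,
            "respiratory_sensitizer": chem.respiratory_sensitizer,
            "max_tested_dose": max(chem.viability.doses),
            "conditions": conditions,
            "vehicle_condition": vehicle.condition_id,
        })
        truth[chem.name] = {
            "true_cv75": {c: r.true_cv75 for c, r in chem.viability.responses.items()},
            "expected": expected,
            "substream_seeds": sub_seeds,
        }

    return PanelBundle(
        wells=pd.concat(well_frames, ignore_index=True),
        events=pd.concat(event_frames, ignore_index=True),
        panel=panel_meta,
        truth=truth,
        seed=seed,
    )


def wells_to_frame(wells: List[WellReading]) -> pd.DataFrame:
    """Tabulate well readings in the pipeline's `wells.csv` column layout."""
    return pd.DataFrame({
        "chemical": [w.chemical for w in wells],
        "compartment": [w.compartment for w in wells],
        "role": [w.role for w in wells],
        "dose_ug_cm2": [w.dose if w.dose is not None else "" for w in wells],
        "replicate": [w.replicate_id for w in wells],
        "fluorescence": [w.raw_fluorescence for w in wells],
    })
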