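"""Ground-truth behaviour and determinism of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from respsens.benchmark import make_benchmark_panel
from respsens.cytometry import rmfi_from_events
from respsens.errors import ConfigurationError
from respsens.synthetic import (
    CompartmentResponse,
    FlowSimConfig,
    PanelChemical,
    ViabilitySimConfig,
    simulate_flow_condition,
    simulate_panel,
    simulate_viability_plate,
    wells_to_frame,
)
from respsens.types import COMPARTMENTS, MARKERS, TIERS
from respsens.viability import build_dose_response
from respsens.types import AVERAGE_CURVE


def viability_config(**kw):
    defaults = dict(
        doses=(5.0, 10.0, 20.0, 40.0, 80.0, 160.0),
        responses={c: CompartmentResponse(true_cv75=30.0) for c in COMPARTMENTS},
        noise_sd=0.0,
        seed=7,
    )
    defaults.update(kw)
    return ViabilitySimConfig(**defaults)


class TestViabilitySimulator:
    def test_noise_free_curve_crosses_75_at_true_cv75(self):
        config = viability_config(doses=(5.0, 10.0, 30.0, 80.0, 160.0))  # includes CV75
        curves = build_dose_response(simulate_viability_plate(config))
        at_cv75 = [p for p in curves[AVERAGE_CURVE] if p.dose == 30.0]
        assert at_cv75[0].viability == pytest.approx(75.0, abs=1e-9)

    def test_low_dose_limit_approaches_top(self):
        resp = CompartmentResponse(top=100.0, true_cv75=30.0)
        assert resp.viability(1e-6) == pytest.approx(100.0, abs=1e-3)

    def test_expected_curve_monotone_non_increasing(self):
        resp = CompartmentResponse(top=98.0, hill_slope=2.0, true_cv75=12.0)
        doses = np.geomspace(0.1, 1000, 50)
        vs = [resp.viability(d) for d in doses]
        assert all(b <= a + 1e-12 for a, b in zip(vs, vs[1:]))

    def test_non_cytotoxic_curve_is_flat(self):
        resp = CompartmentResponse(true_cv75=None)
        assert resp.viability(750.0) == resp.viability(1.0) == 100.0

    def test_seed_determinism_bit_for_bit(self):
        config = viability_config(noise_sd=2.0)
        a = wells_to_frame(simulate_viability_plate(config)).to_csv(index=False)
        b = wells_to_frame(simulate_viability_plate(config)).to_csv(index=False)
        assert a == b

    @pytest.mark.parametrize("kw", [
        dict(doses=(10.0, 5.0, 20.0, 40.0, 80.0, 160.0)),  # non-ascending
        dict(doses=(5.0, 10.0, 20.0, 40.0, 80.0, -1.0)),
        dict(blank_level=1100.0, vehicle_level=1100.0),  # vehicle must exceed blank
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises((ConfigurationError, Exception)):
            viability_config(**kw)


class TestFlowSimulator:
    def test_identity_induction_gives_100_percent(self):
        sample = simulate_flow_condition(FlowSimConfig(seed=21))
        vehicle = simulate_flow_condition(FlowSimConfig(seed=22))
        for marker in MARKERS:
            result, _ = rmfi_from_events(sample.events, vehicle.events, marker)
            assert result.rmfi == pytest.approx(100.0, abs=5.0)

    def test_truth_metadata_matches_closed_form(self):
        config = FlowSimConfig(induction_multiplier={"CD86": 1.0, "CD54": 1.5, "TSLPr": 2.0})
        cond = simulate_flow_condition(config)
        assert cond.expected_rmfi == {"CD86": 100.0, "CD54": 150.0, "TSLPr": 200.0}
        assert cond.expected_viable_fraction == pytest.approx(0.95)

    def test_viable_fraction_converges_with_events(self):
        cond = simulate_flow_condition(FlowSimConfig(n_events=40_000, dead_fraction=0.2, seed=5))
        stained = cond.events[(cond.events.tube == "stained") & (cond.events.marker == "CD86")]
        assert 1.0 - stained["dead"].mean() == pytest.approx(0.8, abs=0.01)

    def test_dead_fraction_bounds_enforced(self):
        with pytest.raises((ConfigurationError, Exception)):
            FlowSimConfig(dead_fraction=1.5)

    def test_isotype_above_baseline_rejected(self):
        with pytest.raises((ConfigurationError, Exception)):
            FlowSimConfig(isotype_mfi={"CD86": 5000.0, "CD54": 250.0, "TSLPr": 150.0})

    def test_seed_determinism(self):
        a = simulate_flow_condition(FlowSimConfig(seed=7)).events
        b = simulate_flow_condition(FlowSimConfig(seed=7)).events
        pd.testing.assert_frame_equal(a, b)


def tiny_chemical(name, tslpr_mult=1.0, n_events=1500):
    mult = {m: 1.0 for m in MARKERS}
    mult["TSLPr"] = tslpr_mult
    return PanelChemical(
        name=name,
        viability=viability_config(noise_sd=1.0),
        flow_by_tier={t: FlowSimConfig(n_events=n_events, induction_multiplier=mult)
                      for t in TIERS},
    )


class TestPanelSimulator:
    def test_duplicate_chemical_ids_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            simulate_panel([tiny_chemical("a"), tiny_chemical("a")])

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_panel([])

    def test_master_seed_spawns_recorded_substreams(self):
        bundle = simulate_panel([tiny_chemical("a"), tiny_chemical("b")], seed=3)
        seeds_a = bundle.truth["a"]["substream_seeds"]
        seeds_b = bundle.truth["b"]["substream_seeds"]
        assert len(seeds_a) == 4 and seeds_a != seeds_b
        assert all(0 <= s < 2**31 for s in seeds_a + seeds_b)

    def test_single_inducer_yields_one_positive_at_150(self):
        chemicals = [tiny_chemical(f"c{i}") for i in range(13)]
        chemicals.append(tiny_chemical("inducer", tslpr_mult=4.0))
        bundle = simulate_panel(chemicals, seed=11)
        by_condition = dict(tuple(bundle.events.groupby("condition_id")))
        for tier in TIERS:
            positive = []
            for entry in bundle.panel:
                sample = by_condition[entry["conditions"][tier]]
                vehicle = by_condition[entry["vehicle_condition"]]
                result, _ = rmfi_from_events(sample, vehicle, "TSLPr")
                if result.evaluable and result.rmfi >= 150.0:
                    positive.append(entry["chemical"])
            assert positive == ["inducer"]

    def test_benchmark_panel_shape(self):
        panel = make_benchmark_panel()
        assert len(panel) == 14
        assert sum(1 for c in panel if c.viability.responses["apical"].true_cv75 is None) == 1
        assert all(not c.respiratory_sensitizer for c in panel)
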