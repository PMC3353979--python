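"""Demographic model loading, time bookkeeping and size/migration schedules."""

import math

import numpy as np
import pytest
import yaml

from paleosweep.demography import (
    DemographicEvent,
    DemographicModel,
    ModelValidationError,
    constant_size_model,
    load_model,
    migration_schedule,
    population_size_at,
    scaled_to_generations,
    size_schedule,
)


def test_minimal_constant_model():
    m = load_model({"N0": 500, "t_end": 0.1, "populations": ["POP"]})
    assert m.n_generations == 100
    assert population_size_at(m, "POP", 0.05) == 500


@pytest.mark.parametrize(
    "t, expected", [(0.607, 607), (0.0, 0), (0.211074, 211), (0.5895, 590)]
)
def test_scaled_time_to_generations(ooa_model, t, expected):
    assert scaled_to_generations(ooa_model, t) == expected


def test_scaled_time_out_of_range(ooa_model):
    with pytest.raises(ValueError):
        scaled_to_generations(ooa_model, -0.01)
    with pytest.raises(ValueError):
        scaled_to_generations(ooa_model, 0.7)


class TestPackagedModel:
    def test_structure(self, ooa_model):
        assert ooa_model.populations == ("AFR", "EUR", "ASN")
        assert ooa_model.N0 == 500 and ooa_model.t_end == 0.607
        assert ooa_model.founding_time("EUR") == 0.211074
        assert ooa_model.founding_time("ASN") == 0.534772
        assert ooa_model.split_parent("ASN") == "EUR"
        assert "eur_7kybp" in ooa_model.record_times

    @pytest.mark.parametrize(
        "pop, t, expected",
        [
            ("AFR", 0.0, 50),          # 500 x 0.1
            ("AFR", 0.004, 500),       # x 10
            ("AFR", 0.006, 841),       # x 1.68202
            ("AFR", 0.6, 841),         # constant thereafter
            ("EUR", 0.211074, 144),    # 841 x 0.170737565 bottleneck
            ("EUR", 0.534772, 104),    # x 0.724763218
            ("ASN", 0.534772, 23),     # 143.6 x 0.162342748 (pre-bottleneck parent)
        ],
    )
    def test_derived_population_sizes(self, ooa_model, pop, t, expected):
        assert population_size_at(ooa_model, pop, t) == expected

    def test_growth_after_second_split(self, ooa_model):
        n_eur = population_size_at(ooa_model, "EUR", 0.607)
        assert n_eur == round(104.07 * math.exp(33.98 * (0.607 - 0.534772)))

    def test_unfounded_population_errors(self, ooa_model):
        with pytest.raises(ValueError):
            population_size_at(ooa_model, "EUR", 0.1)

    def test_migration_values_decode_to_symmetric_rates(self, ooa_model):
        mig = migration_schedule(ooa_model)
        # first epoch: AFR<->EUR per-generation fractions are equal
        assert mig[300, 0, 1] == pytest.approx(mig[300, 1, 0], rel=1e-4)
        assert mig[300, 0, 1] == pytest.approx(3.6465e-3, rel=1e-3)
        # second epoch: AFR<->EUR and AFR<->ASN each symmetric
        assert mig[540, 0, 1] == pytest.approx(mig[540, 1, 0], rel=1e-3)
        assert mig[540, 0, 2] == pytest.approx(mig[540, 2, 0], rel=1e-3)
        # African migration shut off at 0.54805
        assert np.all(mig[550, 0, :] == 0) and np.all(mig[550, :, 0] == 0)
        assert mig[550, 1, 2] > 0

    def test_size_schedule_matches_pointwise_sizes(self, ooa_model):
        sizes = size_schedule(ooa_model)
        assert sizes.shape == (608, 3)
        assert sizes[0, 0] == 50 and sizes[606, 0] == 841
        assert sizes[210, 1] == 0 and sizes[211, 1] == 144
        # generation 535 sits at t=0.535, a hair past the split, so the
        # founding size 23 already carries a sliver of exponential growth
        assert sizes[534, 2] == 0 and sizes[535, 2] == 24
        assert np.all(sizes[sizes > 0] >= 2)


class TestValidation:
    def test_event_after_t_end_rejected(self):
        with pytest.raises(ModelValidationError, match="after t_end"):
            load_model({
                "N0": 500, "t_end": 0.1, "populations": ["A"],
                "events": [{"time": 0.2, "kind": "size_change", "pop": "A", "value": 2.0}],
            })

    def test_unknown_population_rejected(self):
        with pytest.raises(ModelValidationError, match="unknown population"):
            load_model({
                "N0": 500, "t_end": 0.1, "populations": ["A"],
                "events": [{"time": 0.05, "kind": "size_change", "pop": "B", "value": 2.0}],
            })

    def test_event_before_founding_rejected(self):
        with pytest.raises(ModelValidationError, match="before it exists"):
            load_model({
                "N0": 500, "t_end": 0.2, "populations": ["A", "B"],
                "events": [
                    {"time": 0.1, "kind": "split", "pop": "A", "daughter": "B"},
                    {"time": 0.05, "kind": "size_change", "pop": "B", "value": 2.0},
                ],
            })

    def test_negative_rate_and_missing_fields_rejected(self):
        with pytest.raises(ModelValidationError):
            DemographicEvent(time=0.1, kind="migration_change", pop="A",
                             source="B", value=-0.5)
        with pytest.raises(ModelValidationError, match="missing required"):
            load_model({"N0": 500, "populations": ["A"]})

    def test_events_are_time_sorted_on_load(self):
        m = load_model({
            "N0": 100, "t_end": 0.5, "populations": ["A"],
            "events": [
                {"time": 0.3, "kind": "size_change", "pop": "A", "value": 2.0},
                {"time": 0.1, "kind": "size_change", "pop": "A", "value": 0.5},
            ],
        })
        assert [e.time for e in m.events] == [0.1, 0.3]


def test_yaml_round_trip(tmp_path, ooa_model):
    path = tmp_path / "model.yaml"
    ooa_model.to_yaml(path)
    reloaded = load_model(path)
    assert reloaded.to_dict() == ooa_model.to_dict()


def test_constant_size_model_helper():
    m = constant_size_model(500, 1000)
    assert m.n_generations == 1000
    assert population_size_at(m, "POP", m.t_end) == 500


def test_years_bp_conversion(ooa_model):
    # the out-of-Africa split lands near 145 ka under kappa=14.62, 25 y/gen
    years = ooa_model.scaled_time_to_years_bp(0.211074)
    assert years == pytest.approx(145_000, rel=0.01)
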