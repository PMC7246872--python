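"""Zone insulation calculus and aggregation to regions and whole body."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatstrain.fixtures import load_fixture
from heatstrain.manikin import (
    DEFAULT_AREA_TABLE,
    ManikinValidationError,
    ZoneAreaTable,
    ZoneRecord,
    aggregate,
    aggregate_excluding,
    average_replicates,
    build_insulation_table,
    dynamic_comparison,
    zone_insulation,
)
from heatstrain.synthetic import (
    DEFAULT_ZONE_TRUTHS,
    SyntheticSpec,
    generate_zone_dataset,
)

insulations = st.floats(0.02, 0.5)
areas = st.floats(0.01, 0.3)
zone_sets = st.lists(st.tuples(insulations, areas), min_size=1, max_size=20)


def rec(zone="Chest", dt=14.0, q=140.0, **kw):
    return ZoneRecord(
        zone_id=zone, area=0.17, t_surface=20.0 + dt, t_ambient=20.0, q=q, **kw
    )


class TestZoneInsulation:
    @pytest.mark.parametrize(
        "dt, q, expected",
        [(14.0, 142.9, 14.0 / 142.9), (14.0, 140.0, 0.1000)],
    )
    def test_definition(self, dt, q, expected):
        assert zone_insulation(rec(dt=dt, q=q)) == pytest.approx(expected)

    def test_whole_body_air_layer_magnitude(self):
        # at the lab gradient the nude whole-body value ~0.098 m2K/W implies
        # a heat loss near 143 W/m2
        assert zone_insulation(rec(dt=14.0, q=142.9)) == pytest.approx(
            0.098, abs=0.0002
        )

    @pytest.mark.parametrize("q, dt", [(0.0, 14.0), (-5.0, 14.0), (140.0, -1.0)])
    def test_degenerate_inputs_rejected(self, q, dt):
        with pytest.raises(ManikinValidationError, match="Chest"):
            zone_insulation(rec(dt=dt, q=q))


class TestAggregate:
    def test_identical_zones_are_a_fixed_point(self):
        zones = [(0.1, 0.2), (0.1, 0.3)]
        assert aggregate(zones, "parallel") == pytest.approx(0.1)
        assert aggregate(zones, "serial") == pytest.approx(0.1)

    def test_two_zone_closed_forms(self):
        zones = [(0.1, 0.1), (0.2, 0.1)]
        assert aggregate(zones, "parallel") == pytest.approx(2 / 15)
        assert aggregate(zones, "serial") == pytest.approx(0.15)

    def test_seventeen_zone_recovery_against_heat_loss_sum(self):
        """Parallel aggregation equals summing heat losses at a common dT."""
        dt = 14.0
        zones = [
            (ins, DEFAULT_AREA_TABLE.areas[z])
            for z, ins in DEFAULT_ZONE_TRUTHS.items()
        ]
        total_area = sum(a for _, a in zones)
        q_total = sum(dt / ins * a for ins, a in zones) / total_area
        oracle = dt / q_total
        assert aggregate(zones, "parallel") == pytest.approx(oracle, rel=1e-12)

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ManikinValidationError):
            aggregate([])
        with pytest.raises(ManikinValidationError):
            aggregate([(0.1, 0.1)], method="nonsense")
        with pytest.raises(ManikinValidationError):
            aggregate([(-0.1, 0.1)])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(zone_sets)
    def test_parallel_never_exceeds_serial(self, zones):
        par = aggregate(zones, "parallel")
        ser = aggregate(zones, "serial")
        assert par <= ser * (1 + 1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(zone_sets)
    def test_order_invariance(self, zones):
        for method in ("parallel", "serial"):
            assert aggregate(zones, method) == pytest.approx(
                aggregate(zones[::-1], method), rel=1e-12
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(zone_sets, st.floats(0.1, 0.9))
    def test_splitting_a_zone_is_neutral(self, zones, frac):
        """A zone split into two sub-zones of equal insulation and summed
        area leaves the aggregate unchanged."""
        ins0, area0 = zones[0]
        split = [(ins0, area0 * frac), (ins0, area0 * (1 - frac))] + zones[1:]
        for method in ("parallel", "serial"):
            assert aggregate(split, method) == pytest.approx(
                aggregate(zones, method), rel=1e-9
            )


class TestAggregateExcluding:
    ZONES = {
        "Head": (0.17, 0.13),
        "Chest": (0.10, 0.17),
        "L.Hand": (0.11, 0.045),
    }

    def test_empty_exclusion_equals_full_aggregate(self):
        assert aggregate_excluding(self.ZONES, set()) == pytest.approx(
            aggregate(list(self.ZONES.values()))
        )

    def test_uniform_zones_unchanged_by_any_exclusion(self):
        uniform = {z: (0.1, a) for z, (_, a) in self.ZONES.items()}
        assert aggregate_excluding(uniform, {"Head"}) == pytest.approx(0.1)

    def test_removing_extreme_zone_moves_total_toward_rest(self):
        zones = {"A": (0.1, 0.1), "B": (0.1, 0.1), "X": (0.5, 0.1)}
        full = aggregate(list(zones.values()))
        trimmed = aggregate_excluding(zones, {"X"})
        oracle = aggregate([zones["A"], zones["B"]])
        assert trimmed == pytest.approx(oracle, rel=1e-12)
        assert trimmed < full

    def test_unknown_zone_and_empty_remainder_rejected(self):
        with pytest.raises(ManikinValidationError):
            aggregate_excluding(self.ZONES, {"Tail"})
        with pytest.raises(ManikinValidationError):
            aggregate_excluding(self.ZONES, set(self.ZONES))


class TestDynamicComparison:
    def test_published_whole_body_values(self):
        # chemical sprayer whole body
        ratio, diff = dynamic_comparison(0.257, 0.188)
        assert round(diff, 1) == -26.8
        assert round(ratio, 2) == 0.73
        # sugarcane cutter whole body
        ratio, _ = dynamic_comparison(0.191, 0.143)
        assert round(ratio, 2) == 0.75

    def test_identity(self):
        ratio, diff = dynamic_comparison(0.2, 0.2)
        assert ratio == pytest.approx(1.0)
        assert diff == pytest.approx(0.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ManikinValidationError):
            dynamic_comparison(0.0, 0.1)

    def test_published_table_ratios_consistent(self):
        """Ratios recomputed from the printed insulation pairs agree with
        the printed ratios to the printed precision (one unit in the last
        decimal allowed for the laboratory's unrounded sources)."""
        t2 = load_fixture("table2")
        for col in ("SC", "CP"):
            ratio = t2[f"{col}_I_Tr"] / t2[f"{col}_I_T"]
            assert (ratio - t2[f"{col}_ratio"]).abs().max() <= 0.011


class TestReplicatesAndTable:
    def zero_noise_records(self):
        return generate_zone_dataset(SyntheticSpec(seed=3, noise_sd=0.0))

    def test_duplicating_every_record_changes_nothing(self):
        records = self.zero_noise_records()
        t1 = build_insulation_table(records, layer="nude_air_layer")
        t2 = build_insulation_table(records + records, layer="nude_air_layer")
        assert t1.equals(t2)

    def test_replicates_disagreeing_on_area_rejected(self):
        records = [rec(replicate=1), rec(replicate=2)]
        object.__setattr__(records[1], "area", 0.2)
        with pytest.raises(ManikinValidationError, match="area"):
            average_replicates(records)

    def test_zero_noise_table_recovers_truths(self):
        table = build_insulation_table(
            self.zero_noise_records(), layer="nude_air_layer"
        )
        zones = table[table.kind == "zone"].set_index("label")
        for zone, truth in DEFAULT_ZONE_TRUTHS.items():
            assert zones.loc[zone, "I_T"] == pytest.approx(truth, rel=1e-9)

    @pytest.mark.parametrize("truth", [0.05, 0.1, 0.2, 0.4])
    def test_whole_body_recovery_over_truth_grid(self, truth):
        spec = SyntheticSpec(
            seed=0,
            zone_truths={z: truth for z in DEFAULT_ZONE_TRUTHS},
            dynamic_ratios={z: 0.8 for z in DEFAULT_ZONE_TRUTHS},
            noise_sd=0.0,
        )
        table = build_insulation_table(
            generate_zone_dataset(spec), layer="nude_air_layer"
        )
        total = table[table.label == "Total"].iloc[0]
        assert total.I_T == pytest.approx(truth, rel=1e-9)
        assert total.I_Tr == pytest.approx(0.8 * truth, rel=1e-9)

    def test_noisy_recovery_within_sampling_error(self):
        """With 2% multiplicative noise and two replicates the recovered
        whole-body total stays within 3 sigma/sqrt(n) of truth on average."""
        truth = 0.1
        sd = 0.02
        errs = []
        for seed in range(100):
            spec = SyntheticSpec(
                seed=seed,
                zone_truths={z: truth for z in DEFAULT_ZONE_TRUTHS},
                dynamic_ratios={z: 0.8 for z in DEFAULT_ZONE_TRUTHS},
                noise_sd=sd,
            )
            table = build_insulation_table(
                generate_zone_dataset(spec), layer="nude_air_layer"
            )
            errs.append(
                float(table[table.label == "Total"].iloc[0].I_T) - truth
            )
        n_measurements = 2 * len(DEFAULT_ZONE_TRUTHS)
        assert abs(sum(errs) / len(errs)) < 3 * sd * truth / math.sqrt(
            n_measurements
        )

    def test_missing_condition_listed_in_error(self):
        records = [r for r in self.zero_noise_records()
                   if not (r.zone_id == "Head" and r.condition == "dynamic")]
        with pytest.raises(ManikinValidationError, match="Head"):
            build_insulation_table(records, layer="nude_air_layer")

    def test_single_zone_total_equals_zone(self):
        records = [
            rec(zone="Chest", q=140.0, condition="static"),
            rec(zone="Chest", q=175.0, condition="dynamic"),
        ]
        table = build_insulation_table(records)
        zone_row = table[table.kind == "zone"].iloc[0]
        total_row = table[table.label == "Total"].iloc[0]
        assert total_row.I_T == pytest.approx(zone_row.I_T)
        assert total_row.I_Tr == pytest.approx(zone_row.I_Tr)

    def test_rows_sorted_by_percentage_difference(self):
        table = build_insulation_table(
            self.zero_noise_records(), layer="nude_air_layer"
        )
        diffs = table.diff_pct.to_list()
        assert diffs == sorted(diffs)


def test_area_table_invariants():
    assert DEFAULT_AREA_TABLE.total_area == pytest.approx(
        sum(DEFAULT_AREA_TABLE.areas.values()), rel=1e-9
    )
    with pytest.raises(ManikinValidationError):
        ZoneAreaTable(areas={"A": 0.1}, regions={"R": frozenset({"B"})})
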