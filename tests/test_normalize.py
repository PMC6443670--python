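"""Batch normalization, axis placement, filtering rules, population means."""

import numpy as np
import pytest

from dvscale.hill import HillParams, hill_eval
from dvscale.margin import BIN_CENTERS_DEG, MarginProfile
from dvscale.normalize import (
    RejectionReason,
    batch_normalize,
    filter_embryos,
    node_values,
    population_mean,
)

XI = BIN_CENTERS_DEG / 180.0


def make_profile(eid, group="WT", batch="b0", L=1000.0, scale=1.0, shape=None):
    if shape is None:
        shape = hill_eval(HillParams(1.0, 0.35, 5.0), XI)
    return MarginProfile(
        embryo_id=eid,
        group=group,
        batch=batch,
        L=L,
        bin_mean_intensity=np.asarray(shape, float) * scale,
        bin_cell_count=np.full(18, 30),
    )


class TestBatchNormalize:
    def test_two_batches_control_peaks_set_to_one(self):
        profiles = [
            make_profile("a1", batch="day1", scale=100.0),
            make_profile("a2", batch="day2", scale=200.0),
            make_profile("b1", group="Cut", batch="day1", scale=80.0),
            make_profile("b2", group="Cut", batch="day2", scale=160.0),
        ]
        normed = batch_normalize(profiles, control_group="WT")
        by_id = {p.embryo_id: p for p in normed}
        assert by_id["a1"].peak == pytest.approx(1.0)
        assert by_id["a2"].peak == pytest.approx(1.0)
        # batch differences removed: Cut embryos land on one scale
        np.testing.assert_allclose(
            by_id["b1"].norm_intensity, by_id["b2"].norm_intensity
        )
        ctrl = np.mean(
            [by_id["a1"].norm_intensity, by_id["a2"].norm_intensity], axis=0
        )
        assert np.nanmax(ctrl) == pytest.approx(1.0)

    def test_single_batch_reduces_to_population_peak_division(self):
        profiles = [
            make_profile("e1", scale=2.0),
            make_profile("e2", scale=4.0),
        ]
        normed = batch_normalize(profiles, control_group="WT")
        pop_avg = np.mean([p.norm_intensity for p in normed], axis=0)
        assert np.nanmax(pop_avg) == pytest.approx(1.0)
        # shapes preserved up to one common factor
        ratio = normed[1].norm_intensity / normed[0].norm_intensity
        np.testing.assert_allclose(ratio, 2.0)

    def test_global_rescaling_invariance(self):
        profiles = [make_profile("e1", scale=1.0), make_profile("e2", scale=3.0)]
        scaled = [
            make_profile("e1", scale=7.0),
            make_profile("e2", scale=21.0),
        ]
        n1 = batch_normalize(profiles, control_group="WT")
        n2 = batch_normalize(scaled, control_group="WT")
        for p1, p2 in zip(n1, n2):
            np.testing.assert_allclose(p1.norm_intensity, p2.norm_intensity)

    def test_self_normalization_without_controls(self):
        """A lone population (no control group present) normalizes itself."""
        profiles = [
            make_profile("g1", group="Gd", scale=5.0),
            make_profile("g2", group="Gd", scale=6.0),
        ]
        normed = batch_normalize(profiles, control_group="Tu")
        pop_avg = np.mean([p.norm_intensity for p in normed], axis=0)
        assert np.nanmax(pop_avg) == pytest.approx(1.0)

    def test_missing_batch_controls_is_an_error(self):
        profiles = [
            make_profile("a1", batch="day1"),
            make_profile("b2", group="Cut", batch="day2"),
        ]
        with pytest.raises(ValueError, match="day2"):
            batch_normalize(profiles, control_group="WT")

    def test_axis_placement(self):
        profiles = [
            make_profile("e1", L=800.0),
            make_profile("e2", L=1000.0),
        ]
        normed = batch_normalize(profiles, control_group="WT")
        by_id = {p.embryo_id: p for p in normed}
        np.testing.assert_allclose(by_id["e2"].xrel, by_id["e2"].xi)
        np.testing.assert_allclose(by_id["e1"].xrel, by_id["e1"].xi * 0.8)


class TestFilterEmbryos:
    def _normed(self, specs):
        """specs: list of (eid, peak, vd_style) built as synthetic profiles."""
        profiles = []
        for eid, scale, flat in specs:
            shape = (
                np.full(18, 1.0)
                if flat
                else hill_eval(HillParams(1.0, 0.35, 5.0), XI)
            )
            profiles.append(
                make_profile(eid, group="Cut", scale=scale, shape=shape)
            )
        # anchor normalization with controls at peak 1
        profiles.append(make_profile("w1"))
        profiles.append(make_profile("w2"))
        return batch_normalize(profiles, control_group="WT")

    def test_rule_examples(self):
        """Peak 1.50 → rejected; flat gradient → rejected; normal → kept."""
        normed = self._normed(
            [("hot", 1.50, False), ("flat", 1.0, True), ("ok", 1.0, False)]
        )
        flt = {
            p.embryo_id: p
            for p in filter_embryos(normed, control_group="WT")
        }
        assert flt["hot"].rejection_reason == RejectionReason.PEAK_OUT_OF_RANGE
        assert not flt["hot"].retained
        assert flt["flat"].rejection_reason == RejectionReason.GRADIENT_TOO_FLAT
        assert flt["ok"].retained
        assert flt["ok"].rejection_reason == RejectionReason.NONE

    def test_controls_never_filtered(self):
        normed = self._normed([("hot", 1.50, False)])
        flt = filter_embryos(normed, control_group="WT")
        assert all(p.retained for p in flt if p.group == "WT")

    def test_constructed_rejection_fraction(self):
        """With 60% flat-gradient embryos built in, ~40% are retained."""
        specs = [(f"f{i}", 1.0, True) for i in range(12)]
        specs += [(f"g{i}", 1.0, False) for i in range(8)]
        normed = self._normed(specs)
        flt = [p for p in filter_embryos(normed, control_group="WT")
               if p.group == "Cut"]
        assert sum(p.retained for p in flt) == 8

    def test_idempotent_and_order_independent(self):
        normed = self._normed(
            [("hot", 1.50, False), ("flat", 1.0, True), ("ok", 1.0, False)]
        )
        once = filter_embryos(normed, control_group="WT")
        twice = filter_embryos(once, control_group="WT")
        assert [(p.embryo_id, p.retained) for p in once] == [
            (p.embryo_id, p.retained) for p in twice
        ]
        reversed_in = filter_embryos(normed[::-1], control_group="WT")
        flags = {p.embryo_id: p.retained for p in once}
        assert all(flags[p.embryo_id] == p.retained for p in reversed_in)


class TestPopulationMean:
    def test_identical_profiles_zero_spread(self):
        normed = batch_normalize(
            [make_profile("e1"), make_profile("e2")], control_group="WT"
        )
        pop = population_mean(normed, axis="scaled")
        np.testing.assert_allclose(pop.node_mean, normed[0].norm_intensity)
        np.testing.assert_allclose(pop.node_spread, 0.0, atol=1e-12)
        assert np.all(pop.node_n == 2)

    def test_relative_axis_of_largest_embryo_matches_scaled(self):
        normed = batch_normalize(
            [make_profile("big", L=1000.0), make_profile("small", L=700.0)],
            control_group="WT",
        )
        _, vals = node_values(
            [p for p in normed if p.embryo_id == "big"], axis="relative"
        )
        big = next(p for p in normed if p.embryo_id == "big")
        np.testing.assert_allclose(vals[0], big.norm_intensity)

    def test_small_embryo_occupies_lower_relative_nodes(self):
        normed = batch_normalize(
            [make_profile("big", L=1000.0), make_profile("small", L=500.0)],
            control_group="WT",
        )
        _, vals = node_values(
            [p for p in normed if p.embryo_id == "small"], axis="relative"
        )
        assert np.isnan(vals[0][-4:]).all()  # cannot reach the far nodes
        assert np.isfinite(vals[0][:9]).all()

    def test_requires_two_retained(self):
        normed = batch_normalize([make_profile("e1"), make_profile("e2")],
                                 control_group="WT")
        with pytest.raises(ValueError):
            population_mean(normed[:1], axis="scaled")
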