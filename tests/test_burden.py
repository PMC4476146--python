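"""Burden metrics: Fc, Td, divisions, volumes, and clone phenotypes."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from livermet import (
    Colony,
    GrowthScenario,
    LiverBurden,
    classify_phenotype,
    clone_phenotype,
    colonizing_fraction,
    colony_cells,
    doubling_time,
    n_divisions,
    sphere_volume,
    total_burden,
)
from livermet.burden import ClonePhenotype
from livermet.errors import (
    InconsistentBurdenError,
    ModalityMismatchError,
    UndefinedDoublingTimeError,
)


class TestColonizingFraction:
    @pytest.mark.parametrize(
        "n_tumors,n_injected,fc",
        [
            (0, 2_000_000, 0.0),
            (164, 2_000_000, 8.2e-5),
            (12, 2_000_000, 6.0e-6),
            (22, 2_000_000, 1.1e-5),
        ],
    )
    def test_known_ratios(self, n_tumors, n_injected, fc):
        assert colonizing_fraction(n_tumors, n_injected) == pytest.approx(fc)

    def test_more_tumors_than_cells_is_inconsistent(self):
        with pytest.raises(InconsistentBurdenError):
            colonizing_fraction(11, 10)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            colonizing_fraction(1, 0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        k=st.integers(0, 99), n=st.integers(200, 10**6), scale=st.integers(2, 50)
    )
    def test_monotone_and_scale_invariant(self, k, n, scale):
        assert colonizing_fraction(k, n) <= colonizing_fraction(k + 1, n)
        assert colonizing_fraction(k * scale, n * scale) == pytest.approx(
            colonizing_fraction(k, n)
        )


class TestGrowthModel:
    @pytest.mark.parametrize(
        "cells,elapsed,td",
        [
            (1024, 240.0, 24.0),
            (2, 17.0, 17.0),
            (4.31e7, 672.0, 26.5),  # polymetastatic P1-like colony
            (4.82e6, 504.0, 22.7),  # fast-growing P2-like colony
        ],
    )
    def test_doubling_time_examples(self, cells, elapsed, td):
        assert doubling_time(cells, elapsed) == pytest.approx(td, abs=0.1)

    def test_sub_two_cell_colony_has_undefined_td(self):
        with pytest.raises(UndefinedDoublingTimeError):
            doubling_time(1.5, 100.0)

    @pytest.mark.parametrize(
        "cells,divisions", [(1, 0.0), (1024, 10.0), (4.31e7, 25.36)]
    )
    def test_n_divisions(self, cells, divisions):
        assert n_divisions(cells) == pytest.approx(divisions, abs=0.01)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(k=st.integers(1, 40), tau=st.floats(1.0, 100.0))
    def test_k_doublings_in_k_tau_hours(self, k, tau):
        assert doubling_time(2.0**k, k * tau) == pytest.approx(tau, rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(cells=st.floats(2.0, 1e9), t=st.floats(1.0, 1e4))
    def test_divisions_times_td_equals_elapsed(self, cells, t):
        assert n_divisions(cells) * doubling_time(cells, t) == pytest.approx(
            t, rel=1e-12
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(cells=st.floats(2.0, 1e9), t=st.floats(1.0, 1e4), f=st.floats(1.1, 10.0))
    def test_td_monotonicity(self, cells, t, f):
        assert doubling_time(cells * f, t) < doubling_time(cells, t)
        assert doubling_time(cells, t * f) > doubling_time(cells, t)


class TestVolumes:
    @pytest.mark.parametrize(
        "diameter,volume",
        [(2.0, 4.18879), (1.0, 0.523599), (3.7, 26.522)],
    )
    def test_sphere_volume(self, diameter, volume):
        assert sphere_volume(diameter) == pytest.approx(volume, abs=1e-3)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            sphere_volume(0.0)

    def test_total_burden_sums_and_counts(self):
        empty = LiverBurden("m1", "P1", 100, 504.0, ())
        assert total_burden(empty) == (0.0, 0.0, 0)
        two = LiverBurden(
            "m2", "P1", 100, 504.0,
            (Colony(fluor_signal=10.0, diameter_mm=1.0),
             Colony(fluor_signal=20.0, diameter_mm=2.0)),
        )
        tv, tf, n = total_burden(two)
        assert tv == pytest.approx(4.71239, abs=1e-4)
        assert tf == pytest.approx(30.0)
        assert n == 2

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.data())
    def test_total_burden_permutation_invariant_and_additive(self, data):
        colony = st.builds(
            Colony,
            fluor_signal=st.floats(0.0, 1e6),
            diameter_mm=st.floats(0.1, 10.0),
        )
        a = data.draw(st.lists(colony, min_size=0, max_size=8))
        b = data.draw(st.lists(colony, min_size=0, max_size=8))
        perm = data.draw(st.permutations(a))
        mk = lambda cols: LiverBurden("m", "c", 10**6, 100.0, tuple(cols))
        assert total_burden(mk(perm)) == pytest.approx(total_burden(mk(a)))
        joint = total_burden(mk(a + b))
        ta, tb = total_burden(mk(a)), total_burden(mk(b))
        assert joint.total_volume == pytest.approx(ta.total_volume + tb.total_volume)
        assert joint.total_fluor == pytest.approx(ta.total_fluor + tb.total_fluor)
        assert joint.n_tumors == ta.n_tumors + tb.n_tumors


class TestColonyCells:
    def test_inversion_through_curve(self, exact_fluor_curve, offset_fluor_curve):
        c = colony_cells(exact_fluor_curve, Colony(fluor_signal=1e6))
        assert c.cell_count == pytest.approx(1e4)
        c = colony_cells(offset_fluor_curve, Colony(fluor_signal=10_500.0))
        assert c.cell_count == pytest.approx(40.0)

    def test_signal_at_background_floors_to_one_cell(self, offset_fluor_curve):
        c = colony_cells(offset_fluor_curve, Colony(fluor_signal=500.0))
        assert c.cell_count == 1.0

    def test_luminescence_curve_rejected(self, lum_curve):
        with pytest.raises(ModalityMismatchError):
            colony_cells(lum_curve, Colony(fluor_signal=100.0))


def _burden(mouse, counts_cells, harvest=240.0, dose=2_000_000, clone="P1",
            signal_per_cell=100.0):
    colonies = tuple(
        Colony(fluor_signal=n * signal_per_cell, cell_count=None)
        for n in counts_cells
    )
    return LiverBurden(mouse, clone, dose, harvest, colonies)


class TestClonePhenotype:
    def test_constructed_counts_reproduce_polymetastatic_fc(self, exact_fluor_curve):
        burdens = [
            _burden(f"m{i}", [1024.0] * k)
            for i, k in enumerate((158, 170, 164))
        ]
        ph = clone_phenotype(burdens, exact_fluor_curve, seed=0)
        assert ph.fc_mean == pytest.approx(8.2e-5)
        assert ph.n_mice == 3

    def test_single_colony_phenotype(self, exact_fluor_curve):
        ph = clone_phenotype([_burden("m1", [1024.0])], exact_fluor_curve)
        assert ph.td_mean == pytest.approx(24.0)
        assert math.isnan(ph.td_sd)  # n = 1
        assert ph.n_av == pytest.approx(1024.0)
        assert ph.divisions_mean == pytest.approx(10.0)

    def test_identical_mice_have_zero_fc_dispersion(self, exact_fluor_curve):
        burdens = [_burden(f"m{i}", [1024.0] * 7) for i in range(3)]
        ph = clone_phenotype(burdens, exact_fluor_curve, seed=1)
        assert ph.fc_sd == 0.0
        assert ph.td_sd == pytest.approx(0.0, abs=1e-12)
        assert ph.td_mean == pytest.approx(24.0)

    def test_mixed_clones_rejected(self, exact_fluor_curve):
        burdens = [_burden("m1", [4.0]), _burden("m2", [4.0], clone="O1")]
        with pytest.raises(ValueError, match="clone"):
            clone_phenotype(burdens, exact_fluor_curve)

    def test_no_colonies_keeps_fc_defined_td_undefined(self, exact_fluor_curve):
        ph = clone_phenotype([_burden("m1", [])], exact_fluor_curve)
        assert ph.fc_mean == 0.0
        assert math.isnan(ph.td_mean)

    def test_sampling_caps_colonies_per_liver(self, exact_fluor_curve):
        burdens = [_burden("m1", [2.0**10] * 50)]
        ph5 = clone_phenotype(burdens, exact_fluor_curve, sample_size=5, seed=0)
        ph_all = clone_phenotype(burdens, exact_fluor_curve, all_colonies=True)
        assert ph5.td_mean == pytest.approx(ph_all.td_mean)  # identical colonies


class TestClassification:
    @pytest.mark.parametrize(
        "fc,td,expected",
        [
            (8.2e-5, 26.5, GrowthScenario.MANY_SMALL),
            (1.1e-5, 22.7, GrowthScenario.FEW_LARGE),
            (6.0e-6, 26.5, GrowthScenario.FEW_SMALL),
            (8.2e-5, 20.0, GrowthScenario.MANY_LARGE),
        ],
    )
    def test_fc_td_plane_quadrants(self, fc, td, expected):
        ph = ClonePhenotype(
            clone_id="x", fc_mean=fc, fc_sd=0.0, td_mean=td, td_sd=0.0,
            n_av=1e4, divisions_mean=13.3, n_mice=3,
        )
        assert classify_phenotype(ph, fc_threshold=2e-5, td_threshold=24.5) is expected

    def test_thresholds_must_be_positive(self):
        ph = ClonePhenotype("x", 1e-5, 0.0, 25.0, 0.0, 1e4, 13.3, 3)
        with pytest.raises(ValueError):
            classify_phenotype(ph, fc_threshold=0.0)
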