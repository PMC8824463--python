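import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoquad.model import MergedSite, PipelineError, PipelineParameters, Region
from phosphoquad.regions import assign_region, classify_sites, consistency_filter, summarize_regions

finite_coord = st.floats(-6, 6, allow_nan=False)


def site(atri, cko):
    return MergedSite(
        protein_accession="P1",
        representative_position=1,
        clustered_positions=(1,),
        ratios_atri={f"r{i+1}": v for i, v in enumerate(atri)},
        ratios_cko={f"r{i+1}": v for i, v in enumerate(cko)},
    )


class TestAssignRegion:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (0.0, 0.0, Region.CENTER),
            (0.4, -0.4, Region.CENTER),  # r ~ 0.566 <= 0.7
            (-2.0, -2.0, Region.Q2),  # concordant decrease on the diagonal
            (2.0, 2.0, Region.Q4),  # concordant increase
            (-0.3, -2.0, Region.Q1),  # ratio 6.67 > 5: knockout-dominant decrease
            (-2.0, -0.3, Region.Q3),  # ratio 0.15 < 0.2: inhibitor-dominant decrease
            (1.0, -1.0, Region.Q1),  # down on cKO only
            (-1.0, 1.0, Region.Q3),  # down on ATRi only
            (0.3, 2.0, Region.UNCLASSIFIED),  # increase outside the wedge
            (0.0, -2.0, Region.Q1),  # boundary convention: x = 0 with y < 0
            (-2.0, 0.0, Region.Q3),  # boundary convention: y = 0 with x < 0
            (0.0, 2.0, Region.UNCLASSIFIED),
            (2.0, 0.0, Region.UNCLASSIFIED),
            (0.7, 0.0, Region.CENTER),  # circle boundary inclusive
            (-1.0, -5.0, Region.Q2),  # wedge line y = 5x inclusive
            (-5.0, -1.0, Region.Q2),  # wedge line y = x/5 inclusive
        ],
    )
    def test_geometry(self, params, x, y, expected):
        assert assign_region(x, y, params) is expected

    def test_non_finite_coordinates_rejected(self, params):
        with pytest.raises(PipelineError):
            assign_region(float("nan"), 0.0, params)

    @given(x=finite_coord, y=finite_coord)
    @settings(max_examples=300, deadline=None)
    def test_axis_swap_maps_q1_to_q3_and_fixes_the_rest(self, x, y):
        params = PipelineParameters()
        swap = {Region.Q1: Region.Q3, Region.Q3: Region.Q1}
        a = assign_region(x, y, params)
        b = assign_region(y, x, params)
        assert b is swap.get(a, a)

    @given(x=finite_coord, y=finite_coord, bigger=st.floats(0.71, 3.0))
    @settings(max_examples=200, deadline=None)
    def test_growing_the_center_circle_never_unseats_center(self, x, y, bigger):
        small = PipelineParameters(center_radius=0.7)
        large = PipelineParameters(center_radius=bigger)
        if assign_region(x, y, small) is Region.CENTER:
            assert assign_region(x, y, large) is Region.CENTER

    @given(x=finite_coord, y=finite_coord, narrower=st.floats(1.5, 4.99))
    @settings(max_examples=200, deadline=None)
    def test_narrowing_the_bowtie_never_grows_q2(self, x, y, narrower):
        wide = PipelineParameters(bowtie_fold=5.0)
        narrow = PipelineParameters(bowtie_fold=narrower)
        if assign_region(x, y, narrow) is Region.Q2:
            assert assign_region(x, y, wide) is Region.Q2


class TestConsistencyFilter:
    def test_q2_without_inversion_passes(self, params):
        passed, offenders = consistency_filter(
            site([-1.2, -0.9, -1.1], [-0.8, -1.0]), Region.Q2, params
        )
        assert passed and offenders == ()

    def test_q2_with_inverted_replicate_fails_and_names_it(self, params):
        passed, offenders = consistency_filter(
            site([-1.2, -0.9, 0.30, -1.1, -1.0], [-0.8, -1.0]), Region.Q2, params
        )
        assert not passed
        ((_, rep, value),) = offenders
        assert rep == "r3" and value == pytest.approx(0.30)

    def test_inversion_below_magnitude_threshold_passes(self, params):
        passed, _ = consistency_filter(site([-1.2, 0.10], [-0.8, -1.0]), Region.Q2, params)
        assert passed

    def test_q1_only_constrains_the_knockout_axis(self, params):
        passed, _ = consistency_filter(site([0.5, -0.5], [-1.0, -1.2]), Region.Q1, params)
        assert passed
        passed, _ = consistency_filter(site([0.5, -0.5], [-1.0, 0.4]), Region.Q1, params)
        assert not passed

    def test_q4_expects_increases_on_both_axes(self, params):
        passed, _ = consistency_filter(site([1.0, -0.3], [1.0, 1.2]), Region.Q4, params)
        assert not passed

    def test_center_is_out_of_scope(self, params):
        with pytest.raises(PipelineError):
            consistency_filter(site([0.1], [0.1]), Region.CENTER, params)

    def test_idempotence(self, params):
        s = site([-1.2, 0.4], [-0.8])
        first = consistency_filter(s, Region.Q2, params)
        assert consistency_filter(s, Region.Q2, params) == first


class TestSummarizeRegions:
    def test_all_center(self, params):
        sites = [site([0.01 * i], [0.0]) for i in range(10)]
        summary = summarize_regions(classify_sites(sites, params))
        assert summary["pre"]["CENTER"] == 10
        assert sum(summary["pre"].values()) == 10

    def test_counts_partition_and_filter_only_shrinks(self, params):
        sites = (
            [site([-2.0, -1.8], [-1.9, -2.1]) for _ in range(4)]
            + [site([-2.0, 0.5], [-1.9, -2.1]) for _ in range(2)]  # inverted ATRi replicate
            + [site([0.1], [0.1]) for _ in range(3)]
        )
        assignments = classify_sites(sites, params)
        summary = summarize_regions(assignments)
        assert sum(summary["pre"].values()) == len(sites)
        assert summary["pre"]["Q2"] == 6
        assert summary["post"]["Q2"] == 4
        for region in summary["pre"]:
            assert summary["post"][region] <= summary["pre"][region]


class TestGeometryOracle:
    def test_grid_agrees_with_independent_predicates(self, params):
        """Independent region-by-region predicate evaluation on a 100x100 grid."""

        def oracle(x, y):
            F, R = params.bowtie_fold, params.center_radius
            in_center = math.hypot(x, y) <= R
            in_wedge = x != 0 and y != 0 and x * y > 0 and (1 / F) <= y / x <= F
            if in_center:
                return Region.CENTER
            if in_wedge and x < 0:
                return Region.Q2
            if in_wedge and x > 0:
                return Region.Q4
            if y < 0 and (x >= 0 or abs(y) > F * abs(x)):
                return Region.Q1
            if x < 0 and (y >= 0 or abs(y) * F < abs(x)):
                return Region.Q3
            return Region.UNCLASSIFIED

        n = 100
        for i in range(n):
            for j in range(n):
                x = -4 + 8 * i / (n - 1)
                y = -4 + 8 * j / (n - 1)
                assert assign_region(x, y, params) is oracle(x, y), (x, y)
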