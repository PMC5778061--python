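import numpy as np
import pytest

import oracles
from conftest import make_records
from ecrscan import (MultipleAlignment, call_ecrs, compute_profile,
                     filter_gap_columns, moving_average, regions_to_reference,
                     render_outputs, run_analysis)
from ecrscan.ancestral import ColumnStates
from ecrscan.errors import DegenerateProfileError
from ecrscan.profile import EcrRegion


def fake_columns(ss_values, n_informative=4):
    return [
        ColumnStates(candidate_sets={}, assigned={}, column_ss=float(v),
                     n_informative=n_informative)
        for v in ss_values
    ]


def fake_filtered(length):
    seq = "A" * length
    aln = MultipleAlignment(
        records=make_records({"ref": seq, "o1": seq, "o2": seq, "o3": seq}),
        reference_id="ref",
    )
    return filter_gap_columns(aln, threshold=1.0)


class TestComputeProfile:
    def test_all_conserved_is_degenerate(self):
        with pytest.raises(DegenerateProfileError, match="invariant"):
            compute_profile(fake_columns([0.0] * 30), fake_filtered(30))

    def test_constant_track_smooths_to_ones(self):
        profile = compute_profile(fake_columns([0.7] * 40), fake_filtered(40))
        np.testing.assert_allclose(profile.normalized, 1.0)
        np.testing.assert_allclose(profile.smoothed, 1.0, atol=1e-12)

    def test_normalized_track_has_unit_mean(self, rng):
        values = rng.random(80)
        profile = compute_profile(fake_columns(values), fake_filtered(80))
        assert profile.normalized.mean() == pytest.approx(1.0, abs=1e-9)

    def test_uninformative_columns_get_zero_relative_rate(self):
        columns = fake_columns([0.5, 0.5, 0.5])
        columns[1] = ColumnStates(candidate_sets={}, assigned={},
                                  column_ss=0.5, n_informative=1)
        profile = compute_profile(columns, fake_filtered(3))
        assert profile.relative[1] == 0.0
        assert profile.relative[0] == pytest.approx(0.5 / 4)

    def test_smoothing_matches_naive_triple_loop(self, rng):
        for _ in range(20):
            values = rng.random(60) * 3
            profile = compute_profile(fake_columns(values), fake_filtered(60))
            expected = oracles.smooth_naive(profile.normalized, 11, 7, 2)
            np.testing.assert_allclose(profile.smoothed, expected, atol=1e-12)

    def test_smoothing_contracts_toward_the_mean(self, rng):
        values = rng.random(100) * 5
        profile = compute_profile(fake_columns(values), fake_filtered(100))
        assert np.abs(profile.smoothed - 1).max() <= np.abs(profile.normalized - 1).max() + 1e-12


class TestMovingAverage:
    def test_rejects_even_window(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(5), 4)

    def test_window_one_is_identity(self, rng):
        x = rng.random(20)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_truncated_ends_average_available_points(self):
        out = moving_average(np.array([1.0, 2.0, 3.0, 4.0]), 3)
        np.testing.assert_allclose(out, [1.5, 2.0, 3.0, 3.5])


class TestCallEcrs:
    def test_monotone_track_has_no_regions(self):
        assert call_ecrs(np.linspace(0.1, 2.0, 30), minimum_threshold=np.inf) == []

    def test_v_shape_gives_single_region_around_minimum(self):
        regions = call_ecrs(np.array([3.0, 2.0, 1.0, 2.0, 3.0]),
                            minimum_threshold=np.inf)
        assert len(regions) == 1
        region = regions[0]
        assert region.start_col <= 3 <= region.end_col
        assert region.min_col == 3
        assert region.min_value == 1.0

    def test_plateau_minimum_reports_lower_median_column(self):
        track = np.array([3.0, 2.0, 1.0, 1.0, 1.0, 2.0, 3.0])
        regions = call_ecrs(track, minimum_threshold=np.inf)
        assert len(regions) == 1
        assert regions[0].min_col == 4  # middle of the three-column plateau

    def test_minima_at_or_above_threshold_discarded(self):
        track = np.array([3.0, 2.0, 1.2, 2.0, 3.0, 0.5, 3.0])
        regions = call_ecrs(track, minimum_threshold=1.0)
        assert [r.min_value for r in regions] == [0.5]

    def test_cosine_valley_boundaries_near_analytic_inflections(self):
        x = np.arange(100)
        track = 1 + 0.8 * np.cos(2 * np.pi * x / 100)
        regions = call_ecrs(track, minimum_threshold=1.0)
        assert len(regions) == 1
        region = regions[0]
        # cos curvature changes sign at quarter periods: columns 26 and 76
        assert region.start_col <= region.min_col <= region.end_col
        assert abs(region.min_col - 51) <= 1
        assert abs(region.start_col - 26) <= 2
        assert abs(region.end_col - 76) <= 2

    def test_regions_disjoint_sorted_below_threshold(self, rng):
        for _ in range(50):
            raw = rng.random(int(rng.integers(20, 120))) * 2
            track = oracles.smooth_naive(raw, 11, 7, 2)
            regions = call_ecrs(track, minimum_threshold=1.0)
            for region in regions:
                assert region.start_col <= region.min_col <= region.end_col
                assert region.min_value < 1.0
            for left, right in zip(regions, regions[1:]):
                assert left.end_col < right.start_col


class TestRegionsToReference:
    def test_gap_free_reference_is_identity(self):
        filtered = fake_filtered(30)
        regions = [EcrRegion(start_col=5, end_col=9, min_col=7, min_value=0.5)]
        mapped = regions_to_reference(regions, filtered)
        assert (mapped[0].start_ref, mapped[0].end_ref) == (5, 9)

    def test_boundary_on_reference_gap_moves_inward(self):
        aln = MultipleAlignment(
            records=make_records({
                "ref": "AAAA-AAAAA",
                "o1": "AAAAVAAAAA",
                "o2": "AAAAVAAAAA",
                "o3": "AAAAVAAAAA",
            }),
            reference_id="ref",
        )
        filtered = filter_gap_columns(aln, threshold=1.0)
        regions = [EcrRegion(start_col=5, end_col=9, min_col=7, min_value=0.5)]
        mapped = regions_to_reference(regions, filtered)
        # column 5 is a reference gap; start maps to the residue at column 6
        assert mapped[0].start_ref == 5
        assert mapped[0].end_ref == 8

    def test_region_inside_reference_gap_gets_no_reference_coords(self):
        aln = MultipleAlignment(
            records=make_records({
                "ref": "AA---AA",
                "o1": "AAVVVAA",
                "o2": "AAVVVAA",
                "o3": "AAVVVAA",
            }),
            reference_id="ref",
        )
        filtered = filter_gap_columns(aln, threshold=1.0)
        regions = [EcrRegion(start_col=3, end_col=5, min_col=4, min_value=0.5)]
        mapped = regions_to_reference(regions, filtered)
        assert mapped[0].start_ref is None and mapped[0].end_ref is None
        assert (mapped[0].start_col, mapped[0].end_col) == (3, 5)

    def test_mapped_intervals_nonempty_and_within_protein(self, make_family):
        for seed in range(5):
            fam = make_family(seed=seed, indel_prob=0.05)
            result = run_analysis(fam.records, tree=fam.tree)
            ref_len = result.filtered.reference_length
            for region in result.regions:
                if region.start_ref is None:
                    continue
                assert 1 <= region.start_ref <= region.end_ref <= ref_len


class TestRenderOutputs:
    @pytest.fixture()
    def result(self, make_family):
        fam = make_family(seed=11)
        return run_analysis(fam.records, tree=fam.tree)

    def test_tables_parse_back_with_matching_row_counts(self, result, tmp_path):
        import pandas as pd

        written = render_outputs(result.profile, result.regions,
                                 result.filtered, tmp_path, plot=False)
        scores = pd.read_csv(written["substitution_scores"], sep="\t")
        assert len(scores) == result.filtered.length
        raw = pd.read_csv(written["raw_substitution_scores"], sep="\t")
        assert len(raw) == (result.filtered.raw or result.filtered.alignment).length
        with open(written["aligned_sequences"]) as fh:
            lines = fh.read().splitlines()
        assert len(lines) == 3 + result.filtered.alignment.n_records

    def test_ecr_flags_mark_exactly_the_called_union(self, result, tmp_path):
        import pandas as pd

        written = render_outputs(result.profile, result.regions,
                                 result.filtered, tmp_path, plot=False)
        scores = pd.read_csv(written["substitution_scores"], sep="\t")
        flagged = set(scores.loc[scores.ecr == 1, "filtered_index"])
        expected = set()
        for region in result.regions:
            expected.update(range(region.start_col, region.end_col + 1))
        assert flagged == expected

    def test_rerendering_is_byte_identical(self, result, tmp_path):
        a = render_outputs(result.profile, result.regions, result.filtered,
                           tmp_path / "a", plot=False)
        b = render_outputs(result.profile, result.regions, result.filtered,
                           tmp_path / "b", plot=False)
        for key in a:
            with open(a[key], "rb") as fa, open(b[key], "rb") as fb:
                assert fa.read() == fb.read()

    def test_plot_files_created(self, result, tmp_path):
        written = render_outputs(result.profile, result.regions,
                                 result.filtered, tmp_path, plot=True)
        from pathlib import Path

        assert Path(written["plot_png"]).stat().st_size > 0
        assert Path(written["plot_svg"]).stat().st_size > 0
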