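"""Soil-profile arithmetic: fractions, backdating, deposition, file round trips."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csmig import (
    CHERNOBYL_DATE,
    FractionVector,
    Layer,
    SoilProfile,
    backdate_activity,
    deposition_report,
    fractional_contributions,
    read_profiles,
    total_deposition,
    write_profiles,
)
from csmig.profiles import decay_activity, years_between


class TestFractionalContributions:
    @pytest.mark.parametrize(
        "activities, expected",
        [
            ((50, 20, 10, 10, 5, 5), (0.50, 0.20, 0.10, 0.10, 0.05, 0.05)),
            ((10, 10, 10, 10, 10, 10), (1 / 6,) * 6),
        ],
    )
    def test_proportional_shares(self, profile_factory, activities, expected):
        fv = fractional_contributions(profile_factory(activities))
        np.testing.assert_allclose(fv.array, expected, atol=1e-15)

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sums_to_one(self, activities):
        layers = [Layer(5.0 * i, 5.0 * (i + 1), a) for i, a in enumerate(activities)]
        p = SoilProfile(datetime.date(2020, 6, 1), layers)
        assert abs(fractional_contributions(p).total - 1.0) < 1e-12

    def test_all_zero_profile_rejected(self, profile_factory):
        with pytest.raises(ValueError, match="empty profile"):
            fractional_contributions(profile_factory([0, 0, 0]))

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            Layer(0, 5, activity=-1.0)

    def test_elapsed_time_attached(self, profile_factory):
        p = profile_factory([1, 2, 3], date=datetime.date(2023, 4, 20))
        fv = fractional_contributions(p)
        assert fv.t == pytest.approx(years_between(CHERNOBYL_DATE, p.sample_date))
        assert fv.t == pytest.approx(36.98, abs=0.02)


class TestBackdating:
    @pytest.mark.parametrize(
        "activity, elapsed, half_life, expected",
        [
            (100.0, 0.0, 30.08, 100.0),
            (100.0, 30.08, 30.08, 200.0),
            (100.0, 36.95, 30.08, 234.3055223412739),
        ],
    )
    def test_decay_correction(self, activity, elapsed, half_life, expected):
        assert backdate_activity(activity, elapsed, half_life) == pytest.approx(expected, rel=1e-12)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            backdate_activity(100.0, -1.0)

    @given(st.floats(0.1, 1e4), st.floats(0.0, 100.0), st.floats(1.0, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_forward_then_back_is_identity(self, a, dt, half_life):
        assert backdate_activity(decay_activity(a, dt, half_life), dt, half_life) == pytest.approx(a, rel=1e-12)


class TestDeposition:
    def test_zero_profile(self, profile_factory):
        assert total_deposition(profile_factory([0, 0])) == 0.0

    def test_single_layer_unit_arithmetic(self, profile_factory):
        # 100 Bq/kg x 1300 kg/m3 x 0.05 m = 6500 Bq/m2 = 6.5 kBq/m2
        assert total_deposition(profile_factory([100.0])) == pytest.approx(6.5, rel=1e-12)

    def test_reference_inventory_scale(self, profile_factory):
        # a summed backdated activity of 286.2 Bq/kg corresponds to ~18.6 kBq/m2
        p = profile_factory([286.2 / 6] * 6)
        assert total_deposition(p) == pytest.approx(18.603, rel=1e-12)

    def test_linear_in_activity_and_density(self, profile_factory):
        base = total_deposition(profile_factory([30, 20, 10]))
        assert total_deposition(profile_factory([60, 40, 20])) == pytest.approx(2 * base)
        assert total_deposition(profile_factory([30, 20, 10], density=2.6)) == pytest.approx(2 * base)

    def test_backdated_exceeds_measured(self, profile_factory):
        p = profile_factory([10, 5, 2], date=datetime.date(2000, 1, 1))
        assert total_deposition(p, backdated=True) > total_deposition(p)

    def test_missing_density_rejected(self, profile_factory):
        with pytest.raises(ValueError, match="density"):
            profile_factory([1, 2], density=0.0)

    def test_report_columns(self, profile_factory):
        df = deposition_report([profile_factory([10, 20])])
        assert list(df.columns) == ["date", "t_years", "deposition_kBq_m2", "deposition_backdated_kBq_m2"]
        assert len(df) == 1


class TestProfileInvariants:
    def test_non_contiguous_layers_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            SoilProfile(datetime.date(2023, 1, 1), [Layer(0, 5, 1.0), Layer(10, 15, 1.0)])

    def test_non_uniform_thickness_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            SoilProfile(datetime.date(2023, 1, 1), [Layer(0, 5, 1.0), Layer(5, 12, 1.0)])

    def test_inverted_layer_rejected(self):
        with pytest.raises(ValueError, match="below"):
            Layer(5, 5, 1.0)

    def test_fraction_vector_rejects_negative(self):
        with pytest.raises(ValueError):
            FractionVector(0.0, (0.5, -0.1))


class TestFileRoundTrip:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert read_profiles(path) == []

    def test_single_profile(self, tmp_path):
        path = tmp_path / "one.csv"
        rows = "\n".join(
            f"2023-04-20,{5*i},{5*(i+1)},{10.0*(6-i)},0.1" for i in range(6)
        )
        path.write_text("# comment line\ndate,top_cm,bottom_cm,activity_Bq_per_kg,rel_sigma\n" + rows + "\n")
        profs = read_profiles(path)
        assert len(profs) == 1
        assert len(profs[0].layers) == 6
        assert profs[0].layers[0].activity == 60.0

    def test_round_trip_identity(self, tmp_path, profile_factory):
        profs = [
            profile_factory([61.3, 22.7, 9.01, 4.4, 2.2, 1.11], date=datetime.date(1987, 7, 10)),
            profile_factory([20.5, 18.2, 14.9, 11.3, 8.8, 6.1], date=datetime.date(2023, 4, 20)),
        ]
        path = tmp_path / "rt.csv"
        write_profiles(profs, path, header_lines=["provenance test"])
        back = read_profiles(path)
        assert len(back) == 2
        for orig, rec in zip(profs, back):
            assert rec.sample_date == orig.sample_date
            np.testing.assert_array_equal(rec.activities, orig.activities)

    def test_bad_date_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("date,top_cm,bottom_cm,activity_Bq_per_kg,rel_sigma\nnot-a-date,0,5,1.0,0.1\n")
        with pytest.raises(ValueError, match="unparsable date.*line"):
            read_profiles(path)

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("date,activity\n2023-01-01,5\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_profiles(path)

    def test_non_contiguous_file_rejected(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text(
            "date,top_cm,bottom_cm,activity_Bq_per_kg,rel_sigma\n"
            "2023-01-01,0,5,1.0,0.1\n2023-01-01,10,15,1.0,0.1\n"
        )
        with pytest.raises(ValueError, match="2023-01-01"):
            read_profiles(path)
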