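"""Campaign parsing, censoring semantics and occurrence statistics."""

import numpy as np
import pytest

from aquarisk import (
    Measurement,
    campaign_summary,
    compound_maxima,
    compound_summary,
    detection_frequency,
    detection_index,
    percent_detections_below,
    percent_samples_positive,
    read_campaign,
    seasonal_comparison,
    write_campaign,
)
from aquarisk.errors import DomainError, ParseError, ValidationError

from conftest import make_measurement


class TestMeasurement:
    def test_detected_value_below_loq_rejected(self):
        with pytest.raises(ValidationError, match="below its LOQ"):
            make_measurement(value=5.0, loq=10.0)

    def test_censored_measurement_carries_loq_only(self):
        m = make_measurement(value=None, loq=2.0)
        assert not m.detected
        assert m.loq == 2.0

    def test_unknown_season_rejected(self):
        with pytest.raises(ValidationError, match="season"):
            make_measurement(season="monsoon")


class TestCampaignIO:
    def test_toy_file_roundtrip_with_censoring(self, tmp_path):
        path = tmp_path / "campaign.csv"
        path.write_text(
            "city,season,sample_id,compound,value_ng_L,loq_ng_L\n"
            "Nanjing,dry,D01,caffeine,12.5,1.0\n"
            "Nanjing,dry,D01,diclofenac,ND,0.5\n"
            "Nanjing,wet,W01,caffeine,3.0,1.0\n"
        )
        ms = read_campaign(path)
        assert len(ms) == 3
        assert sum(not m.detected for m in ms) == 1
        out = tmp_path / "out.csv"
        write_campaign(ms, out, header_comment="roundtrip")
        assert read_campaign(out) == ms
        assert out.read_text().startswith("# roundtrip")

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("city,season,sample_id,compound,value_ng_L,loq_ng_L\n")
        assert read_campaign(path) == []

    def test_value_below_loq_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "city,season,sample_id,compound,value_ng_L,loq_ng_L\n"
            "Nanjing,dry,D01,caffeine,5,10\n"
        )
        with pytest.raises(ValidationError, match="row 0"):
            read_campaign(path)

    def test_unknown_season_tag_is_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "city,season,sample_id,compound,value_ng_L,loq_ng_L\n"
            "Nanjing,typhoon,D01,caffeine,5,1\n"
        )
        with pytest.raises(ValidationError, match="season"):
            read_campaign(path)

    def test_non_numeric_value_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "city,season,sample_id,compound,value_ng_L,loq_ng_L\n"
            "Nanjing,dry,D01,caffeine,lots,1\n"
        )
        with pytest.raises(ParseError, match="neither numeric"):
            read_campaign(path)


class TestFrequencies:
    def test_detection_frequency(self, toy_campaign):
        assert detection_frequency(toy_campaign, "caffeine") == pytest.approx(0.75)
        assert detection_frequency(toy_campaign, "atenolol") == pytest.approx(0.25)

    def test_all_censored_compound_has_zero_frequency(self):
        ms = [make_measurement(sample_id=f"D{i}", value=None) for i in range(5)]
        assert detection_frequency(ms, "caffeine") == 0.0

    def test_absent_compound_is_domain_error(self, toy_campaign):
        with pytest.raises(DomainError):
            detection_frequency(toy_campaign, "unicornium")

    def test_percent_samples_positive(self, toy_campaign):
        assert percent_samples_positive(toy_campaign) == pytest.approx(0.75)

    def test_percent_samples_positive_all_censored(self):
        ms = [make_measurement(sample_id=f"D{i}", value=None) for i in range(4)]
        assert percent_samples_positive(ms) == 0.0

    def test_positive_fraction_invariant_to_row_permutation_and_censored_duplication(
        self, toy_campaign
    ):
        base = percent_samples_positive(toy_campaign)
        assert percent_samples_positive(toy_campaign[::-1]) == base
        extra_censored = toy_campaign + [
            m for m in toy_campaign if not m.detected
        ]
        assert percent_samples_positive(extra_censored) == base

    @pytest.mark.parametrize(
        "threshold, expected", [(50.0, 0.75), (1000.0, 1.0), (0.0, 0.0), (2.0, 0.0)]
    )
    def test_percent_detections_below_strict(self, toy_campaign, threshold, expected):
        # detections: 10, 60, 5, 2 -> strict comparison at the threshold
        assert percent_detections_below(toy_campaign, threshold) == pytest.approx(expected)

    def test_percent_detections_below_requires_detections(self):
        ms = [make_measurement(value=None)]
        with pytest.raises(DomainError):
            percent_detections_below(ms, 50.0)


class TestDetectionIndex:
    def test_detections_per_sample(self):
        ms = []
        for i in range(4):  # 4 samples x 3 compounds = 12 detections
            for c in ("a", "b", "c"):
                ms.append(make_measurement(sample_id=f"D{i}", compound=c, value=5.0))
        assert detection_index(ms, "Nanjing") == pytest.approx(3.0)

    def test_zero_for_clean_city(self):
        ms = [make_measurement(city="Beijing", value=None)]
        assert detection_index(ms, "Beijing") == 0.0

    def test_identity_with_per_compound_counts(self, toy_campaign):
        for city in ("CityA", "CityB"):
            ms = [m for m in toy_campaign if m.city == city]
            total = sum(
                sum(1 for m in ms if m.compound == c and m.detected)
                for c in {m.compound for m in ms}
            )
            n_samples = len({m.sample_key for m in ms})
            assert detection_index(toy_campaign, city) == pytest.approx(total / n_samples)

    def test_absent_city_or_season(self, toy_campaign):
        with pytest.raises(DomainError):
            detection_index(toy_campaign, "Atlantis")
        with pytest.raises(DomainError):
            detection_index(toy_campaign, "CityA", season="wet")


class TestCompoundSummary:
    @pytest.mark.parametrize(
        "values, median, maximum",
        [([1, 2, 30], 2.0, 30.0), ([7], 7.0, 7.0), ([1, 2, 3, 4], 2.5, 4.0)],
    )
    def test_median_max_over_detections(self, values, median, maximum):
        ms = [
            make_measurement(sample_id=f"D{i}", value=float(v), loq=0.1)
            for i, v in enumerate(values)
        ]
        s = compound_summary(ms, "caffeine")
        assert s["median_detected"] == pytest.approx(median)
        assert s["max_detected"] == pytest.approx(maximum)

    def test_matches_plain_numpy_oracle_on_uncensored_data(self):
        rng = np.random.default_rng(11)
        values = rng.lognormal(2, 1, size=101).round(2) + 1.0
        ms = [
            make_measurement(sample_id=f"D{i}", value=float(v), loq=0.0)
            for i, v in enumerate(values)
        ]
        s = compound_summary(ms, "caffeine")
        assert s["median_detected"] == pytest.approx(float(np.median(values)))
        assert s["max_detected"] == pytest.approx(float(values.max()))
        assert s["detection_frequency"] == 1.0

    def test_censored_rows_excluded_by_default_but_substitutable(self):
        ms = [
            make_measurement(sample_id="D0", value=10.0, loq=2.0),
            make_measurement(sample_id="D1", value=None, loq=2.0),
            make_measurement(sample_id="D2", value=None, loq=2.0),
        ]
        assert compound_summary(ms, "caffeine")["median_detected"] == 10.0
        sub = compound_summary(ms, "caffeine", censored_substitution=True)
        assert sub["median_detected"] == pytest.approx(1.0)  # median of {10, 1, 1}
        assert sub["max_detected"] == 10.0  # max stays over detections

    def test_zero_detections_returns_absent_summary(self):
        ms = [make_measurement(value=None)]
        s = compound_summary(ms, "caffeine")
        assert s["detection_frequency"] == 0.0
        assert s["median_detected"] is None and s["max_detected"] is None

    def test_compound_maxima(self, toy_campaign):
        assert compound_maxima(toy_campaign) == {"caffeine": 60.0, "atenolol": 5.0}


class TestSeasonalComparison:
    def test_dry_exclusive_flagged(self, toy_campaign):
        df = seasonal_comparison(toy_campaign).set_index("compound")
        assert df.loc["atenolol", "exclusive"] == "dry_exclusive"
        assert df.loc["caffeine", "exclusive"] == ""

    def test_identical_seasons_are_symmetric(self):
        ms = []
        for season, sid in (("dry", "D01"), ("wet", "W01")):
            ms.append(
                make_measurement(season=season, sample_id=sid, value=8.0, loq=1.0)
            )
        df = seasonal_comparison(ms).set_index("compound")
        row = df.loc["caffeine"]
        assert row["dry_median"] == row["wet_median"] == 8.0
        assert row["exclusive"] == ""

    def test_missing_season_marked_absent(self):
        ms = [make_measurement(season="dry", value=8.0)]
        row = seasonal_comparison(ms).iloc[0]
        assert np.isnan(row["wet_frequency"])
        assert row["exclusive"] == "dry_exclusive"


class TestCampaignSummary:
    def test_bundles_consistent_statistics(self, toy_campaign):
        s = campaign_summary(toy_campaign, threshold_ng_L=50.0)
        assert s.n_samples == 4
        assert s.percent_samples_positive == pytest.approx(0.75)
        assert s.percent_detections_below_threshold == pytest.approx(0.75)
        per = s.per_compound.set_index("compound")
        assert per.loc["caffeine", "max_ng_L"] == 60.0
        assert not s.per_city_index.empty

    def test_empty_campaign_rejected(self):
        with pytest.raises(DomainError):
            campaign_summary([])
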