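"""Green-to-dry ratios, basic density and the three estimation approaches."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harvestledger import density as dn
from harvestledger.errors import (ConfigurationError, DensityLookupError,
                                  DomainError, EstimationError)
from harvestledger.fixtures import four_tree_fixture
from harvestledger.harvest_data import Disc, Subsample


def _sub(dry_mass, green_volume=100.0, q=1.7, qv=1.15, position="inner"):
    return Subsample(green_mass=q * dry_mass, dry_mass=dry_mass,
                     green_volume=green_volume,
                     dry_volume=green_volume / qv, radial_position=position)


class TestSubsampleDensity:
    @pytest.mark.parametrize("dry,vol,expected", [
        (60.0, 100.0, 600.0),
        (56.76, 100.0, 567.6),
    ])
    def test_dry_mass_over_green_volume(self, dry, vol, expected):
        assert dn.subsample_basic_density(_sub(dry, vol)) == pytest.approx(
            expected)

    def test_zero_volume_is_domain_error(self):
        s = Subsample(100.0, 60.0, green_volume=0.0, dry_volume=90.0)
        with pytest.raises(DomainError):
            dn.subsample_basic_density(s)

    def test_unimputed_missing_volume_is_domain_error(self):
        s = Subsample(100.0, 60.0, green_volume=None, dry_volume=90.0)
        with pytest.raises(DomainError, match="not imputed"):
            dn.subsample_basic_density(s)


class TestRatiosAndMoisture:
    def test_g2d_mass_ratio_values(self):
        assert dn.g2d_mass_ratio(100.0, 60.0) == pytest.approx(1.6667, abs=1e-4)
        assert dn.g2d_mass_ratio(173.1, 100.0) == pytest.approx(1.731)
        assert dn.g2d_mass_ratio(50.0, 50.0) == 1.0

    @pytest.mark.parametrize("ratio,expected", [
        (1.731, 0.4223), (1.0, 0.0), (2.0, 0.5)])
    def test_moisture_content(self, ratio, expected):
        assert dn.moisture_content(ratio) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(min_value=1.0, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_moisture_round_trips_through_ratio(self, ratio):
        m = dn.moisture_content(ratio)
        assert 1.0 / (1.0 - m) == pytest.approx(ratio, rel=1e-12)

    def test_moisture_monotone_in_ratio(self):
        values = [dn.moisture_content(r) for r in (1.0, 1.2, 1.6, 2.5)]
        assert values == sorted(values)

    def test_campaign_moisture_in_region_of_40_percent(self):
        for t in four_tree_fixture():
            assert 0.35 < dn.moisture_content(t.g2d_mass_ratio) < 0.45


class TestImputation:
    def test_imputed_volume_is_dry_times_ratio(self):
        assert dn.impute_green_volume(100.0, 1.169) == pytest.approx(116.9)
        assert dn.impute_green_volume(80.0, 1.0) == 80.0
        with pytest.raises(DomainError):
            dn.impute_green_volume(-5.0, 1.1)

    def test_tree_level_imputation_uses_measured_reference(self, noiseless_tree):
        import copy
        tree = copy.deepcopy(noiseless_tree.tree)
        target = tree.discs[0].subsamples[0]
        qv = target.green_volume / target.dry_volume
        target.green_volume = None
        n = dn.impute_missing_green_volumes(tree)
        assert n == 1
        assert target.imputed_green_volume
        # all synthetic subsamples share one swelling ratio, so the
        # reconstruction is exact
        assert target.green_volume == pytest.approx(target.dry_volume * qv)

    def test_no_reference_and_no_fallback_is_configuration_error(self):
        disc = Disc("d", "SD1", subsamples=[
            Subsample(100.0, 60.0, None, 90.0, "outer"),
            Subsample(100.0, 60.0, None, 90.0, "outer")])
        from harvestledger.harvest_data import HarvestTree, Section
        tree = HarvestTree("X", "sp", 0, 0, 0.5, 30.0,
                           sections=[Section("stem", 10.0)], discs=[disc])
        with pytest.raises(ConfigurationError):
            dn.impute_missing_green_volumes(tree)


class TestPoolAggregation:
    def test_pool_mean_is_unweighted(self):
        assert dn.pool_mean([500.0, 700.0]) == 600.0
        assert dn.pool_mean([612.3]) == 612.3
        with pytest.raises(EstimationError, match="crown"):
            dn.pool_mean([], "crown")

    def test_mass_weighted_estimate(self):
        est = dn.mass_weighted_estimate({"stem": 600.0, "crown": 500.0},
                                        {"stem": 400.0, "crown": 600.0})
        assert est == pytest.approx(540.0)

    def test_mass_weighted_limit_cases(self):
        same = dn.mass_weighted_estimate({"stem": 620.0, "crown": 620.0},
                                         {"stem": 1.0, "crown": 99.0})
        assert same == 620.0
        one = dn.mass_weighted_estimate({"stem": 600.0, "crown": 500.0},
                                        {"stem": 0.0, "crown": 10.0})
        assert one == 500.0
        with pytest.raises(DomainError):
            dn.mass_weighted_estimate({"stem": 600.0}, {"stem": 0.0})

    @given(st.floats(100, 1000), st.floats(100, 1000),
           st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_mass_weighted_is_convex_combination(self, x1, x2, m1, m2):
        est = dn.mass_weighted_estimate({"stem": x1, "crown": x2},
                                        {"stem": m1, "crown": m2})
        assert min(x1, x2) - 1e-9 <= est <= max(x1, x2) + 1e-9


class TestApproaches:
    def test_stem_estimate_uses_outer_breast_height_subsamples(self):
        from harvestledger.harvest_data import HarvestTree, Section
        disc = Disc("d", "SD1", subsamples=[
            _sub(56.0, position="outer"), _sub(61.0), _sub(59.0, position="outer")])
        tree = HarvestTree("X", "sp", 0, 0, 0.5, 30.0,
                           sections=[Section("stem", 10.0)], discs=[disc])
        assert dn.stem_estimate(tree).basic_density == pytest.approx(575.0)

    def test_missing_breast_height_disc_is_estimation_error(self):
        from harvestledger.harvest_data import HarvestTree, Section
        tree = HarvestTree("X", "sp", 0, 0, 0.5, 30.0,
                           sections=[Section("stem", 10.0)],
                           discs=[Disc("d", "SD2", subsamples=[
                               _sub(60.0, position="outer"),
                               _sub(60.0, position="outer")])])
        with pytest.raises(EstimationError, match="SD1"):
            dn.stem_estimate(tree)

    def test_literature_lookup_averages_species_matches(self):
        db = pd.DataFrame({"species": ["Inga alba", "  inga ALBA ", "Other sp"],
                           "basic_density_kg_m3": [450.0, 470.0, 900.0]})
        est = dn.literature_estimate("Inga alba", db)
        assert est.basic_density == 460.0

    def test_literature_lookup_has_no_genus_fallback(self):
        db = pd.DataFrame({"species": ["Inga alba"],
                           "basic_density_kg_m3": [450.0]})
        with pytest.raises(DensityLookupError):
            dn.literature_estimate("Inga edulis", db)

    def test_basic_density_never_exceeds_green_density(self, noisy_tree):
        est = dn.mass_weighted_density(noisy_tree.tree)
        assert est.green_density >= est.basic_density


class TestProfileAndDifference:
    def test_single_disc_profile(self):
        from harvestledger.harvest_data import HarvestTree, Section
        disc = Disc("d", "SD1", subsamples=[
            _sub(60.0, position="outer"), _sub(64.0, position="outer")])
        tree = HarvestTree("X", "sp", 0, 0, 0.5, 30.0,
                           sections=[Section("stem", 10.0)], discs=[disc])
        profile = dn.density_profile(tree)
        loc = profile.locations["SD1"]
        assert loc["mean"] == pytest.approx(620.0)
        assert loc["max"] - loc["min"] == pytest.approx(40.0)
        assert profile.max_pairwise_difference == pytest.approx(40.0)

    def test_two_disc_max_pairwise_difference(self):
        from harvestledger.harvest_data import HarvestTree, Section
        discs = [Disc("a", "SD1", subsamples=[_sub(50.0, position="outer"),
                                              _sub(50.0, position="outer")]),
                 Disc("b", "SD2", subsamples=[_sub(66.0, position="outer"),
                                              _sub(66.0, position="outer")])]
        tree = HarvestTree("X", "sp", 0, 0, 0.5, 30.0,
                           sections=[Section("stem", 10.0)], discs=discs)
        assert dn.density_profile(tree).max_pairwise_difference == \
            pytest.approx(160.0)

    @pytest.mark.parametrize("a,b,expected", [
        (639.0, 554.5, 14.2), (567.6, 586.1, 3.2), (567.0, 460.0, 20.8)])
    def test_symmetric_percent_difference_on_campaign_values(self, a, b,
                                                             expected):
        assert dn.percent_difference(a, b) == pytest.approx(expected, abs=0.05)

    def test_percent_difference_identity_and_domain(self):
        assert dn.percent_difference(500.0, 500.0) == 0.0
        with pytest.raises(DomainError):
            dn.percent_difference(-1.0, 500.0)

    def test_relative_form_available(self):
        assert dn.percent_difference(100.0, 80.0, form="relative") == \
            pytest.approx(20.0)
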