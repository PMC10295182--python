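import itertools

import numpy as np
import pandas as pd
import pytest

from benthet import diversity as dv
from benthet.core_data import CommunityMatrix
from benthet.diversity import RareSpeciesCriteria


def matrix_with_occupancy(occupancies, n_stations=162, abundance=1):
    """Matrix where taxon i occupies the first occupancies[i] stations."""
    counts = pd.DataFrame(
        0,
        index=[f"s{i}" for i in range(n_stations)],
        columns=[f"t{j}" for j in range(len(occupancies))],
    )
    for j, occ in enumerate(occupancies):
        counts.iloc[:occ, j] = abundance
    return CommunityMatrix(counts=counts)


class TestRichness:
    def test_counts_positive_taxa_only(self):
        m = CommunityMatrix(
            counts=pd.DataFrame({"a": [3, 0], "b": [0, 0], "c": [1, 0]}, index=["s1", "s2"])
        )
        assert dv.richness_per_sample(m).tolist() == [2, 0]

    def test_matches_generator_bookkeeping(self, default_dataset):
        rich = dv.richness_per_sample(default_dataset["community"])
        truth = default_dataset["truth"].stations["richness_drawn"]
        pd.testing.assert_series_equal(
            rich, truth, check_names=False, check_dtype=False
        )


class TestOccupancyFrequency:
    @pytest.mark.parametrize(
        "occ,n,expected", [(147, 162, 90.7), (140, 162, 86.4), (162, 162, 100.0)]
    )
    def test_survey_report_rounding(self, occ, n, expected):
        m = matrix_with_occupancy([occ], n_stations=n)
        out = dv.occupancy_and_frequency(m)
        assert out.loc["t0", "occupancy"] == occ
        assert out.loc["t0", "frequency_pct"] == expected


class TestIdentifyRare:
    def test_three_stations_low_abundance_is_rare(self):
        m = matrix_with_occupancy([3], abundance=1)
        m.counts.iloc[1, 0] = 2
        m.counts.iloc[2, 0] = 3
        assert dv.identify_rare(m) == ["t0"]

    def test_abundance_above_cap_excludes(self):
        m = matrix_with_occupancy([3])
        m.counts.iloc[0, 0] = 4
        assert dv.identify_rare(m) == []

    def test_four_stations_not_rare_at_162(self):
        # 4/162 ~ 2.47% is not below the 2% frequency bound
        m = matrix_with_occupancy([4])
        assert dv.identify_rare(m) == []

    def test_tightening_criteria_is_monotone(self, default_dataset):
        m = default_dataset["community"]
        base = set(dv.identify_rare(m, RareSpeciesCriteria(0.02, 3)))
        tighter_freq = set(dv.identify_rare(m, RareSpeciesCriteria(0.01, 3)))
        tighter_abund = set(dv.identify_rare(m, RareSpeciesCriteria(0.02, 1)))
        assert tighter_freq <= base
        assert tighter_abund <= base


class TestRareRateTable:
    def test_single_station_no_rare(self):
        counts = pd.DataFrame({"common": [5]}, index=["s1"])
        stations = pd.DataFrame(
            {"sediment_type": ["mud"], "geoclass": ["none"]}, index=["s1"]
        )
        tab = dv.rare_rate_table(CommunityMatrix(counts=counts), stations)
        assert tab.total_records == 0
        assert tab.with_margins().loc["Overall", "Overall"] == 0.0

    def test_missing_labels_error_lists_stations(self):
        counts = pd.DataFrame({"a": [1, 1]}, index=["s1", "s2"])
        stations = pd.DataFrame(
            {"sediment_type": ["mud", None], "geoclass": ["none", "low"]},
            index=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="s2"):
            dv.rare_rate_table(CommunityMatrix(counts=counts), stations)

    def test_margins_are_pooled_sums(self, default_dataset):
        m = default_dataset["community"]
        stations = default_dataset["stations_frame"]
        tab = dv.rare_rate_table(m, stations)
        full = tab.with_margins(decimals=None)
        n = tab.n_samples
        assert tab.records.sum().sum() == tab.total_records
        assert full.loc["Overall", "Overall"] * n.sum().sum() == pytest.approx(
            tab.total_records
        )
        # row margin equals pooled records over pooled samples
        for geo in tab.records.index:
            pooled = tab.records.loc[geo].sum() / n.loc[geo].sum()
            assert full.loc[geo, "Overall"] == pytest.approx(pooled)


class TestRarefaction:
    def test_k_equals_n_gives_total_richness(self, toy_community):
        curve = dv.rarefaction_exact(toy_community)
        total = (toy_community.counts.sum(axis=0) > 0).sum()
        assert curve.expected_richness[-1] == pytest.approx(total)

    def test_k_one_gives_mean_sample_richness(self, toy_community):
        curve = dv.rarefaction_exact(toy_community)
        assert curve.expected_richness[0] == pytest.approx(
            dv.richness_per_sample(toy_community).mean()
        )

    def test_exact_equals_bruteforce_all_subsets(self, toy_community):
        curve = dv.rarefaction_exact(toy_community)
        inc = toy_community.counts.to_numpy() > 0
        n = inc.shape[0]
        for k in range(1, n + 1):
            vals = [
                inc[list(sub)].any(axis=0).sum()
                for sub in itertools.combinations(range(n), k)
            ]
            assert curve.expected_richness[k - 1] == pytest.approx(np.mean(vals))

    def test_curve_nondecreasing_and_concave(self, default_dataset):
        curve = dv.rarefaction_exact(default_dataset["community"], kmax=60)
        diffs = np.diff(curve.expected_richness)
        assert np.all(diffs >= -1e-9)
        assert np.all(np.diff(diffs) <= 1e-9)

    def test_permutation_mean_tracks_exact(self, toy_community):
        exact = dv.rarefaction_exact(toy_community)
        perm = dv.rarefaction_permutation(toy_community, n_perm=400, rng=5)
        for k in range(len(exact.k)):
            se = perm.sd[k] / np.sqrt(400) if perm.sd[k] > 0 else 1e-9
            assert abs(perm.expected_richness[k] - exact.expected_richness[k]) < max(
                3 * se, 0.15
            )

    def test_permutation_sd_zero_at_full_pooling(self, toy_community):
        perm = dv.rarefaction_permutation(toy_community, n_perm=50, rng=1)
        assert perm.sd[-1] == pytest.approx(0.0)

    def test_permutation_deterministic_under_seed(self, toy_community):
        a = dv.rarefaction_permutation(toy_community, n_perm=50, rng=9)
        b = dv.rarefaction_permutation(toy_community, n_perm=50, rng=9)
        assert np.array_equal(a.expected_richness, b.expected_richness)
        assert np.array_equal(a.sd, b.sd)

    def test_k_beyond_n_rejected(self, toy_community):
        with pytest.raises(ValueError):
            dv.rarefaction_exact(toy_community, kmax=7)


class TestTaxonGroups:
    def test_tally_counts_present_taxa_per_group(self):
        counts = pd.DataFrame(
            {"a": [1, 0], "b": [2, 1], "c": [0, 0]}, index=["s1", "s2"]
        )
        m = CommunityMatrix(
            counts=counts,
            taxon_groups={"a": "polychaete", "b": "polychaete", "c": "mollusc"},
        )
        assert dv.taxon_group_tally(m) == {"polychaete": 2}

    def test_unlabeled_taxon_rejected(self):
        m = CommunityMatrix(
            counts=pd.DataFrame({"a": [1]}, index=["s1"]), taxon_groups={}
        )
        with pytest.raises(ValueError, match="without group label"):
            dv.taxon_group_tally(m)

    def test_synthetic_pool_group_design(self, default_dataset):
        pool = default_dataset["truth"].pool
        assert pool["group"].value_counts().to_dict() == {
            "polychaete": 79,
            "mollusc": 54,
            "crustacean": 39,
            "other": 27,
        }
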