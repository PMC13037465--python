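"""Virus-host grouping, rank statistics, sensitivity, name inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sedavirome.tables import aggregate_cumulative, relative_abundance
from sedavirome.virushost import (
    VirusHostError,
    build_host_groups,
    exclusion_sensitivity,
    group_abundance_series,
    infer_host_from_name,
    phage_class_groups,
    positive_shift_test,
    spearman,
)

from conftest import rank_then_pearson, signed_rank_enumeration


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 10.0])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_closed_form_example(self):
        r = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.rho == pytest.approx(0.6)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = int(rng.integers(4, 15))
            x = rng.integers(0, 6, n).astype(float)  # ties likely
            y = rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            r = spearman(x, y, exact_max_n=0)
            assert r.rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        # perfectly concordant n=4: p = 2/4! (both extremes) under the
        # two-sided permutation null
        r = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.method == "exact-permutation"
        assert r.pvalue == pytest.approx(2 / 24)

    def test_constant_series_flagged_undefined(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert r.undefined and np.isnan(r.rho)

    def test_nan_pairs_dropped(self):
        r = spearman([1, 2, np.nan, 4, 5], [1, 2, 3, 4, 5])
        assert r.n == 4 and r.rho == pytest.approx(1.0)

    def test_too_few_observations(self):
        with pytest.raises(VirusHostError):
            spearman([1, 2], [2, 1])


class TestShiftTest:
    def test_five_positive_coefficients(self):
        t = positive_shift_test([0.2, 0.5, 0.7, 0.9, 0.3], "greater")
        assert t.method == "exact"
        assert t.pvalue == pytest.approx(1 / 32)

    def test_symmetric_pair(self):
        t = positive_shift_test([-0.4, 0.4], "greater")
        assert t.pvalue == pytest.approx(0.75)

    def test_single_positive(self):
        assert positive_shift_test([0.8], "greater").pvalue == pytest.approx(0.5)

    def test_zeros_dropped_and_all_zero_degenerate(self):
        t = positive_shift_test([0.0, 0.5, 0.0, 0.7], "greater")
        assert t.n == 2
        with pytest.raises(VirusHostError, match="degenerate"):
            positive_shift_test([0.0, 0.0])

    def test_direction_less(self):
        t = positive_shift_test([-0.2, -0.5, -0.9], "less")
        assert t.pvalue == pytest.approx(1 / 8)

    def test_exact_matches_full_enumeration_up_to_n10(self):
        rng = np.random.default_rng(13)
        for n in range(1, 11):
            for _ in range(5):
                v = np.round(rng.normal(size=n), 3)
                v = v[v != 0]
                if v.size == 0:
                    continue
                for direction in ("greater", "less"):
                    t = positive_shift_test(v, direction)
                    w_obs, p = signed_rank_enumeration(v, direction)
                    assert t.statistic == pytest.approx(w_obs)
                    assert t.pvalue == pytest.approx(p, abs=1e-12)

    def test_normal_approximation_above_exact_limit(self):
        rng = np.random.default_rng(14)
        v = rng.normal(0.3, 0.4, size=40)
        t = positive_shift_test(v, "greater")
        assert t.method == "normal"
        assert 0 < t.pvalue < 1


class TestGrouping:
    def test_aggregation_ranks_by_domain(self, default_sim):
        res = default_sim["res"]
        groups = build_host_groups(res.pairs, res.tree)
        names = {res.tree.name(g): v for g, v in groups.items()}
        # bacteria at genus, eukaryotes at phylum, archaea at superkingdom
        assert "Pelagibacter" in names
        assert "Haptophyta" in names
        assert "Archaea" in names
        truth = res.truth["couplings"]
        for cname, tc in truth.items():
            assert set(tc["virus_taxa"]) <= groups[tc["host_group"]]

    def test_missing_rank_ancestor_drops_pair(self, four_node_tree):
        pairs = pd.DataFrame(
            [
                {
                    "virus_taxid": 5,
                    "virus_name": "v",
                    "host_taxid": 6,
                    "host_name": "h",
                    "host_domain": "eukaryota",  # no phylum in this tree
                    "evidence": "literature",
                }
            ]
        )
        with pytest.warns(UserWarning, match="phylum"):
            groups = build_host_groups(pairs, four_node_tree)
        assert groups == {}

    def test_virus_sum_is_member_order_invariant(self, default_sim):
        res = default_sim["res"]
        tc = res.truth["couplings"]["pelagiphage"]
        site = next(iter(tc["per_site"]))
        s1 = group_abundance_series(
            default_sim["ab_all"], res.meta, site, tc["host_group"],
            tc["virus_taxa"],
        )
        s2 = group_abundance_series(
            default_sim["ab_all"], res.meta, site, tc["host_group"],
            list(reversed(tc["virus_taxa"])),
        )
        pd.testing.assert_frame_equal(s1.frame, s2.frame)

    def test_absent_group_flagged_empty(self, default_sim):
        res = default_sim["res"]
        site = res.meta.loc[res.meta.environment == "lake", "site"].iloc[0]
        s = group_abundance_series(
            default_sim["ab_all"], res.meta, site, group=999999,
            virus_taxa=[999998],
        )
        assert s.empty


class TestExclusionSensitivity:
    def test_noop_exclusion_of_zero_abundance_taxon(self, default_sim):
        res = default_sim["res"]
        tc = res.truth["couplings"]["pelagiphage"]
        site = next(iter(tc["per_site"]))
        tab = exclusion_sensitivity(
            default_sim["ab_all"], res.meta, site, tc["host_group"],
            tc["virus_taxa"], candidate_taxa=[999999],
            epoch_subsets=("all",),
        )
        base = tab[tab.excluded == "baseline"]["rho"].iloc[0]
        excl = tab[tab.excluded == "999999"]["rho"].iloc[0]
        assert base == pytest.approx(excl, abs=1e-12)

    def test_excluding_whole_group_is_undefined(self, default_sim):
        res = default_sim["res"]
        tree = res.tree
        tc = res.truth["couplings"]["pelagiphage"]
        site = next(iter(tc["per_site"]))
        members = tree.descendants(tc["host_group"], include_self=True)
        tab = exclusion_sensitivity(
            default_sim["ab_all"], res.meta, site, tc["host_group"],
            tc["virus_taxa"], candidate_taxa=members, epoch_subsets=("all",),
        )
        full = tab[tab.excluded == "all-candidates"]
        assert bool(full["undefined"].iloc[0])


class TestNameInference:
    KNOWN = {"Pelagibacter", "Synechococcus", "Flavobacterium"}

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Pelagibacter phage HTVC010P", "Pelagibacter"),
            ("uncultured Caudovirales phage", None),
            ("phage X17", None),
            ("Synechococcus PHAGE S-PM2", "Synechococcus"),
            ("pelagibacter phage X", None),  # exact-match, capitalised only
            ("Micromonas virus 1", None),  # no "phage" token
        ],
    )
    def test_trivial_name_convention(self, name, expected):
        assert infer_host_from_name(name, self.KNOWN) == expected


class TestPhageClassGroups:
    def test_resolution_precedence_and_class_lift(self, default_sim):
        res = default_sim["res"]
        tree = res.tree
        groups, unresolved = phage_class_groups(
            res.annotations, res.pairs, res.vmr, tree
        )
        names = {tree.name(c): v for c, v in groups.items()}
        # curated pelagiphages land under Alphaproteobacteria even though
        # the VMR table lists one of them under the wrong genus
        pel = set(res.truth["couplings"]["pelagiphage"]["virus_taxa"])
        assert pel <= names["Alphaproteobacteria"]
        cyano = set(res.truth["couplings"]["cyanophage"]["virus_taxa"])
        assert cyano <= names["Cyanophyceae"]
        # the orphan phage is resolvable only through its trivial name
        for env, orphan in (("lake", "Flavobacteriia"), ("marine", "Cyanophyceae")):
            taxid = next(
                t for t, row in res.annotations.iterrows()
                if "orphan-sim" in row["name"] and env in row["name"]
            )
            assert taxid in names[orphan]
            assert taxid not in unresolved
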