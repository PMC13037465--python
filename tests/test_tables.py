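"""Count parsing, cumulative aggregation, normalisation, blanks."""

import io
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sedavirome.tables import (
    CountMatrix,
    TableError,
    aggregate_cumulative,
    blank_summary,
    read_lca_counts,
    read_sample_metadata,
    relative_abundance,
    round_sig,
    write_lca_counts,
)
from sedavirome.taxonomy import parse_taxonomy

from conftest import descendant_sum_oracle, random_taxonomy


def _cm(index, columns, values, mode="assigned"):
    return CountMatrix(
        pd.DataFrame(values, index=pd.Index(index, name="taxid"), columns=columns),
        mode,
    )


@pytest.fixture()
def chain_tree():
    # species S1, S2 under genus G under family F under root
    return parse_taxonomy(
        [
            (1, 1, "no-rank"),
            (2, 1, "family"),
            (3, 2, "genus"),
            (4, 3, "species"),
            (5, 3, "species"),
        ],
        [(1, "root"), (2, "F"), (3, "G"), (4, "S1"), (5, "S2")],
    )


class TestAggregateCumulative:
    def test_four_node_example(self, chain_tree):
        cm = _cm([4, 5, 3, 2], ["s"], [[3], [2], [1], [0]])
        cum = aggregate_cumulative(cm, chain_tree)
        assert cum.mode == "cumulative"
        assert cum.data.loc[4, "s"] == 3
        assert cum.data.loc[5, "s"] == 2
        assert cum.data.loc[3, "s"] == 6
        assert cum.data.loc[2, "s"] == 6
        assert cum.data.loc[1, "s"] == 6
        # input untouched
        assert cm.data.loc[3, "s"] == 1 and cm.mode == "assigned"

    def test_all_zero_counts_stay_zero(self, chain_tree):
        cum = aggregate_cumulative(
            _cm([4, 5], ["a", "b"], [[0, 0], [0, 0]]), chain_tree
        )
        assert (cum.data.to_numpy() == 0).all()

    def test_single_leaf_propagates_to_every_ancestor(self, chain_tree):
        cum = aggregate_cumulative(_cm([4], ["s"], [[7]]), chain_tree)
        for node in (1, 2, 3, 4):
            assert cum.data.loc[node, "s"] == 7

    def test_unknown_taxon_named_in_error(self, chain_tree):
        with pytest.raises(TableError, match="99"):
            aggregate_cumulative(_cm([99], ["s"], [[1]]), chain_tree)

    def test_matches_descendant_sum_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            tree = random_taxonomy(rng, int(rng.integers(5, 50)))
            taxa = sorted(
                rng.choice(list(tree), size=int(rng.integers(2, len(tree))),
                           replace=False).tolist()
            )
            vals = rng.integers(0, 50, size=(len(taxa), 3))
            cm = _cm(taxa, ["a", "b", "c"], vals)
            cum = aggregate_cumulative(cm, tree)
            oracle = descendant_sum_oracle(cm.data, tree)
            assert set(cum.data.index) == set(oracle)
            for node, expected in oracle.items():
                np.testing.assert_array_equal(
                    cum.data.loc[node].to_numpy(), expected
                )

    @given(st.integers(0, 2**31 - 1))
    def test_cumulative_monotonicity_property(self, seed):
        """cum(parent) >= cum(child) on every edge; root total conserved."""
        rng = np.random.default_rng(seed)
        tree = random_taxonomy(rng, int(rng.integers(3, 30)))
        taxa = sorted(
            rng.choice(list(tree), size=int(rng.integers(1, len(tree))),
                       replace=False).tolist()
        )
        vals = rng.integers(0, 100, size=(len(taxa), 2))
        cum = aggregate_cumulative(_cm(taxa, ["x", "y"], vals), tree)
        for t in cum.data.index:
            if t != tree.root and tree.parent(int(t)) in cum.data.index:
                assert (
                    cum.data.loc[tree.parent(int(t))] >= cum.data.loc[t]
                ).all()
        np.testing.assert_array_equal(
            cum.data.loc[tree.root].to_numpy(), vals.sum(axis=0)
        )


class TestRelativeAbundance:
    def test_pooled_viral_share_arithmetic(self):
        # one pooled pseudo-sample: root carries everything mapped,
        # the viral subtree 357161 of 400186289 mapped reads
        tree = parse_taxonomy(
            [(1, 1, "no-rank"), (2, 1, "superkingdom")], [(1, "root"), (2, "Viruses")]
        )
        cm = _cm([1, 2], ["pool"], [[400186289 - 357161], [357161]])
        ab = relative_abundance(aggregate_cumulative(cm, tree), tree, "root")
        assert ab.data.loc[2, "pool"] == pytest.approx(0.00089, abs=5e-6)
        assert round(100 * ab.data.loc[2, "pool"], 3) == 0.089

    def test_scope_root_abundance_is_one(self, chain_tree):
        cum = aggregate_cumulative(_cm([4], ["s"], [[12]]), chain_tree)
        ab = relative_abundance(cum, chain_tree, 3)
        assert ab.data.loc[3, "s"] == 1.0
        assert set(ab.data.index) <= {3, 4, 5}

    def test_zero_denominator_flagged_missing(self, chain_tree):
        cum = aggregate_cumulative(
            _cm([4], ["has", "empty"], [[5, 0]]), chain_tree
        )
        ab = relative_abundance(cum, chain_tree, 3)
        assert np.isnan(ab.data.loc[4, "empty"])
        assert ab.data.loc[4, "has"] == 1.0

    def test_reads_above_scope_children_stay_in_denominator(self, chain_tree):
        # genus-level stragglers: children sum + root's own share = 1
        cm = _cm([3, 4, 5], ["s"], [[4], [3], [3]])
        ab = relative_abundance(aggregate_cumulative(cm, chain_tree), chain_tree, 3)
        child_sum = ab.data.loc[4, "s"] + ab.data.loc[5, "s"]
        own = 4 / 10
        assert child_sum + own == pytest.approx(1.0, abs=1e-12)


class TestIO:
    def _write(self, text):
        return io.StringIO(text)

    def test_round_trip(self, chain_tree, tmp_path):
        cm = _cm([4, 5], ["a", "b"], [[1, 2], [3, 4]])
        ann = pd.DataFrame(
            {"name": ["S1", "S2"], "rank": ["species", "species"]},
            index=pd.Index([4, 5], name="taxid"),
        )
        p = tmp_path / "counts.tsv"
        write_lca_counts(cm, ann, p, header_comment="round trip")
        back, ann2 = read_lca_counts(p)
        pd.testing.assert_frame_equal(back.data, cm.data)
        assert list(ann2["rank"]) == ["species", "species"]

    def test_duplicate_rows_summed_with_warning(self):
        text = "taxid\tname\trank\ts1\n4\tS1\tspecies\t3\n4\tS1\tspecies\t4\n"
        with pytest.warns(UserWarning, match="duplicated"):
            cm, _ = read_lca_counts(self._write(text))
        assert cm.data.loc[4, "s1"] == 7

    def test_negative_count_cites_row(self):
        text = "taxid\tname\trank\ts1\n4\tS1\tspecies\t2\n5\tS2\tspecies\t-1\n"
        with pytest.raises(TableError, match="row 2"):
            read_lca_counts(self._write(text))

    def test_metadata_epoch_assignment(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text(
            "sample_id,site,environment,age_cal_ka_bp\n"
            "a,L,lake,3.0\nb,L,lake,11.7\nc,L,lake,20.0\nd,blank,blank,\n"
        )
        meta = read_sample_metadata(p)
        assert list(meta["epoch"]) == ["Holocene", "Holocene", "Pleistocene", None]

    def test_metadata_rejects_aged_blank(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text(
            "sample_id,site,environment,age_cal_ka_bp\nd,blank,blank,4.2\n"
        )
        with pytest.raises(TableError, match="blank"):
            read_sample_metadata(p)


class TestBlankSummary:
    def _meta(self, samples, blanks):
        rows = [
            {"sample_id": s, "site": "L", "environment": "lake", "age_cal_ka_bp": 1.0}
            for s in samples
        ]
        rows += [
            {"sample_id": b, "site": "blank", "environment": "blank",
             "age_cal_ka_bp": float("nan")}
            for b in blanks
        ]
        return pd.DataFrame(rows)

    def test_published_scale_blank_fraction(self, chain_tree):
        # 45 blank viral reads against a 357161 viral total -> 0.013 %
        cm = _cm([3], ["s1", "b1"], [[357161 - 45, 45]], mode="cumulative")
        res = blank_summary(cm, self._meta(["s1"], ["b1"]), 3)
        assert res.blank_reads == 45
        assert res.fraction_pct_rounded(2) == 0.013

    def test_all_blanks_clean(self, chain_tree):
        cm = _cm([3], ["s1", "b1", "b2"], [[10, 0, 0]], mode="cumulative")
        res = blank_summary(cm, self._meta(["s1"], ["b1", "b2"]), 3)
        assert res.fraction_pct == 0.0
        assert res.clean_blanks == 2

    def test_extreme_contamination(self, chain_tree):
        cm = _cm([3], ["s1", "b1"], [[0, 9]], mode="cumulative")
        res = blank_summary(cm, self._meta(["s1"], ["b1"]), 3)
        assert res.fraction_pct == 100.0

    def test_no_blanks_is_error(self, chain_tree):
        cm = _cm([3], ["s1"], [[5]], mode="cumulative")
        with pytest.raises(TableError, match="blank"):
            blank_summary(cm, self._meta(["s1"], []), 3)


def test_round_sig():
    assert round_sig(0.012594, 2) == 0.013
    assert round_sig(0.0, 2) == 0.0
    assert round_sig(123.4, 2) == 120.0
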