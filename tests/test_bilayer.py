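"""Interaction loading, e_uv / C(i)_uv scoring, ranking and pathway focus."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bilayernet import (InputError, InteractionTable,
                        export_association_heatmap_table,
                        interactions_from_pairs, load_interactions,
                        module_association, pathway_focus, rank_compounds)
from bilayernet.bilayer import write_contributions_tsv
from bilayernet.cs_network import CSNetwork
from bilayernet.tpt_network import EnrichmentResult, TPTNetwork


def make_cs(partition, edges=()):
    g = nx.Graph()
    g.add_nodes_from(partition)
    for a, b in edges:
        g.add_edge(a, b, tc=1.0, weight=1.0)
    return CSNetwork(graph=g, partition=dict(partition))


def make_tpt(partition, edges=()):
    g = nx.Graph()
    g.add_nodes_from(partition)
    for a, b in edges:
        g.add_edge(a, b, weight=1)
    return TPTNetwork(graph=g, partition=dict(partition))


class TestLoadInteractions:
    def _write(self, tmp_path, text):
        p = tmp_path / "it.tsv"
        p.write_text(text)
        return p

    def test_indicator_merges_sources(self, tmp_path):
        p = self._write(tmp_path,
                        "c1\tT1\tSEA\nc1\tT1\tTCMSP\n")
        it = load_interactions(p, weighting="indicator")
        assert len(it) == 1
        row = it.df.iloc[0]
        assert row["d"] == 1.0
        assert row["sources"] == {"SEA", "TCMSP"}

    def test_source_count_weighting(self, tmp_path):
        p = self._write(tmp_path, "c1\tT1\tSEA\nc1\tT1\tTCMSP\n")
        it = load_interactions(p, weighting="source_count")
        assert it.df.iloc[0]["d"] == 2.0

    def test_distinct_pairs_kept_separately(self, tmp_path):
        rows = "".join(f"c{i}\tT{i}\tSEA\n" for i in range(5))
        it = load_interactions(self._write(tmp_path, rows))
        assert len(it) == 5

    def test_malformed_rows_skipped(self, tmp_path, caplog):
        p = self._write(tmp_path, "c1\tT1\tSEA\nbroken_row\nc2\tT2\tSEA\n")
        with caplog.at_level("WARNING"):
            it = load_interactions(p)
        assert len(it) == 2
        assert any("malformed" in r.message for r in caplog.records)

    def test_unknown_source_kept_with_warning(self, tmp_path, caplog):
        p = self._write(tmp_path, "c1\tT1\tMystery\n")
        with caplog.at_level("WARNING"):
            it = load_interactions(p)
        assert len(it) == 1
        assert any("unknown predictor source" in r.message
                   for r in caplog.records)

    def test_header_line_tolerated(self, tmp_path):
        p = self._write(tmp_path, "compound\ttarget\tsource\nc1\tT1\tSEA\n")
        assert len(load_interactions(p)) == 1

    def test_bad_weighting_rejected(self, tmp_path):
        p = self._write(tmp_path, "c1\tT1\tSEA\n")
        with pytest.raises(ValueError, match="weighting"):
            load_interactions(p, weighting="bogus")


class TestModuleAssociation:
    def test_hand_worked_example(self):
        # m_u = {c1, c2}, m_v = {t1, t2}, indicator interactions
        # c1-t1, c2-t1, c2-t2  ->  e_uv = 3, C(c1) = 1, C(c2) = 2
        cs = make_cs({"c1": 1, "c2": 1}, edges=[("c1", "c2")])
        tpt = make_tpt({"t1": 1, "t2": 1}, edges=[("t1", "t2")])
        it = interactions_from_pairs(
            [("c1", "t1", "SEA"), ("c2", "t1", "SEA"), ("c2", "t2", "SEA")])
        ma = module_association(cs, tpt, it)
        assert ma.e.loc[1, 1] == 3.0
        assert ma.contribution("c1", 1, 1) == 1.0
        assert ma.contribution("c2", 1, 1) == 2.0

    def test_empty_cell_is_zero(self):
        cs = make_cs({"c1": 1, "c2": 2})
        tpt = make_tpt({"t1": 1, "t2": 2})
        it = interactions_from_pairs([("c1", "t1", "SEA")])
        ma = module_association(cs, tpt, it)
        assert ma.e.loc[2, 2] == 0.0
        assert ma.e.loc[1, 1] == 1.0

    def test_contributions_sum_to_e_uv(self):
        rng = np.random.default_rng(31)
        comps = [f"c{i}" for i in range(12)]
        targs = [f"t{i}" for i in range(9)]
        cs = make_cs({c: rng.integers(1, 4) for c in comps})
        tpt = make_tpt({t: rng.integers(1, 3) for t in targs})
        pairs = [(c, t, "SEA") for c in comps for t in targs
                 if rng.random() < 0.4]
        ma = module_association(cs, tpt, interactions_from_pairs(pairs))
        for u in ma.e.index:
            for v in ma.e.columns:
                sel = ma.contributions
                total = sel[(sel["u"] == u) & (sel["v"] == v)]["C"].sum()
                assert total == pytest.approx(ma.e.loc[u, v])

    def test_conservation_of_total_weight(self):
        cs = make_cs({"c1": 1, "c2": 2})
        tpt = make_tpt({"t1": 1, "t2": 2})
        it = interactions_from_pairs(
            [("c1", "t1", "SEA"), ("c1", "t2", "SEA"), ("c2", "t2", "SEA")],
            weighting="source_count")
        ma = module_association(cs, tpt, it)
        assert ma.e.values.sum() == pytest.approx(it.total_weight)

    def test_off_layer_rows_excluded(self):
        cs = make_cs({"c1": 1})
        tpt = make_tpt({"t1": 1})
        it = interactions_from_pairs(
            [("c1", "t1", "SEA"), ("c_gone", "t1", "SEA"),
             ("c1", "t_gone", "SEA")])
        ma = module_association(cs, tpt, it)
        assert ma.e.values.sum() == 1.0
        assert ma.n_excluded == {"compound_not_in_cs": 1,
                                 "target_not_in_tpt": 1}

    def test_no_join_is_fatal(self):
        cs = make_cs({"c1": 1})
        tpt = make_tpt({"t1": 1})
        it = interactions_from_pairs([("other", "t1", "SEA")])
        with pytest.raises(InputError, match="no interaction joins"):
            module_association(cs, tpt, it)

    def test_merging_modules_adds_rows(self):
        """Coarsening the compound partition adds e rows elementwise."""
        rng = np.random.default_rng(8)
        comps = [f"c{i}" for i in range(10)]
        targs = [f"t{i}" for i in range(6)]
        part = {c: rng.integers(1, 4) for c in comps}
        tpt = make_tpt({t: rng.integers(1, 3) for t in targs})
        pairs = [(c, t, "SEA") for c in comps for t in targs
                 if rng.random() < 0.5]
        it = interactions_from_pairs(pairs)
        ma_fine = module_association(make_cs(part), tpt, it)
        merged = {c: (1 if part[c] in (1, 2) else 2) for c in comps}
        ma_coarse = module_association(make_cs(merged), tpt, it)
        want = ma_fine.e.reindex(index=[1, 2, 3], fill_value=0.0)
        for v in ma_coarse.e.columns:
            assert ma_coarse.e.loc[1, v] == pytest.approx(
                want.loc[1, v] + want.loc[2, v])
            assert ma_coarse.e.loc[2, v] == pytest.approx(want.loc[3, v])


class TestRankCompounds:
    def _ma(self):
        cs = make_cs({"c1": 1, "c2": 1, "c3": 1},
                     edges=[("c1", "c2"), ("c1", "c3"), ("c2", "c3")])
        tpt = make_tpt({"t1": 1, "t2": 1})
        it = interactions_from_pairs(
            [("c1", "t1", "SEA"), ("c2", "t1", "SEA"), ("c2", "t2", "SEA")])
        return module_association(cs, tpt, it)

    def test_top_1(self):
        top = rank_compounds(self._ma(), 1, 1, k=1)
        assert list(top["compound"]) == ["c2"]
        assert top.iloc[0]["C"] == 2.0

    def test_zero_contribution_members_included(self):
        top = rank_compounds(self._ma(), 1, 1, k=5)
        assert list(top["compound"]) == ["c2", "c1", "c3"]
        assert top.iloc[2]["C"] == 0.0

    def test_ties_broken_by_degree_then_id(self):
        cs = make_cs({"c1": 1, "c2": 1, "c3": 1},
                     edges=[("c1", "c2"), ("c2", "c3")])  # deg: 1, 2, 1
        tpt = make_tpt({"t1": 1, "t2": 1, "t3": 1})
        it = interactions_from_pairs(
            [(c, t, "SEA") for c in ("c1", "c2", "c3") for t in ("t1",)])
        ma = module_association(cs, tpt, it)
        top = rank_compounds(ma, 1, 1, k=3)
        assert list(top["compound"]) == ["c2", "c1", "c3"]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rank_compounds(self._ma(), 1, 1, k=0)

    def test_missing_pair_rejected(self):
        with pytest.raises(InputError, match="module pair"):
            rank_compounds(self._ma(), 7, 1, k=1)

    def test_normalized_scores_sum_to_one(self):
        top = rank_compounds(self._ma(), 1, 1, k=5, normalized=True)
        assert top["C"].sum() == pytest.approx(1.0)


def _enr(pid, name, members):
    return EnrichmentResult(pathway_id=pid, name=name, overlap=len(members),
                            pathway_size=len(members), query_size=10,
                            background_size=100, p=1e-4,
                            overlap_members=frozenset(members))


class TestPathwayFocus:
    def _setup(self, t3_module=1):
        cs = make_cs({"c1": 1, "c2": 2})
        tpt = make_tpt({"t1": 1, "t2": 1, "t3": t3_module})
        it = interactions_from_pairs(
            [("c1", "t1", "SEA"), ("c1", "t3", "SEA"), ("c2", "t2", "SEA")])
        ma = module_association(cs, tpt, it)
        return ma, tpt

    def test_single_module_pathway_highlights_one_column(self):
        ma, tpt = self._setup(t3_module=1)
        enriched = [_enr("pw1", "focus", {"t1", "t3"})]
        focus = pathway_focus(ma, tpt, enriched, "focus")
        assert focus.target_modules == [1]
        assert focus.compound_modules == [1]
        assert list(focus.ranking["compound"]) == ["c1"]
        assert focus.ranking.iloc[0]["C_restricted"] == 2.0

    def test_split_pathway_highlights_two_columns(self):
        ma, tpt = self._setup(t3_module=2)
        enriched = [_enr("pw1", "focus", {"t1", "t3"})]
        focus = pathway_focus(ma, tpt, enriched, "focus")
        assert focus.target_modules == [1, 2]
        assert set(focus.cells) == {(1, 1), (1, 2)}

    def test_unenriched_pathway_named_in_error(self):
        ma, tpt = self._setup()
        with pytest.raises(InputError, match="ghost"):
            pathway_focus(ma, tpt, [_enr("pw1", "focus", {"t1"})], "ghost")


class TestHeatmapExport:
    def test_two_by_two_roundtrip(self, tmp_path):
        cs = make_cs({"c1": 1, "c2": 2})
        tpt = make_tpt({"t1": 1, "t2": 2})
        it = interactions_from_pairs(
            [("c1", "t1", "SEA"), ("c2", "t2", "SEA"), ("c2", "t1", "SEA")])
        ma = module_association(cs, tpt, it)
        out = tmp_path / "e.tsv"
        table = export_association_heatmap_table(ma, out)
        assert table.shape == (2, 2)
        back = pd.read_csv(out, sep="\t", index_col=0)
        assert list(back.columns) == ["TPT_Module_1", "TPT_Module_2"]
        for u, row_name in enumerate(back.index, start=1):
            for v, col in enumerate(back.columns, start=1):
                assert back.loc[row_name, col] == ma.e.loc[u, v]

    def test_zero_matrix(self):
        cs = make_cs({"c1": 1, "c2": 2})
        tpt = make_tpt({"t1": 1, "t2": 2})
        it = interactions_from_pairs([("c1", "t1", "SEA")])
        ma = module_association(cs, tpt, it)
        ma.e.loc[:, :] = 0.0
        table = export_association_heatmap_table(ma)
        assert (table.values == 0).all()

    def test_contributions_tsv_has_ranks(self, tmp_path):
        cs = make_cs({"c1": 1, "c2": 1})
        tpt = make_tpt({"t1": 1})
        it = interactions_from_pairs(
            [("c1", "t1", "SEA"), ("c2", "t1", "SEA"), ("c2", "t1", "TCMSP")])
        ma = module_association(cs, tpt, it)
        out = tmp_path / "contrib.tsv"
        n = write_contributions_tsv(ma, out)
        df = pd.read_csv(out, sep="\t")
        assert n == len(df) == 2
        assert set(df.columns) == {"compound", "m_u", "m_v", "C", "rank"}
        assert list(df.sort_values("rank")["rank"]) == [1, 2]
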