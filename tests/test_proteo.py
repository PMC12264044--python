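"""Proteomics stage: replicate collapse, imputation, DE, pathways, scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spleenniche import proteo as pr
from spleenniche import synthgeom as sg
from spleenniche.synthgeom import AbundanceMatrix


def make_matrix(values: dict[str, list], cell_types: list[str],
                bioreps: list[int], techreps: list[int] | None = None
                ) -> AbundanceMatrix:
    vals = pd.DataFrame(values).T
    cols = []
    for i, (ct, b) in enumerate(zip(cell_types, bioreps)):
        t = techreps[i] if techreps else 1
        cols.append(f"{ct}_{b}_{t}")
    vals.columns = cols
    samples = pd.DataFrame({
        "cell_type": cell_types,
        "biorep": bioreps,
        "techrep": techreps or [1] * len(cols),
    }, index=pd.Index(cols, name="sample"))
    return AbundanceMatrix(values=vals, samples=samples)


class TestCollapseTechnical:
    def test_mean_ignores_missing_runs(self):
        m = make_matrix({"P1": [10.0, 20.0, np.nan]},
                        ["A", "A", "A"], [1, 1, 1], [1, 2, 3])
        out = pr.collapse_technical(m)
        assert out.values.loc["P1", "A_1"] == 15.0

    def test_all_runs_missing_stays_missing(self):
        m = make_matrix({"P1": [np.nan, np.nan, np.nan]},
                        ["A", "A", "A"], [1, 1, 1], [1, 2, 3])
        out = pr.collapse_technical(m)
        assert np.isnan(out.values.loc["P1", "A_1"])

    def test_single_run_is_identity(self):
        m = make_matrix({"P1": [7.0]}, ["A"], [1], [1])
        out = pr.collapse_technical(m)
        assert out.values.loc["P1", "A_1"] == 7.0

    def test_unbalanced_replication_raises(self):
        m = make_matrix({"P1": [1.0, 2.0, 3.0]},
                        ["A", "A", "B"], [1, 1, 1], [1, 2, 1])
        with pytest.raises(pr.LabelError):
            pr.collapse_technical(m)


class TestImputeLowest:
    def test_global_minimum_fills_missing(self):
        m = make_matrix({"P1": [4.0, np.nan], "P2": [9.0, 11.0]},
                        ["A", "B"], [1, 1])
        out = pr.impute_lowest(m)
        assert out.values.loc["P1"].tolist() == [4.0, 4.0]
        assert out.values.loc["P2"].tolist() == [9.0, 11.0]

    def test_idempotent_and_minimum_preserving(self):
        m = make_matrix({"P1": [4.0, np.nan], "P2": [np.nan, 11.0]},
                        ["A", "B"], [1, 1])
        once = pr.impute_lowest(m)
        twice = pr.impute_lowest(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert once.values.min().min() == m.values.min().min()

    def test_per_protein_scope(self):
        m = make_matrix({"P1": [4.0, np.nan], "P2": [np.nan, 11.0]},
                        ["A", "B"], [1, 1])
        out = pr.impute_lowest(m, scope="protein")
        assert out.values.loc["P1", "B_1_1"] == 4.0
        assert out.values.loc["P2", "A_1_1"] == 11.0

    def test_all_missing_raises(self):
        m = make_matrix({"P1": [np.nan, np.nan]}, ["A", "B"], [1, 1])
        with pytest.raises(pr.ImputationError):
            pr.impute_lowest(m)


class TestDifferentialAbundance:
    def _paired(self, a_vals, b_vals):
        values = {}
        for i, (av, bv) in enumerate(zip(a_vals, b_vals)):
            values[f"P{i}"] = list(av) + list(bv)
        ct = ["A"] * len(a_vals[0]) + ["B"] * len(b_vals[0])
        reps = list(range(1, len(a_vals[0]) + 1)) + \
            list(range(1, len(b_vals[0]) + 1))
        return make_matrix(values, ct, reps)

    def test_identical_groups_yield_null_table(self):
        m = self._paired([(3.0, 4.0, 5.0)], [(3.0, 4.0, 5.0)])
        de = pr.differential_abundance(m, "A", "B")
        assert de["log2fc"].iloc[0] == 0.0
        assert not de["enriched"].any()

    def test_fourfold_ratio_has_log2fc_2(self):
        m = self._paired([(4.0, 4.0, 4.0)], [(1.0, 1.0, 1.0)])
        de = pr.differential_abundance(m, "A", "B")
        assert de["log2fc"].iloc[0] == pytest.approx(2.0)
        assert de["enriched_up"].iloc[0]

    def test_threshold_is_strictly_greater_than_2(self):
        m = self._paired([(2.0, 2.0, 2.0)], [(1.0, 1.0, 1.0)])
        de = pr.differential_abundance(m, "A", "B")
        assert de["log2fc"].iloc[0] == pytest.approx(1.0)
        assert not de["enriched"].any()   # FC == 2 does not pass FC > 2

    def test_swapping_groups_negates_fold_changes(self, rng):
        vals = [(tuple(rng.lognormal(3, 0.3, 3)), tuple(rng.lognormal(3, 0.3, 3)))
                for _ in range(20)]
        m = self._paired([v[0] for v in vals], [v[1] for v in vals])
        ab = pr.differential_abundance(m, "A", "B")
        ba = pr.differential_abundance(m, "B", "A")
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"])
        np.testing.assert_allclose(ab["p_adj"], ba["p_adj"])

    def test_adjusted_p_dominates_raw_p(self, rng):
        m = sg.simulate_abundance(300, {"A": 4, "B": 4}, missing_rate=0.0,
                                  seed=8)
        de = pr.differential_abundance(m, "A", "B")
        assert (de["p_adj"] >= de["p"] - 1e-12).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=60))
    def test_bh_stepup_is_monotone_in_raw_p(self, pvals):
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(np.asarray(pvals), method="fdr_bh")
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_too_few_samples_raises(self):
        m = self._paired([(3.0,)], [(4.0, 5.0)])
        with pytest.raises(pr.DesignError):
            pr.differential_abundance(m, "A", "B")

    def test_moderated_mode_recovers_planted_effects(self):
        eff = pd.DataFrame({"A": [2.0] * 40},
                           index=[f"P{i:05d}" for i in range(40)])
        m = sg.simulate_abundance(400, {"A": 6, "B": 6}, effects=eff,
                                  missing_rate=0.0, seed=9)
        de = pr.differential_abundance(m, "A", "B", moderated=True)
        truth = m.truth["A"] != 0
        called = de["enriched_up"]
        assert (called & truth).sum() / truth.sum() >= 0.9


class TestSetsAndSecretome:
    def test_venn_counts_example(self):
        def table(members, universe=("a", "b", "c", "d")):
            return pd.DataFrame({"enriched": [u in members for u in universe]},
                                index=list(universe))
        out = pr.pairwise_sets({"X": table({"a", "b"}), "Y": table({"b", "c"}),
                                "Z": table(set())})
        c = out["counts"]
        assert (c["X"], c["Y"], c["Z"]) == (1, 1, 0)
        assert (c["X&Y"], c["X&Z"], c["Y&Z"]) == (1, 0, 0)
        assert c["X&Y&Z"] == 0

    def test_identical_sets_concentrate_in_triple(self):
        t = pd.DataFrame({"enriched": [True, True]}, index=["a", "b"])
        out = pr.pairwise_sets({"X": t, "Y": t.copy(), "Z": t.copy()})
        assert out["counts"]["X&Y&Z"] == 2
        assert out["counts"]["X"] == 0

    def test_secretome_intersection(self):
        ann = pr.AnnotationBundle(secretory={"P2": True, "P3": False},
                                  pathways=pd.DataFrame(), lr_pairs=pd.DataFrame())
        assert pr.secretome_subset({"P1", "P2"}, ann) == {"P2"}
        assert pr.secretome_subset(set(), ann) == set()
        ann_all = pr.AnnotationBundle(secretory={"P1": True, "P2": True},
                                      pathways=pd.DataFrame(),
                                      lr_pairs=pd.DataFrame())
        assert pr.secretome_subset({"P1", "P2"}, ann_all) == {"P1", "P2"}


class TestPathwayClasses:
    def _ann(self, mapping):
        rows = [dict(protein=p, pathway_id=pid)
                for pid, members in mapping.items() for p in members]
        return pr.AnnotationBundle(secretory={}, pathways=pd.DataFrame(rows),
                                   lr_pairs=pd.DataFrame())

    def test_three_way_classification(self):
        ann = self._ann({"pw1": ["L1", "R1"], "pw2": ["L1", "L2", "R2"],
                         "pw3": ["L2", "R3"]})
        out = pr.pathway_classes({"L1"}, {"L2"}, {"R1", "R2", "R3"}, ann)
        got = out.set_index("pathway_id")["class"]
        assert got["pw1"] == "CTM_only"
        assert got["pw2"] == "common"
        assert got["pw3"] == "STC_only"

    def test_no_secretome_yields_neither(self):
        ann = self._ann({"pw1": ["R1"]})
        out = pr.pathway_classes(set(), set(), {"R1"}, ann)
        assert (out["class"] == "neither").all()

    def test_planted_split_recovered_exactly(self):
        # 10 LSK pathways planted as 7 CTM-only : 1 common : 2 STC-only
        mapping, ctm, stc, lsk = {}, set(), set(), set()
        for i in range(10):
            lig_c, lig_s, rec = f"C{i}", f"S{i}", f"R{i}"
            lsk.add(rec)
            members = [rec]
            if i < 7:
                members.append(lig_c)
                ctm.add(lig_c)
            elif i < 8:
                members += [lig_c, lig_s]
                ctm.add(lig_c)
                stc.add(lig_s)
            else:
                members.append(lig_s)
                stc.add(lig_s)
            mapping[f"pw{i}"] = members
        out = pr.pathway_classes(ctm, stc, lsk, self._ann(mapping))
        counts = out["class"].value_counts()
        assert counts["CTM_only"] == 7
        assert counts["common"] == 1
        assert counts["STC_only"] == 2

    def test_empty_pathway_map_raises(self):
        ann = pr.AnnotationBundle(secretory={}, pathways=pd.DataFrame(),
                                  lr_pairs=pd.DataFrame())
        with pytest.raises(pr.AnnotationError):
            pr.pathway_classes(set(), set(), set(), ann)


class TestInteractionScores:
    def test_score_is_mean_of_sender_and_receiver_means(self):
        m = make_matrix({"L": [16.0, 16.0, 4.0, 4.0],
                         "R": [1.0, 1.0, 4.0, 4.0]},
                        ["CTM", "CTM", "LSK", "LSK"], [1, 2, 1, 2])
        lr = pd.DataFrame({"ligand": ["L"], "receptor_monomers": ["R"]})
        out = pr.interaction_scores(m, lr, "CTM", n_perm=100, seed=0)
        # ligand mean log2 in CTM = 4, receptor mean log2 in LSK = 2 → 3.0
        assert out["score"].iloc[0] == pytest.approx(3.0)

    def test_dimer_takes_minimum_over_monomers(self):
        m = make_matrix({"L": [16.0, 16.0, 4.0, 4.0],
                         "Ra": [4.0, 4.0, 16.0, 16.0],
                         "Rb": [4.0, 4.0, 4.0, 4.0]},
                        ["CTM", "CTM", "LSK", "LSK"], [1, 2, 1, 2])
        lr = pd.DataFrame({"ligand": ["L"], "receptor_monomers": ["Ra;Rb"]})
        out = pr.interaction_scores(m, lr, "CTM", n_perm=100, seed=0)
        assert out["score"].iloc[0] == pytest.approx(0.5 * (4.0 + 2.0))

    def test_exchangeable_samples_give_p_of_one(self):
        m = make_matrix({"L": [8.0] * 6, "R": [8.0] * 6},
                        ["CTM"] * 3 + ["LSK"] * 3, [1, 2, 3, 1, 2, 3])
        lr = pd.DataFrame({"ligand": ["L"], "receptor_monomers": ["R"]})
        out = pr.interaction_scores(m, lr, "CTM", n_perm=200, seed=1)
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1 / 200)

    def test_planted_ctm_specific_pair_is_significant(self):
        eff = pd.DataFrame({"CTM": [3.0]}, index=["P00000"])  # 8-fold ligand
        m = sg.simulate_abundance(100, {"CTM": 6, "STC": 6, "LSK": 6},
                                  effects=eff, missing_rate=0.0, seed=2)
        imp = pr.impute_lowest(pr.collapse_technical(m))
        lr = pd.DataFrame({"ligand": ["P00000"],
                           "receptor_monomers": ["P00050"]})
        ctm = pr.interaction_scores(imp, lr, "CTM", n_perm=1000, seed=3)
        stc = pr.interaction_scores(imp, lr, "STC", n_perm=1000, seed=3)
        assert ctm["p"].iloc[0] < 0.05
        assert ctm["score"].iloc[0] > stc["score"].iloc[0]

    def test_deterministic_and_order_invariant(self):
        m = sg.simulate_abundance(50, {"CTM": 4, "STC": 4, "LSK": 4},
                                  missing_rate=0.0, seed=4)
        imp = pr.impute_lowest(m)
        shuffled = AbundanceMatrix(
            values=imp.values[imp.values.columns[::-1]],
            samples=imp.samples.iloc[::-1], truth=imp.truth)
        lr = pd.DataFrame({"ligand": ["P00001"], "receptor_monomers": ["P00002"]})
        a = pr.interaction_scores(imp, lr, "CTM", n_perm=300, seed=5)
        b = pr.interaction_scores(shuffled, lr, "CTM", n_perm=300, seed=5)
        assert a["score"].iloc[0] == pytest.approx(b["score"].iloc[0])
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0])

    def test_undetected_partner_is_dropped(self):
        m = make_matrix({"L": [np.nan, np.nan, 4.0, 4.0],
                         "R": [1.0, 1.0, 4.0, 4.0]},
                        ["CTM", "CTM", "LSK", "LSK"], [1, 2, 1, 2])
        lr = pd.DataFrame({"ligand": ["L"], "receptor_monomers": ["R"]})
        out = pr.interaction_scores(m, lr, "CTM", n_perm=100, seed=0)
        assert len(out) == 0
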