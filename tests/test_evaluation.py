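import math

import numpy as np
import pandas as pd
import pytest

from allophase.evaluation import (BestHitReport, best_hit_fraction,
                                  compare_assignments, concordance,
                                  fractionation_profile, label_accuracy,
                                  random_sort)
from allophase.phylo import AssignmentTable, consensus_tree, gene_tree_from_newick


def table_from(labels, species="S", length=100, evidence="phylogeny"):
    return AssignmentTable.from_labels(
        species, {c: length for c in labels}, labels, evidence)


class TestRandomSort:
    def test_single_label_input_unchanged(self):
        t = table_from({"c1": "A", "c2": "A"})
        ctrl, mapping = random_sort(t, [[("S", "c1"), ("S", "c2")]], seed=5)
        assert set(mapping.values()) == {"1"}

    def test_label_multiset_preserved_per_group(self):
        t = table_from({f"c{i}": l for i, l in enumerate("ABCABC")})
        groups = [[("S", f"c{i}") for i in range(3)],
                  [("S", f"c{i}") for i in range(3, 6)]]
        for seed in range(10):
            ctrl, mapping = random_sort(t, groups, seed=seed)
            for g in groups:
                labs = sorted(mapping[m] for m in g)
                assert labs == ["1", "2", "3"]

    def test_seeded_determinism(self):
        t = table_from({f"c{i}": l for i, l in enumerate("ABC")})
        g = [[("S", f"c{i}") for i in range(3)]]
        m1 = random_sort(t, g, seed=3)[1]
        m2 = random_sort(t, g, seed=3)[1]
        assert m1 == m2

    def test_shuffle_probability_over_seeds(self):
        """With 7 groups of 3 labels the chance that every group keeps its
        true labels is (1/6)^7; over 20 seeds at least one group must be
        shuffled every time."""
        labels = {}
        groups = []
        for g in range(7):
            groups.append([("S", f"c{g}_{j}") for j in range(3)])
            for j, l in enumerate("ABC"):
                labels[f"c{g}_{j}"] = l
        t = table_from(labels)
        to_int = {"A": "1", "B": "2", "C": "3"}
        for seed in range(20):
            _, mapping = random_sort(t, groups, seed=seed)
            identity = all(mapping[("S", f"c{g}_{j}")] == to_int["ABC"[j]]
                           for g in range(7) for j in range(3))
            assert not identity

    def test_incomplete_group_rejected(self):
        t = table_from({"c1": "A"})
        with pytest.raises(ValueError, match="no assignment"):
            random_sort(t, [[("S", "c1"), ("S", "ghost")]], seed=0)

    def test_evidence_tag_is_random(self):
        t = table_from({"c1": "A", "c2": "B"})
        ctrl, _ = random_sort(t, [[("S", "c1"), ("S", "c2")]], seed=1)
        assert all(r.evidence == "random" for r in ctrl.rows)


class TestConcordance:
    def test_all_trees_equal_reference(self):
        nwk = "((A,B),(C,Out));"
        trees = [gene_tree_from_newick(nwk)] * 6
        ref = consensus_tree(trees, outgroup="Out")
        res = concordance(trees, ref)
        assert all(v == 100.0 for v in res["per_branch"].values())
        assert res["overall"] == 100.0

    def test_five_of_seven_branch(self):
        trees = [gene_tree_from_newick("((A,D),(B,Out));")] * 5 + \
                [gene_tree_from_newick("((A,B),(D,Out));")] * 2
        ref = consensus_tree(trees, outgroup="Out")
        res = concordance(trees, ref)
        (val,) = res["per_branch"].values()
        assert val == pytest.approx(100 * 5 / 7, abs=0.05)

    def test_invariant_to_tree_order(self):
        trees = [gene_tree_from_newick("((A,D),(B,Out));")] * 5 + \
                [gene_tree_from_newick("((A,B),(D,Out));")] * 2
        ref = consensus_tree(trees, outgroup="Out")
        r1 = concordance(trees, ref)
        r2 = concordance(list(reversed(trees)), ref)
        assert r1["per_branch"] == r2["per_branch"]


class TestBestHits:
    def test_verbatim_copy_hits_source(self):
        prots = {f"g{i}": "MKLVNNPQRSTWYFA"[i:] * 3 + "MKLVNNPQRSTWYFA"
                 for i in range(5)}
        other = {f"h{i}": "GGGHHHIIIKKKWWW" * 3 for i in range(5)}
        rep = best_hit_fraction({"sub1": dict(prots)},
                                {"PA": prots, "PB": other})
        assert rep.percent_of_all.at["sub1", "PA"] == 100.0
        assert rep.percent_of_all.at["sub1", "PB"] == 0.0

    def test_simulated_diagonal_dominates(self, wheat_bundle):
        gc = wheat_bundle.complexes["TT"]
        progs = {}
        for lab, sim in wheat_bundle.progenitors.items():
            from allophase.synthetic import render
            pgc, _ = render(sim)
            progs[lab] = pgc.proteins
        subs = {}
        for g in gc.genes:
            lab = g.chromosome[-1]
            subs.setdefault(lab, {})[g.gene_id] = gc.proteins[g.gene_id]
        rep = best_hit_fraction(subs, progs)
        for sub in ("A", "B"):
            own = rep.percent_of_hit.at[sub, sub]
            for other in rep.percent_of_hit.columns:
                if other != sub:
                    assert own > rep.percent_of_hit.at[sub, other]

    def test_identical_progenitors_all_ambiguous(self):
        prots = {"g1": "MKLVNNPQRSTWYFA" * 3}
        with pytest.warns(UserWarning, match="ambiguous"):
            rep = best_hit_fraction({"s": prots},
                                    {"P1": prots, "P2": dict(prots)})
        assert rep.ambiguous["s"] == 1
        assert rep.percent_of_all.loc["s"].sum() == 0.0

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            best_hit_fraction({"s": {}}, {"P": {"g": "MKL" * 10}})


class TestCompareAssignments:
    def test_identical_tables_full_agreement(self):
        t = table_from({"c1": "A", "c2": "B"})
        rep = compare_assignments(t, t)
        assert rep.percent_agreement == 100.0
        assert rep.segments.agree.all()

    def test_permuted_labels_match_after_mapping(self):
        a = table_from({"c1": "A", "c2": "B", "c3": "A"})
        b = table_from({"c1": "x", "c2": "y", "c3": "x"})
        rep = compare_assignments(a, b)
        assert rep.percent_agreement == 100.0
        assert rep.label_mapping == {"x": "A", "y": "B"}

    def test_disjoint_chromosomes_rejected(self):
        a = table_from({"c1": "A"})
        b = table_from({"c9": "A"})
        with pytest.raises(ValueError, match="different chromosome"):
            compare_assignments(a, b)

    def test_disagreement_localised_to_modified_span(self):
        a = table_from({"c1": "A", "c2": "B"})
        b = table_from({"c1": "A", "c2": "B"})
        b.set_span("S", "c1", 40, 60, "B", "kmer")
        rep = compare_assignments(a, b)
        bad = rep.segments[~rep.segments.agree]
        assert list(bad[["start", "end"]].itertuples(index=False, name=None)) \
            == [(40, 60)]
        assert rep.percent_agreement == pytest.approx(90.0)


class TestLabelAccuracy:
    def test_relative_pair_counts_as_correct(self):
        truth = table_from({"c1": "T1", "c2": "T2", "c3": "V"})
        pred = table_from({"c1": "2", "c2": "1", "c3": "3"})
        # force a crossed matching by giving the pair swapped majorities
        acc_strict = label_accuracy(pred, truth)
        acc_rel = label_accuracy(pred, truth, relative_pairs=[("T1", "T2")])
        assert acc_rel == 1.0
        assert acc_strict == 1.0  # Hungarian already aligns a clean bijection

    def test_per_group_inconsistent_sisters_still_score(self):
        truth = table_from({"c1": "T1", "c2": "T2", "c3": "T1", "c4": "T2"})
        pred = table_from({"c1": "1", "c2": "2", "c3": "2", "c4": "1"})
        assert label_accuracy(pred, truth) == 0.5
        assert label_accuracy(pred, truth,
                              relative_pairs=[("T1", "T2")]) == 1.0


class TestFractionation:
    def _matrix(self, present):
        idx = [f"o{i}" for i in range(len(next(iter(present.values()))))]
        df = pd.DataFrame({c: ["g" if p else None for p in v]
                           for c, v in present.items()}, index=idx)
        df.insert(0, "outgroup_gene", idx)
        df["outgroup_chromosome"] = "c1"
        return df

    def test_no_deletions_all_ones(self):
        gm = self._matrix({"S|A": [1] * 40, "S|B": [1] * 40})
        prof = fractionation_profile(gm, window_genes=10, step_genes=5)
        assert (prof.frame.to_numpy() == 1.0).all()

    def test_biased_column_detected(self, rng):
        keep = rng.random(400) > 0.2
        gm = self._matrix({"S|A": list(keep), "S|B": [1] * 400})
        prof = fractionation_profile(gm, window_genes=50, step_genes=10)
        means = prof.column_means()
        assert means["S|B"] == 1.0
        assert abs(means["S|A"] - 0.8) < 3 * math.sqrt(0.2 * 0.8 / 400)

    def test_equal_fractionation_not_separable(self, rng):
        cols = {}
        for c in ("S|A", "S|B", "S|C"):
            cols[c] = list(rng.random(500) > 0.2)
        prof = fractionation_profile(self._matrix(cols), 50, 10)
        means = prof.column_means()
        sd = math.sqrt(0.2 * 0.8 / 500)
        for c in cols:
            assert abs(means[c] - 0.8) < 3 * sd

    def test_bad_window_rejected(self):
        gm = self._matrix({"S|A": [1] * 10})
        with pytest.raises(ValueError):
            fractionation_profile(gm, window_genes=0)
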