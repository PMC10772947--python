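import numpy as np
import pytest

from allophase.kmer_phasing import (GroupingError, KmerError, KmerMatrix,
                                    call_exchanges, canonical,
                                    cluster_subgenomes, count_kmers,
                                    encode_kmer, project_pca, relabel_kmers,
                                    rerun_subset, scan_windows,
                                    select_differential, DifferentialKmerSet,
                                    WindowEnrichment)


class TestCounting:
    def test_worked_example_acgtt(self):
        m = count_kmers({"c": "ACGTT"}, 3)
        assert m.string_counts("c") == {"ACG": 2, "AAC": 1}

    def test_canonicalisation_matches_bruteforce(self):
        import itertools, random
        r = random.Random(5)
        seq = "".join(r.choice("ACGT") for _ in range(300))
        m = count_kmers({"c": seq}, 5)
        brute = {}
        for i in range(len(seq) - 4):
            km = canonical(seq[i:i + 5])
            brute[km] = brute.get(km, 0) + 1
        assert m.string_counts("c") == brute
        assert sum(brute.values()) == len(seq) - 4

    def test_ambiguous_bases_skipped(self):
        m = count_kmers({"c": "N" * 50}, 13)
        assert m.counts["c"] == {}

    def test_even_k_rejected(self):
        with pytest.raises(KmerError, match="odd"):
            count_kmers({"c": "ACGT"}, 10)


def _matrix(counts, lengths=None, k=13):
    lengths = lengths or {c: 1_000_000 for c in counts}
    coded = {c: {encode_kmer("A" * 6 + "C" * 7) if km == "x" else encode_kmer(km): n
                 for km, n in d.items()} for c, d in counts.items()}
    return KmerMatrix(k=k, counts=coded, chromosome_lengths=lengths)


class TestDifferentialSelection:
    def test_tenfold_kmer_retained(self):
        m = _matrix({"1A": {"x": 100}, "1B": {"x": 10},
                     "2A": {"x": 100}, "2B": {"x": 10}})
        d = select_differential(m, [["1A", "1B"], ["2A", "2B"]],
                                min_fold=2, min_freq=10)
        assert len(d.kmers) == 1
        norm = d.normalized()
        assert norm.iloc[:, 0]["1A"] > norm.iloc[:, 0]["1B"]

    def test_below_fold_rejected(self):
        m = _matrix({"1A": {"x": 3}, "1B": {"x": 2},
                     "2A": {"x": 3}, "2B": {"x": 2}})
        d = select_differential(m, [["1A", "1B"], ["2A", "2B"]],
                                min_fold=2, min_freq=2)
        assert d.kmers == []

    def test_min_freq_filters_rare(self):
        m = _matrix({"1A": {"x": 4}, "1B": {}, "2A": {"x": 4}, "2B": {}})
        d = select_differential(m, [["1A", "1B"], ["2A", "2B"]],
                                min_fold=2, min_freq=10)
        assert d.kmers == []

    def test_small_group_rejected(self):
        m = _matrix({"1A": {"x": 10}})
        with pytest.raises(GroupingError):
            select_differential(m, [["1A"]])

    def test_injected_lineage_motifs_recovered(self, wheat_bundle):
        """Every lineage-specific k-mer found by exhaustive set difference
        on the simulated genomes is retained with the correct label."""
        gc = wheat_bundle.complexes["TT"]
        m = count_kmers(gc.chromosomes, 13)
        groups = wheat_bundle.groups["TT"]
        d = select_differential(m, groups, min_fold=2, min_freq=10)
        labels, _ = cluster_subgenomes(d, 2, seed=0)
        relabel_kmers(d, labels)
        # exhaustive oracle: k-mers on all A chromosomes and no B chromosome
        a_chroms = [c for c in gc.chromosomes if c.endswith("A")]
        b_chroms = [c for c in gc.chromosomes if c.endswith("B")]
        inter_a = set.intersection(*(set(m.counts[c]) for c in a_chroms))
        union_b = set.union(*(set(m.counts[c]) for c in b_chroms))
        a_specific = {c for c in inter_a - union_b
                      if sum(m.counts[ch].get(c, 0) for ch in a_chroms) >= 10}
        selected = {encode_kmer(km) for km in d.kmers}
        assert a_specific <= selected
        a_label = labels[a_chroms[0]]
        for km in d.kmers:
            if encode_kmer(km) in a_specific:
                assert d.labels[km] == a_label


class TestClusteringAndPCA:
    def _diffset(self, rows):
        import pandas as pd
        frame = pd.DataFrame(rows).T.astype(float)
        frame.columns = [f"{'A'*10}CG{i}"[-13:] for i in range(frame.shape[1])]
        return DifferentialKmerSet(
            k=13, frame=frame,
            chromosome_lengths={c: 1_000_000 for c in frame.index})

    def test_two_cluster_partition_matches_exhaustive(self):
        """k-means labels agree with the exhaustive minimum within-cluster
        sum-of-squares 2-partition."""
        from itertools import combinations
        rows = {"A1": [100, 0], "A2": [90, 5], "B1": [2, 80], "B2": [0, 95]}
        d = self._diffset(rows)
        labels, _ = cluster_subgenomes(d, 2, seed=0)
        # exhaustive search over 2-partitions
        X = {c: np.array(v, dtype=float) for c, v in rows.items()}
        best, best_ss = None, np.inf
        chroms = sorted(rows)
        for r in range(1, 3):
            for left in combinations(chroms, r):
                right = [c for c in chroms if c not in left]
                ss = 0.0
                for side in (left, right):
                    pts = np.array([X[c] for c in side])
                    ss += ((pts - pts.mean(axis=0)) ** 2).sum()
                if ss < best_ss:
                    best, best_ss = set(left), ss
        got_partition = {c for c in chroms if labels[c] == labels["A1"]}
        assert got_partition in (best, set(chroms) - best)

    def test_identical_rows_degenerate_warning(self):
        d = self._diffset({"c1": [5, 5], "c2": [5, 5], "c3": [5, 5]})
        with pytest.warns(UserWarning, match="degenerate"):
            labels, _ = cluster_subgenomes(d, 2, seed=0)
        assert set(labels.values()) == {0}

    def test_seeded_determinism(self):
        rows = {f"c{i}": list(np.random.default_rng(i).integers(0, 50, 6))
                for i in range(6)}
        d = self._diffset(rows)
        l1, _ = cluster_subgenomes(d, 3, seed=9)
        l2, _ = cluster_subgenomes(d, 3, seed=9)
        assert l1 == l2

    def test_too_few_chromosomes(self):
        d = self._diffset({"c1": [1, 2]})
        with pytest.raises(KmerError):
            cluster_subgenomes(d, 2, seed=0)

    def test_pca_separates_true_subgenomes(self, wheat_bundle):
        gc = wheat_bundle.complexes["TT"]
        m = count_kmers(gc.chromosomes, 13)
        d = select_differential(m, wheat_bundle.groups["TT"])
        coords = project_pca(d)
        sign_a = {np.sign(coords.at[c, "pc1"]) for c in coords.index
                  if c.endswith("A")}
        sign_b = {np.sign(coords.at[c, "pc1"]) for c in coords.index
                  if c.endswith("B")}
        assert len(sign_a) == 1 and len(sign_b) == 1 and sign_a != sign_b
        assert coords["pc1"].var() >= coords["pc2"].var()

    def test_pca_duplicates_coincide_and_constant_at_origin(self):
        d = self._diffset({"c1": [10, 0], "c2": [10, 0], "c3": [0, 10]})
        coords = project_pca(d)
        assert np.allclose(coords.loc["c1"], coords.loc["c2"])
        dc = self._diffset({"c1": [5, 5], "c2": [5, 5], "c3": [5, 5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            coords2 = project_pca(dc)
        assert np.allclose(coords2.to_numpy(), 0.0)


class TestWindowsAndCalls:
    def test_window_inside_unbalanced_he_is_donor_enriched(self):
        from allophase.presets import build_preset
        from allophase.synthetic import ExchangeEvent, inject_exchange, render
        b = build_preset("wheat", seed=6)
        sim = b.sims["TT"]
        n = min(len(sim.chromosome("1A").genes),
                len(sim.chromosome("1B").genes))
        inject_exchange(sim, ExchangeEvent("unbalanced", "1B", "1A",
                                           (n - 12, n)))
        gc, _ = render(sim, b.config.species_tree)
        m = count_kmers(gc.chromosomes, 13)
        d = select_differential(m, b.groups["TT"])
        labels, _ = cluster_subgenomes(d, 2, seed=6)
        relabel_kmers(d, labels)
        windows = scan_windows(gc.chromosomes, d, window=2000, step=1000)
        b_label = labels["1B"]
        chrom_len = len(gc.chromosomes["1A"])
        inside = [w for w in windows if w.chromosome == "1A"
                  and w.start >= chrom_len - 4000]
        assert inside
        assert all(w.enriched_label == b_label for w in inside)
        cands = call_exchanges(windows, labels, min_consecutive=3)
        assert any(c.chromosome == "1A" and c.enriched_label == b_label
                   for c in cands)

    def test_null_calibration_uniform_genome(self):
        """On a uniform random genome with a synthetic differential set the
        fraction of significant windows stays near the binomial nominal
        level."""
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400_000))
        chroms = {"c1": seq[:200_000], "c2": seq[200_000:]}
        m = count_kmers(chroms, 13)
        # synthetic diffset: a random sample of k-mers actually present,
        # split between two pseudo-labels
        all_codes = sorted(set(m.counts["c1"]) | set(m.counts["c2"]))
        sample = list(rng.choice(len(all_codes), size=4000, replace=False))
        from allophase.kmer_phasing import decode_kmer
        import pandas as pd
        kms = [decode_kmer(all_codes[i], 13) for i in sample]
        frame = pd.DataFrame(
            {km: [m.counts["c1"].get(all_codes[i], 0),
                  m.counts["c2"].get(all_codes[i], 0)]
             for km, i in zip(kms, sample)}, index=["c1", "c2"], dtype=float)
        d = DifferentialKmerSet(k=13, frame=frame,
                                chromosome_lengths={c: len(s) for c, s
                                                    in chroms.items()})
        d.labels = {km: (0 if j % 2 == 0 else 1)
                    for j, km in enumerate(kms)}
        windows = scan_windows(chroms, d, window=1000, step=500, alpha=0.01)
        n_sig = sum(1 for w in windows if w.enriched_label is not None)
        assert len(windows) >= 700
        assert n_sig / len(windows) <= 0.02   # <= 2x nominal threshold

    def test_isolated_window_not_called(self):
        mk = lambda s, lab: WindowEnrichment("c", s, s + 10, {}, {}, {0: 2.0},
                                             {}, lab)
        windows = [mk(0, None), mk(10, 1), mk(20, None), mk(30, None)]
        assert call_exchanges(windows, {"c": 0}, min_consecutive=3) == []

    def test_consecutive_run_called_and_merged(self):
        mk = lambda s, lab: WindowEnrichment("c", s, s + 20, {}, {},
                                             {1: 3.0}, {}, lab)
        windows = [mk(i * 10, 1) for i in range(5)]
        (cand,) = call_exchanges(windows, {"c": 0}, min_consecutive=3)
        assert cand.start == 0 and cand.end == 60
        assert cand.n_windows == 5

    def test_missing_assignment_raises(self):
        w = WindowEnrichment("c", 0, 10, {}, {}, {}, {}, None)
        with pytest.raises(KeyError):
            call_exchanges([w], {}, 3)


class TestRerunSubset:
    def test_pair_rerun_recovers_at_least_full_run_kmers(self):
        """Re-selecting over a close pair only can only add pair-specific
        k-mers relative to the full run restricted to that pair."""
        from allophase.presets import build_preset
        b = build_preset("oat", seed=2)     # A and D are the close pair
        gc = b.complexes["AS"]
        m = count_kmers(gc.chromosomes, 13)
        groups = b.groups["AS"]
        d_full = select_differential(m, groups)
        labels, _ = cluster_subgenomes(d_full, 3, seed=2)
        relabel_kmers(d_full, labels)
        pair = (labels["1A"], labels["1D"])
        d_pair = rerun_subset(m, groups, labels, pair)
        full_restricted = {km for km, l in d_full.labels.items() if l in pair}
        assert len(d_pair.kmers) >= len(full_restricted)

    def test_unknown_label_rejected(self):
        m = _matrix({"1A": {"x": 50}, "1B": {"x": 5}})
        with pytest.raises(KmerError, match="unknown"):
            rerun_subset(m, [["1A", "1B"]], {"1A": 0, "1B": 1}, (0, 7))
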