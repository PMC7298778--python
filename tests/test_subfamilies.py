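"""Similarity links, Markov clustering, and profile construction."""

import numpy as np
import pytest

from caskit.simulate import generate_protein_families
from caskit.subfamilies import (ClusterParams, SimilarityRecord, build_collection,
                                build_profile_from_cluster, center_star_alignment,
                                cluster_family, link_criteria, mcl_cluster,
                                pairwise_similarity)


class TestPairwiseSimilarity:
    def test_self_alignment_full_coverage(self):
        seq = "MKVLACDEFGHIKWWYPQRST"
        rec = pairwise_similarity(seq, seq)
        assert rec.cov_a == rec.cov_b == 1.0
        # ungapped self-score: sum of diagonal BLOSUM62 entries
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        assert rec.score == pytest.approx(sum(blosum[c, c] for c in seq))

    def test_all_negative_comparison_scores_zero(self):
        rec = pairwise_similarity("AAAA", "GGGG")
        assert rec.score == 0.0 and rec.aln_len == 0
        assert rec.cov_a == rec.cov_b == 0.0

    def test_symmetry(self):
        a, b = "MKVLACDEFGHIK", "ACDEFGHIKWWYP"
        r1 = pairwise_similarity(a, b)
        r2 = pairwise_similarity(b, a)
        assert r1.score == r2.score
        assert (r1.cov_a, r1.start_a, r1.end_a) == (r2.cov_b, r2.start_b, r2.end_b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity("", "ACD")


class TestLinkCriteria:
    def _rec(self, score=100.0, cov=0.9, start_a=0, end_a=90, start_b=0, end_b=90):
        return SimilarityRecord("a", "b", score, end_a - start_a, cov, cov,
                                start_a, end_a, start_b, end_b)

    def test_identical_sequences_pass_defaults(self):
        seq = "MKVLACDEFGHIKWWYPQRST" * 5
        rec = pairwise_similarity(seq, seq)
        assert link_criteria(rec, len(seq), len(seq), ClusterParams())

    def test_low_coverage_fails(self):
        rec = self._rec(cov=0.2)
        assert not link_criteria(rec, 100, 100, ClusterParams(min_cov=0.5))

    def test_low_score_fails(self):
        rec = self._rec(score=10.0)
        assert not link_criteria(rec, 100, 100, ClusterParams(min_score=50))

    def test_positional_shift_fails(self):
        # alignment at the N-terminus of a (midpoint 0.1) but C-terminus of b
        # (midpoint 0.9): shift 0.8 > 0.3
        rec = self._rec(start_a=0, end_a=20, start_b=80, end_b=100, cov=0.9)
        assert not link_criteria(rec, 100, 100, ClusterParams(max_pos_shift=0.3))
        rec_ok = self._rec(start_a=0, end_a=20, start_b=0, end_b=20, cov=0.9)
        assert link_criteria(rec_ok, 100, 100, ClusterParams(max_pos_shift=0.3))


class TestMCL:
    def test_no_links_gives_singletons(self):
        clusters = mcl_cluster(list("abcd"), {}, ClusterParams())
        assert sorted(map(sorted, clusters)) == [["a"], ["b"], ["c"], ["d"]]

    def test_two_cliques_with_weak_bridge_separate(self):
        links = {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0,
                 ("d", "e"): 1.0, ("d", "f"): 1.0, ("e", "f"): 1.0,
                 ("c", "d"): 0.05}
        clusters = mcl_cluster(list("abcdef"), links, ClusterParams(inflation=2.0))
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_complete_uniform_graph_stays_together(self):
        nodes = list("abcde")
        links = {(x, y): 1.0 for i, x in enumerate(nodes) for y in nodes[i + 1:]}
        clusters = mcl_cluster(nodes, links, ClusterParams(inflation=2.0))
        assert clusters == [set(nodes)]

    @pytest.mark.parametrize("inflation", [1.5, 2.0, 4.0])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_property(self, inflation, seed):
        """Clusters are disjoint and cover every node for all settings."""
        r = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(12)]
        links = {}
        for i in range(12):
            for j in range(i + 1, 12):
                if r.random() < 0.3:
                    links[(nodes[i], nodes[j])] = float(r.uniform(0.1, 1.0))
        clusters = mcl_cluster(nodes, links, ClusterParams(inflation=inflation))
        flat = [n for c in clusters for n in c]
        assert sorted(flat) == sorted(nodes)
        assert len(flat) == len(set(flat))

    def test_empty_node_list_rejected(self):
        with pytest.raises(ValueError):
            mcl_cluster([], {}, ClusterParams())


class TestProfileConstruction:
    def test_single_sequence_gives_identity_profile(self):
        model = build_profile_from_cluster(["MKVLACDE"], name="cas1__cluster1")
        assert model.length == 8
        assert model.consensus == "MKVLACDE"

    def test_identical_sequences_concentrate_emissions(self):
        model = build_profile_from_cluster(["ACDE"] * 10, pseudocount=0.01)
        for k, aa in enumerate("ACDE"):
            from caskit.profiles import AA_INDEX
            # frequency 1 before pseudocounts: observed residue keeps almost all mass
            assert model.match_emissions[k, AA_INDEX[aa]] >= 1.0 / (1 + 20 * 0.01 / 10)

    def test_column_frequencies_follow_counts(self):
        # 3 sequences differing at one column: expect 2/3 - 1/3 (+pseudocount)
        model = build_profile_from_cluster(["ACDE", "ACDE", "AFDE"], pseudocount=0.01)
        from caskit.profiles import AA_INDEX
        em = model.match_emissions[1]
        assert em[AA_INDEX["C"]] == pytest.approx((2 + 0.01) / (3 + 0.2))
        assert em[AA_INDEX["F"]] == pytest.approx((1 + 0.01) / (3 + 0.2))
        assert model.consensus == "ACDE"

    def test_gapped_cluster_majority_columns(self):
        msa_input = ["MKVLACDE", "MKVLCDE", "MKVLACDE"]
        model = build_profile_from_cluster(msa_input)
        # all sequences align; the 'A' column is present in 2/3 >= 50%
        assert model.length == 8

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            build_profile_from_cluster([])

    def test_center_star_handles_indels(self):
        msa = center_star_alignment(["ACDEF", "ACDE", "ACDEF"])
        assert len({len(row) for row in msa}) == 1
        assert msa[1].count("-") == 1


class TestBuildCollection:
    def test_identical_family_collapses_to_one_model(self):
        coll = build_collection({"cas1": {"s1": "MKVLACDEFGHIKWWYPQRST",
                                          "s2": "MKVLACDEFGHIKWWYPQRST",
                                          "s3": "MKVLACDEFGHIKWWYPQRST"}},
                                ClusterParams(), "C")
        assert len(coll.models["cas1"]) == 1

    def test_two_subfamilies_give_two_discriminating_models(self):
        fams, partition = generate_protein_families(n_families=1, seed=4)
        coll = build_collection({"cas1": fams["fam1"]}, ClusterParams(inflation=2.0), "C")
        models = coll.models["cas1"]
        assert len(models) == 2
        subs = list(partition["fam1"].values())
        # each model scores its own subfamily's members higher than the other's
        for model in models:
            means = [np.mean([model.normalized_score(fams["fam1"][sid]) for sid in sub])
                     for sub in subs]
            own = int(np.argmax(means))
            assert means[own] > means[1 - own]

    def test_stricter_min_score_refines_clusters(self):
        fams, _ = generate_protein_families(n_families=1, seed=9)
        loose = build_collection({"f": fams["fam1"]}, ClusterParams(min_score=20), "L")
        strict = build_collection({"f": fams["fam1"]}, ClusterParams(min_score=400), "S")
        assert len(strict.models["f"]) >= len(loose.models["f"])

    def test_deterministic_given_inputs(self):
        fams, _ = generate_protein_families(n_families=1, seed=2)
        c1 = build_collection({"f": fams["fam1"]}, ClusterParams(), "A")
        c2 = build_collection({"f": fams["fam1"]}, ClusterParams(), "A")
        for m1, m2 in zip(c1.models["f"], c2.models["f"]):
            assert m1.name == m2.name
            assert np.array_equal(m1.match_emissions, m2.match_emissions)
            assert np.array_equal(m1.transitions, m2.transitions)

    def test_unreadable_fasta_names_family(self, tmp_path):
        with pytest.raises(IOError, match="cas1"):
            build_collection({"cas1": tmp_path / "missing.fasta"}, ClusterParams(), "X")


class TestSubfamilyRecovery:
    def test_planted_partition_recovered_across_seeds(self):
        """MCL with inflation 2 separates two planted subfamilies."""
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            fams, partition = generate_protein_families(n_families=1, seed=seed)
            clusters = cluster_family(fams["fam1"], ClusterParams(inflation=2.0))
            planted = sorted(sorted(v) for v in partition["fam1"].values())
            hits += (sorted(sorted(c) for c in clusters) == planted)
        assert hits >= 0.95 * n_runs
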