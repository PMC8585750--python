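import itertools

import numpy as np
import pytest

from _oracles import pair_diff_oracle, syn_sites_oracle
from nbs_profiler.evolution import (
    DuplicationParams,
    SENSE_CODONS,
    classify_duplications,
    detect_collinear_blocks,
    kaks_ng86,
    select_pairs,
    subfamily_kaks_contrast,
)
from nbs_profiler.models import HomologPair, KaKsResult
from nbs_profiler.synthetic_data import evolve_codon_pair, reverse_translate


class TestNG86Counting:
    def test_site_counts_match_oracle_for_every_sense_codon(self):
        for codon in SENSE_CODONS:
            res = kaks_ng86(codon, codon)
            assert res.s_sites == pytest.approx(syn_sites_oracle(codon), abs=1e-12)
            assert res.n_sites + res.s_sites == pytest.approx(3.0)

    def test_differences_match_pathway_oracle_on_all_codon_pairs(self):
        for c1, c2 in itertools.product(SENSE_CODONS, repeat=2):
            res = kaks_ng86(c1, c2)
            sd, nd = pair_diff_oracle(c1, c2)
            assert res.s_diffs == pytest.approx(sd, abs=1e-12), (c1, c2)
            assert res.n_diffs == pytest.approx(nd, abs=1e-12), (c1, c2)

    def test_random_short_alignments_match_oracle(self):
        rng = np.random.default_rng(17)
        codons = np.array(SENSE_CODONS)
        for _ in range(1000):
            k = int(rng.integers(1, 4))
            a = "".join(rng.choice(codons, size=k))
            b = "".join(rng.choice(codons, size=k))
            res = kaks_ng86(a, b)
            sd = nd = s = 0.0
            for i in range(k):
                ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
                d = pair_diff_oracle(ca, cb)
                sd += d[0]
                nd += d[1]
                s += (syn_sites_oracle(ca) + syn_sites_oracle(cb)) / 2
            assert res.s_diffs == pytest.approx(sd, abs=1e-12)
            assert res.n_diffs == pytest.approx(nd, abs=1e-12)
            assert res.s_sites == pytest.approx(s, abs=1e-12)
            assert res.n_sites + res.s_sites == pytest.approx(3.0 * k)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        anc = reverse_translate(prot, rng)
        a, b = evolve_codon_pair(anc, 0.5, 40, seed=9)
        fwd = kaks_ng86(a, b)
        rev = kaks_ng86(b, a)
        assert (fwd.ka, fwd.ks, fwd.omega) == (rev.ka, rev.ks, rev.omega)


class TestNG86Edges:
    def test_identical_sequences(self):
        res = kaks_ng86("ATGGCT", "ATGGCT")
        assert res.ka == 0.0 and res.ks == 0.0
        assert res.omega is None and res.selection_call == "undefined"

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kaks_ng86("ATG", "ATGGCT")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            kaks_ng86("TAAGCT", "ATGGCT")

    def test_gap_codons_skipped_pairwise(self):
        res = kaks_ng86("ATG---GCT", "ATGAAAGCA")
        assert res.codons == 2

    def test_saturated_pair_is_undefined(self):
        a = "ATG" * 30
        b = "CGC" * 30  # 3 differences per codon, heavily nonsynonymous
        res = kaks_ng86(a, b)
        assert res.selection_call == "undefined"

    def test_selection_calls_follow_omega(self):
        rng = np.random.default_rng(21)
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=400))
        anc = reverse_translate(prot, rng)
        low_a, low_b = evolve_codon_pair(anc, 0.1, 120, seed=1)
        res = kaks_ng86(low_a, low_b)
        assert res.selection_call == "purifying" and res.omega < 1


class TestEvolveCodonPair:
    def test_zero_substitutions_identity(self):
        anc = "ATGGCTAAA"
        assert evolve_codon_pair(anc, 0.5, 0, seed=1) == (anc, anc)

    def test_seed_determinism(self):
        anc = reverse_translate("M" * 50 + "K" * 50, np.random.default_rng(0))
        assert evolve_codon_pair(anc, 0.4, 30, seed=5) == evolve_codon_pair(anc, 0.4, 30, seed=5)

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            evolve_codon_pair("ATG", 0.0, 1, seed=0)

    def test_no_stop_codons_introduced(self):
        rng = np.random.default_rng(2)
        anc = reverse_translate("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200)), rng)
        a, b = evolve_codon_pair(anc, 1.5, 150, seed=3)
        for seq in (a, b):
            assert all(seq[i : i + 3] not in ("TAA", "TAG", "TGA") for i in range(0, len(seq), 3))

    def test_frozen_codons_keep_their_amino_acid(self):
        rng = np.random.default_rng(4)
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        anc = reverse_translate(prot, rng)
        frozen = range(10, 30)
        a, b = evolve_codon_pair(anc, 1.0, 80, seed=6, frozen_codons=frozen)
        from nbs_profiler.evolution import translate_codon

        for seq in (a, b):
            for i in frozen:
                assert translate_codon(seq[3 * i : 3 * i + 3]) == prot[i]


class TestAlignCodons:
    def test_deletion_mapped_to_codon_gap(self):
        from nbs_profiler.evolution import align_codons

        a = "ATGGCTAAAGGGTTTCCC"  # MAKGFP
        b = "ATGGCTGGGTTTCCA"     # MAGFP (K deleted, one synonymous change)
        aa, bb = align_codons(a, b)
        assert len(aa) == len(bb) and "---" in bb
        res = kaks_ng86(aa, bb)
        assert res.codons == 5 and res.s_diffs == pytest.approx(1.0)
        assert res.n_diffs == pytest.approx(0.0)

    def test_internal_stop_rejected(self):
        from nbs_profiler.evolution import align_codons

        with pytest.raises(ValueError):
            align_codons("ATGTAAGCT", "ATGGCTGCT")


class TestSelectPairs:
    def test_identity_window(self):
        classes = {"a": "CNL", "b": "CNL", "c": "TNL", "d": "TNL"}
        pairs = [
            HomologPair("a", "b", 1.0, 300),
            HomologPair("c", "d", 0.7, 200),
            HomologPair("a", "c", 0.7, 50),
        ]
        kept = select_pairs(pairs, classes)
        assert [(p.gene_a, p.gene_b) for p in kept] == [("c", "d")]

    def test_unclassified_genes_excluded_and_dedup(self):
        classes = {"a": "CNL", "b": "CNL"}
        pairs = [
            HomologPair("a", "b", 0.8, 300),
            HomologPair("b", "a", 0.8, 300),
            HomologPair("a", "z", 0.8, 300),
        ]
        assert len(select_pairs(pairs, classes)) == 1

    def test_near_identical_quadruplet_excluded_entirely(self):
        """A conserved near-identical family drops out, like the RNL quartet."""
        ids = [f"r{i}" for i in range(4)]
        classes = {g: "RNL" for g in ids}
        pairs = [
            HomologPair(a, b, 0.995, 300)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        ]
        assert select_pairs(pairs, classes) == []


class TestContrast:
    def test_identical_groups_nonsignificant(self):
        res = [KaKsResult("a", "b", 0.1, 0.4, w, "purifying") for w in (0.2, 0.3, 0.4)]
        out = subfamily_kaks_contrast({"CNL": res, "TNL": res})
        assert out["p_value"] == pytest.approx(1.0)

    def test_single_group_is_error(self):
        res = [KaKsResult("a", "b", 0.1, 0.4, 0.3, "purifying")] * 3
        with pytest.raises(ValueError):
            subfamily_kaks_contrast({"CNL": res})

    def test_all_undefined_is_error(self):
        res = [KaKsResult("a", "b", None, None, None, "undefined")] * 3
        with pytest.raises(ValueError):
            subfamily_kaks_contrast({"CNL": res, "TNL": res})

    def test_separated_cohorts_detected(self):
        """omega 0.3 vs 0.42 cohorts: means recovered within 0.05 and contrast
        significant.  Pairs are 1000 codons long; at shorter lengths the mean
        of per-pair Ka/Ks ratios carries a known upward small-sample bias.
        """
        rng = np.random.default_rng(31)
        groups = {}
        for name, omega in (("CNL", 0.30), ("TNL", 0.42)):
            results = []
            for _ in range(30):
                prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 1000))
                anc = reverse_translate(prot, rng)
                a, b = evolve_codon_pair(anc, omega, 200, seed=int(rng.integers(2**31)))
                results.append(kaks_ng86(a, b))
            groups[name] = results
        out = subfamily_kaks_contrast(groups)
        assert out["means"]["CNL"] == pytest.approx(0.30, abs=0.05)
        assert out["means"]["TNL"] == pytest.approx(0.42, abs=0.05)
        assert out["p_value"] < 0.01


def simple_rank_map():
    # chr1: a0..a9 ; chr2: b0..b9
    ranks = {}
    for i in range(10):
        ranks[f"a{i}"] = ("chr1", i)
        ranks[f"b{i}"] = ("chr2", i)
    return ranks


class TestCollinearity:
    def test_planted_run_forms_one_block(self):
        ranks = simple_rank_map()
        pairs = [HomologPair(f"a{i}", f"b{i}", 0.8, 200) for i in range(6)]
        blocks = detect_collinear_blocks(ranks, pairs)
        assert len(blocks) == 1 and len(blocks[0].pairs) == 6

    def test_shuffled_pairs_give_no_block(self):
        ranks = simple_rank_map()
        partner = [7, 2, 9, 0, 5, 3]
        pairs = [HomologPair(f"a{i}", f"b{partner[i]}", 0.8, 200) for i in range(6)]
        assert detect_collinear_blocks(ranks, pairs) == []

    def test_min_block_size_threshold(self):
        ranks = simple_rank_map()
        pairs = [HomologPair(f"a{i}", f"b{i}", 0.8, 200) for i in range(4)]
        assert detect_collinear_blocks(ranks, pairs) == []

    def test_local_duplicates_are_not_anchors(self):
        ranks = {f"a{i}": ("chr1", i) for i in range(12)}
        pairs = [HomologPair(f"a{i}", f"a{i + 1}", 0.9, 200) for i in range(0, 10, 2)]
        assert detect_collinear_blocks(ranks, pairs) == []


class TestClassifyDuplications:
    def test_rank_adjacent_pair_is_tandem(self):
        ranks = {"a": ("chr1", 0), "b": ("chr1", 1)}
        calls = classify_duplications(["a", "b"], ranks, [HomologPair("a", "b", 0.8, 200)], [])
        assert calls["a"].dup_type == calls["b"].dup_type == "tandem"

    def test_cross_chromosome_without_block_is_dispersed(self):
        ranks = {"a": ("chr1", 0), "b": ("chr2", 5)}
        calls = classify_duplications(["a", "b"], ranks, [HomologPair("a", "b", 0.8, 200)], [])
        assert calls["a"].dup_type == "dispersed"

    def test_proximal_window(self):
        ranks = {"a": ("chr1", 0), "b": ("chr1", 5), "c": ("chr1", 30)}
        pairs = [HomologPair("a", "b", 0.8, 200), HomologPair("a", "c", 0.8, 200)]
        calls = classify_duplications(["a", "b", "c"], ranks, pairs, [])
        assert calls["b"].dup_type == "proximal"
        assert calls["c"].dup_type == "dispersed"

    def test_no_homolog_is_singleton(self):
        ranks = {"a": ("chr1", 0)}
        calls = classify_duplications(["a"], ranks, [], [])
        assert calls["a"].dup_type == "singleton"

    def test_block_membership_outranks_tandem(self):
        """Priority: a gene with both collinear-block and tandem evidence is WGD."""
        ranks = simple_rank_map()
        ranks["t"] = ("chr1", 10)
        pairs = [HomologPair(f"a{i}", f"b{i}", 0.8, 200) for i in range(6)]
        pairs.append(HomologPair("a9", "t", 0.8, 200))  # tandem partner for a9
        blocks = detect_collinear_blocks(ranks, pairs)
        # extend block over a9 artificially by including it in a planted run
        pairs2 = [HomologPair(f"a{i}", f"b{i}", 0.8, 200) for i in range(10)]
        pairs2.append(HomologPair("a9", "t", 0.8, 200))
        blocks2 = detect_collinear_blocks(ranks, pairs2)
        calls = classify_duplications(["a9", "t"], ranks, pairs2, blocks2)
        assert calls["a9"].dup_type == "wgd_segmental"
        assert calls["t"].dup_type == "tandem"

    def test_missing_rank_is_error(self):
        with pytest.raises(ValueError):
            classify_duplications(["ghost"], {}, [], [])

    def test_partition_on_synthetic_truth(self, default_genome):
        ranks = default_genome.rank_map()
        params = DuplicationParams()
        blocks = detect_collinear_blocks(ranks, default_genome.homolog_pairs, params)
        calls = classify_duplications(
            default_genome.nbs_gene_ids, ranks, default_genome.homolog_pairs, blocks, params
        )
        assert set(calls) == set(default_genome.nbs_gene_ids)
        match = sum(
            calls[g].dup_type == default_genome.truth.duplication[g] for g in calls
        )
        assert match == len(calls)
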