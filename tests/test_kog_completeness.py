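import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import gotoh_local_score

from depthsat.kog_completeness import (
    OrthologCluster,
    SizeClass,
    TranslatedAlignment,
    classify_length,
    compare_canonical,
    extract_cds,
    make_aligner,
    read_cluster_fasta,
    saturation_table,
    score_assembly,
    select_best,
    six_frame_translate,
    size_bounds,
    translated_search,
)
from depthsat.sequtils import reverse_complement
from depthsat.synthetic_data import AMINO_ACIDS, back_translate, gen_kog_cluster


class TestSixFrameTranslate:
    def test_standard_code_with_stop_sentinel(self):
        frames = dict(six_frame_translate("ATGAAATAA"))
        assert frames[1] == "MK*"

    def test_reverse_frames_translate_the_reverse_complement(self):
        seq = "ATGGCCAAAGTTTGA"
        frames = dict(six_frame_translate(seq))
        rc_frames = dict(six_frame_translate(reverse_complement(seq)))
        assert frames[-1] == rc_frames[1]
        assert frames[1] == rc_frames[-1]

    def test_partial_trailing_codons_dropped(self):
        frames = dict(six_frame_translate("ATGAAATTTC"))  # length 10
        assert (len(frames[1]), len(frames[2]), len(frames[3])) == (3, 3, 2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")


class TestSizeBounds:
    def test_shortest_80_second_100_gives_lower_64(self):
        assert size_bounds([80, 100, 110, 130])[0] == 64

    def test_equal_lengths_collapse_the_range(self):
        assert size_bounds([100, 100, 100]) == (100, 100)

    def test_longest_120_second_100_gives_upper_144(self):
        assert size_bounds([90, 100, 120])[1] == 144

    def test_fewer_than_two_lengths_rejected(self):
        with pytest.raises(ValueError):
            size_bounds([100])

    @given(st.lists(st.integers(10, 3000), min_size=2, max_size=12))
    def test_bounds_always_bracket_observed_lengths(self, lengths):
        lower, upper = size_bounds(lengths)
        assert lower <= min(lengths)
        assert upper >= max(lengths)


class TestClassifyLength:
    BOUNDS = (64, 150)

    @pytest.mark.parametrize("length,aligned,expected", [
        (100, 95, SizeClass.WITHIN_RANGE),
        (100, 80, SizeClass.WITHIN_RANGE_SHORT_ALIGN),
        (200, 180, SizeClass.TOO_LONG),
        (50, 45, SizeClass.TOO_SHORT),
        (50, 50, SizeClass.TOO_SHORT),        # equal lengths are class 4
        (50, 60, SizeClass.SHORTER_THAN_ALIGNMENT),
        (64, 58, SizeClass.WITHIN_RANGE),     # 58 >= 0.9 * 64
        (150, 134, SizeClass.WITHIN_RANGE_SHORT_ALIGN),
    ])
    def test_five_class_assignment(self, length, aligned, expected):
        assert classify_length(length, aligned, self.BOUNDS) is expected

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            classify_length(0, 10, self.BOUNDS)

    def test_exactly_one_class_on_a_dense_grid(self):
        rng = random.Random(3)
        bounds_set = [size_bounds([rng.randint(40, 200) for _ in range(6)])
                      for _ in range(10)]
        for bounds in bounds_set:
            for length in range(1, 60):
                for aligned in range(0, 60):
                    assert classify_length(length, aligned, bounds) in SizeClass


class TestLocalAlignmentScores:
    @pytest.mark.parametrize("seed", range(8))
    def test_aligner_matches_gotoh_oracle(self, seed):
        rng = random.Random(seed)
        q = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(10, 120)))
        s = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(10, 120)))
        assert make_aligner().score(q, s) == gotoh_local_score(q, s)

    def test_oracle_agreement_with_homologous_pairs(self):
        rng = random.Random(99)
        base = "".join(rng.choice(AMINO_ACIDS) for _ in range(90))
        mutated = "".join(rng.choice(AMINO_ACIDS) if rng.random() < 0.15 else c
                          for c in base)
        assert make_aligner().score(base, mutated) == gotoh_local_score(base, mutated)


def embed_cds(protein, rng, utr5=60, utr3=60):
    cds = back_translate(protein, rng)
    left = "".join(rng.choice("ACT") for _ in range(utr5))   # no G: no ATG, and
    right = "".join(rng.choice("ACT") for _ in range(utr3))  # TAA stops abound
    return left + cds + right


class TestTranslatedSearch:
    def setup_method(self):
        self.rng = random.Random(11)
        self.cluster = gen_kog_cluster(120, seed=12, cluster_id="KOGX")

    def test_exact_backtranslation_scores_full_identity(self):
        protein = self.cluster.members["sp1"]
        contig = embed_cds(protein, self.rng)
        hits = translated_search(self.cluster, {"c1": contig})
        best = hits[0]
        assert best.percent_identity == 100.0 or best.species != "sp1"
        sp1_hits = [h for h in hits if h.species == "sp1"]
        assert sp1_hits and sp1_hits[0].percent_identity == 100.0
        assert sp1_hits[0].query_span_aa == (0, len(protein))

    def test_reverse_strand_hits_are_found(self):
        protein = self.cluster.members["sp1"]
        contig = reverse_complement(embed_cds(protein, self.rng))
        hits = translated_search(self.cluster, {"c1": contig})
        assert hits and hits[0].frame < 0

    def test_random_contigs_stay_below_the_evalue_gate(self):
        rng = random.Random(13)
        for rep in range(20):
            contig = "".join(rng.choice("ACGT") for _ in range(600))
            assert translated_search(self.cluster, {"r": contig},
                                     word_size=0) == []

    def test_word_prefilter_does_not_lose_the_planted_hit(self):
        protein = self.cluster.members["sp3"]
        contig = embed_cds(protein, self.rng)
        with_filter = translated_search(self.cluster, {"c": contig})
        without = translated_search(self.cluster, {"c": contig}, word_size=0)
        assert with_filter[0].score == without[0].score

    def test_empty_contig_set_rejected(self):
        with pytest.raises(ValueError):
            translated_search(self.cluster, {})


class TestExtractCds:
    def setup_method(self):
        self.rng = random.Random(21)

    def _hit_for(self, contig, protein):
        cluster = OrthologCluster.from_members(
            "K", {"a": protein, "b": protein[: len(protein) - 2]})
        hits = translated_search(cluster, {"c": contig})
        assert hits
        return hits[0]

    def test_full_orf_recovered_from_utr_flanked_cds(self):
        protein = "M" + "".join(self.rng.choice(AMINO_ACIDS) for _ in range(80))
        contig = embed_cds(protein, self.rng)
        hit = self._hit_for(contig, protein)
        assert extract_cds(contig, hit) == protein

    def test_missing_stop_codon_returns_none(self):
        protein = "M" + "".join(self.rng.choice(AMINO_ACIDS) for _ in range(80))
        cds = back_translate(protein, self.rng)
        contig = "".join(self.rng.choice("ACT") for _ in range(60)) + cds[:-3]
        hit = self._hit_for(contig, protein)
        assert extract_cds(contig, hit) is None

    def test_missing_start_codon_returns_none(self):
        protein = "M" + "".join(self.rng.choice(AMINO_ACIDS) for _ in range(80))
        cds = back_translate(protein, self.rng)
        # drop the ATG and 9 more residues; an in-frame TAA upstream blocks
        # any further 5' scan
        contig = ("".join(self.rng.choice("ACT") for _ in range(57)) + "TAA"
                  + cds[30:] + "".join(self.rng.choice("ACT") for _ in range(30)))
        hit = self._hit_for(contig, protein)
        assert extract_cds(contig, hit) is None

    def test_internal_stop_yields_protein_shorter_than_alignment(self):
        protein = "M" + "".join(self.rng.choice(AMINO_ACIDS) for _ in range(90))
        cds = back_translate(protein, self.rng)
        broken = cds[:90] + "TGA" + cds[93:]  # stop replacing codon 30
        contig = embed_cds_raw(broken, self.rng)
        hit = self._hit_for(contig, protein)
        extracted = extract_cds(contig, hit)
        assert extracted == protein[:30]


def embed_cds_raw(cds, rng, utr5=60, utr3=60):
    left = "".join(rng.choice("ACT") for _ in range(utr5))
    right = "".join(rng.choice("ACT") for _ in range(utr3))
    return left + cds + right


def _mk_alignment(score, identity=95.0, alen=100, contig="c1"):
    return TranslatedAlignment("K", contig, "sp1", 1, score, 1e-30,
                               (0, alen), (0, 3 * alen), alen, identity)


class TestSelectBest:
    def test_single_candidate_returned(self):
        cand = (_mk_alignment(50), "MAAA")
        assert select_best([cand]) is cand

    def test_highest_score_wins(self):
        lo, hi = (_mk_alignment(80), "MA"), (_mk_alignment(120), "MB")
        assert select_best([lo, hi]) is hi

    def test_tie_breaks_follow_identity_then_length_then_contig(self):
        import itertools

        a = (_mk_alignment(100, identity=98.0), "Ma")
        b = (_mk_alignment(100, identity=95.0), "Mb")
        c = (_mk_alignment(100, identity=95.0, alen=90), "Mc")
        d = (_mk_alignment(100, identity=95.0, alen=90, contig="c9"), "Md")
        expected_order = [a, b, c, d]
        for perm in itertools.permutations(expected_order):
            assert select_best(list(perm)) is a
        assert select_best([b, c, d]) is b
        assert select_best([c, d]) is c

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestScoreAssembly:
    def test_planted_orfs_are_detected_and_full_length(self):
        rng = random.Random(31)
        clusters, contigs = [], {}
        for i in range(10):
            cluster = gen_kog_cluster(100, seed=100 + i, cluster_id=f"K{i:02d}")
            clusters.append(cluster)
            if i < 5:  # plant ORFs for half the clusters
                contigs[f"t{i}"] = embed_cds(cluster.members["sp2"], rng)
        for j in range(5):  # noise contigs
            contigs[f"n{j}"] = "".join(rng.choice("ACGT") for _ in range(500))
        records, summary = score_assembly(contigs, clusters)
        assert summary.n_detected == 5
        assert summary.n_full_length == 5
        assert summary.n_full_length <= summary.n_within_length <= summary.n_detected

    def test_empty_assembly_detects_nothing(self):
        clusters = [gen_kog_cluster(100, seed=1, cluster_id="K0")]
        records, summary = score_assembly({}, clusters)
        assert summary.n_detected == 0 and records[0].detected is False

    def test_internally_truncated_orf_is_detected_but_not_full_length(self):
        rng = random.Random(33)
        cluster = gen_kog_cluster(120, seed=34, cluster_id="K0")
        cds = back_translate(cluster.members["sp1"], rng)
        broken = cds[:150] + "TAA" + cds[153:]
        contigs = {"c": embed_cds_raw(broken, rng)}
        records, summary = score_assembly(contigs, [cluster])
        assert records[0].detected is True
        assert records[0].full_length is False
        assert records[0].size_class is SizeClass.SHORTER_THAN_ALIGNMENT


class TestCompareCanonical:
    def test_verbatim_protein_is_identical(self):
        res = compare_canonical("MKLV", {"p1": "MKLV", "p2": "MML"})
        assert res["identical"] is True and res["n_mismatches"] == 0

    def test_single_substitution_counts_one_mismatch(self):
        res = compare_canonical("MKLV", {"p1": "MKIV"})
        assert res["identical"] is False and res["n_mismatches"] == 1

    def test_empty_canonical_set_rejected(self):
        with pytest.raises(ValueError):
            compare_canonical("MKLV", {})


class TestClusterFasta:
    def test_headers_group_by_cluster(self):
        records = [("K1|sp1", "MAAAKKLV"), ("K1|sp2", "MAAAKKL"),
                   ("K2|sp1", "MVVV"), ("K2|sp2", "MVVVA")]
        clusters = read_cluster_fasta(records)
        assert sorted(c.cluster_id for c in clusters) == ["K1", "K2"]
        k1 = next(c for c in clusters if c.cluster_id == "K1")
        assert k1.members == {"sp1": "MAAAKKLV", "sp2": "MAAAKKL"}


def test_saturation_table_requires_ascending_depths():
    from depthsat.toy_assembler import Assembly

    clusters = [gen_kog_cluster(80, seed=2, cluster_id="K0")]
    empty = Assembly([], {})
    with pytest.raises(ValueError):
        saturation_table([(200, empty), (100, empty)], clusters)


def test_saturation_table_single_depth_row():
    from depthsat.toy_assembler import Assembly, ContigRecord

    rng = random.Random(41)
    cluster = gen_kog_cluster(90, seed=42, cluster_id="K0")
    contig = embed_cds(cluster.members["sp1"], rng)
    asm = Assembly([ContigRecord("c0", contig)], {"L0": ["c0"]})
    table = saturation_table([(1000, asm)], [cluster])
    assert len(table) == 1
    assert table.loc[0, "n_detected"] == 1
    assert table.loc[0, "n_full_length"] == 1
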