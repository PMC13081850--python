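"""Operation catalog: layouts, enumeration orders, construction rules."""

import itertools
import math

import numpy as np
import pytest

import poolforge as pf
from poolforge.seqmodel import Style, translate


class TestSources:
    def test_from_seq_single(self):
        pool = pf.from_seq("ACGT")
        assert pool.size == 1
        assert pool.generate(0).sequence.chars == "ACGT"

    def test_from_seqs_enumerates_in_order(self):
        pool = pf.from_seqs(["AAA", "CCC", "GGG"])
        assert pool.size == 3
        assert [pool.generate(i).sequence.chars for i in range(3)] == \
            ["AAA", "CCC", "GGG"]

    def test_from_seqs_style_applied_to_every_character(self):
        pool = pf.from_seqs(["ACGT"], style="blue")
        seq = pool.generate(0).sequence
        assert all(s == Style(fg="blue") for s in seq.styles)

    def test_from_pwm_degenerate_yields_consensus(self):
        pwm = pf.PWM([[1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        pool = pf.from_pwm(pwm, 5)
        assert {r.sequence.chars for r in pool.iter_results()} == {"AGT"}

    def test_from_pwm_sizes_and_lengths(self):
        from poolforge._data import SS5_PWM_ROWS
        pool = pf.from_pwm(SS5_PWM_ROWS, 2000)
        assert pool.size == 2000
        sample = pf.sample_library(pool, 5, master_seed=1)
        assert all(len(r.sequence.chars) == 9 for r in sample)

    def test_from_pwm_column_frequencies_within_3_sigma(self):
        rows = [[0.1, 0.2, 0.3, 0.4], [0.7, 0.1, 0.1, 0.1]]
        n = 10_000
        pool = pf.from_pwm(rows, n)
        chars = [r.sequence.chars for r in pool.iter_results(master_seed=0)]
        for col, probs in enumerate(rows):
            counts = np.array([
                sum(1 for c in chars if c[col] == b) for b in "ACGT"
            ])
            for k, p in zip(counts, probs):
                sigma = math.sqrt(n * p * (1 - p))
                assert abs(k - n * p) <= 3 * sigma

    def test_invalid_pwm_rejected(self):
        with pytest.raises(ValueError):
            pf.PWM([[0.5, 0.5, 0.1, 0]])
        with pytest.raises(ValueError):
            pf.PWM([[1.2, -0.2, 0, 0]])

    def test_iupac_fixed_motif_is_single(self):
        assert pf.from_iupac("ACGT").size == 1

    def test_iupac_nn_enumerates_all_dimers_once(self):
        pool = pf.from_iupac("NN")
        got = [r.sequence.chars for r in pool.iter_results()]
        assert len(got) == 16
        assert set(got) == {"".join(p) for p in itertools.product("ACGT", repeat=2)}
        # leftmost position is the least significant digit
        assert got[0] == "AA" and got[1] == "CA" and got[4] == "AC"

    def test_iupac_two_letter_code(self):
        pool = pf.from_iupac("AY")
        assert {r.sequence.chars for r in pool.iter_results()} == {"AC", "AT"}

    def test_iupac_invalid_code(self):
        with pytest.raises(ValueError):
            pf.from_iupac("AXG")

    def test_random_kmers_contract_and_uniformity(self):
        pool = pf.random_kmers(5, 2000)
        assert pool.size == 2000
        a = [r.sequence.chars for r in pool.iter_results(master_seed=4)]
        b = [r.sequence.chars for r in pool.iter_results(master_seed=4)]
        assert a == b
        counts = np.zeros(4)
        for s in a:
            for c in s:
                counts["ACGT".index(c)] += 1
        n = counts.sum()
        chi2 = float((((counts - n / 4) ** 2) / (n / 4)).sum())
        assert chi2 < 16.27  # chi2_{3, 0.999}


class TestBarcodes:
    def test_distinct_barcodes_small(self):
        parent = pf.repeat(pf.from_seq("AC<bc></bc>GT"), 100)
        pool = pf.get_barcodes(parent, "bc", 4, prefix="bc")
        codes = {r.card["bc.barcode"] for r in pool.iter_results()}
        assert len(codes) == 100
        assert all(len(c) == 4 for c in codes)

    def test_minimal_length_covers_full_space(self):
        parent = pf.repeat(pf.from_seq("A<bc></bc>"), 16)
        pool = pf.get_barcodes(parent, "bc", 2, prefix="bc")
        codes = [r.card["bc.barcode"] for r in pool.iter_results()]
        assert sorted(codes) == sorted(
            "".join(p) for p in itertools.product("ACGT", repeat=2))

    def test_capacity_error_states_minimal_length(self):
        parent = pf.repeat(pf.from_seq("A<bc></bc>"), 100)
        with pytest.raises(pf.CapacityError, match="minimal length is 4"):
            pf.get_barcodes(parent, "bc", 3)

    def test_barcode_replaces_region_and_is_bold(self):
        parent = pf.from_seq("AC<bc>TTTT</bc>GT")
        pool = pf.get_barcodes(parent, "bc", 6)
        seq = pool.generate(0).sequence
        assert len(seq.chars) == 10
        r = seq.region("bc")
        assert r.end - r.start == 6
        assert seq.styles[r.start] == Style(bold=True)


class TestMutagenize:
    def test_all_single_substitutions(self):
        pool = pf.mutagenize(pf.from_seq("AAAA"), scheme="single")
        got = {r.sequence.chars for r in pool.iter_results()}
        assert pool.size == 12
        assert got == {"AAAA"[:i] + c + "AAAA"[i + 1:]
                       for i in range(4) for c in "CGT"}

    def test_region_restricts_targets(self):
        pool = pf.mutagenize(pf.from_seq("AAA<t>CCCGGG</t>TTT"),
                             scheme="single", region="t")
        assert pool.size == 18
        for r in pool.iter_results():
            diff = [i for i, (a, b) in
                    enumerate(zip(r.sequence.chars, "AAACCCGGGTTT")) if a != b]
            assert len(diff) == 1 and 3 <= diff[0] < 9

    def test_random_rate_zero_is_identity(self):
        pool = pf.mutagenize(pf.from_seq("ACGTACGT"), scheme="random",
                             rate=0.0, n=5)
        assert {r.sequence.chars for r in pool.iter_results()} == {"ACGTACGT"}

    def test_mutated_positions_styled(self):
        pool = pf.mutagenize(pf.from_seq("AAAA"), scheme="single", prefix="m")
        r = pool.generate(0)
        p = r.card["m.positions"][0]
        assert r.sequence.styles[p] == Style(fg="red")


class TestMutagenizeOrf:
    def test_three_codon_toy_counts_match_brute_force(self):
        # ATG GGT ACC: start excluded, P=2 eligible codons
        src = pf.from_seq("ATGGGTACC")
        single = pf.mutagenize_orf(src, scheme="single")
        double = pf.mutagenize_orf(src, scheme="pairwise")
        assert single.size == 2 * 19 == 38
        assert double.size == math.comb(2, 2) * 19 * 19 == 361

        peptides = {translate(r.sequence.chars) for r in single.iter_results()}
        expected = set()
        for pos in (1, 2):
            for aa in "ACDEFGHIKLMNPQRSTVWY":
                wt = "MGT"
                if aa != wt[pos]:
                    expected.add(wt[:pos] + aa + wt[pos + 1:])
        assert peptides == expected

    def test_pairwise_peptides_differ_at_both_positions(self):
        src = pf.from_seq("ATGGGTACC")
        double = pf.mutagenize_orf(src, scheme="pairwise")
        for r in double.iter_results():
            pep = translate(r.sequence.chars)
            assert pep[0] == "M"
            assert pep[1] != "G" and pep[2] != "T"

    def test_missense_policy_hits_target_never_wildtype(self):
        # exhaustive on a 10-codon toy ORF
        peptide = "MKLVNDQRSW"
        from poolforge._data import usage_table
        dna = "".join(usage_table()[aa][0][0] for aa in peptide)
        pool = pf.mutagenize_orf(pf.from_seq(dna), scheme="single", prefix="mut")
        assert pool.size == 9 * 19
        for r in pool.iter_results():
            card = r.card
            pos = card["mut.positions"][0]
            intended = card["mut.mut_aa"][0]
            wt = card["mut.wt_aa"][0]
            got = translate(r.sequence.chars)[pos - 1]
            assert got == intended
            assert got != wt

    def test_substitutes_in_alphabetical_order(self):
        pool = pf.mutagenize_orf(pf.from_seq("ATGGGTACC"), scheme="single",
                                 prefix="mut")
        first_pos = [pool.generate(i).card["mut.mut_aa"][0]
                     for i in range(19)]
        assert first_pos == [aa for aa in "ACDEFGHIKLMNPQRSTVWY" if aa != "G"]

    def test_random_scheme_keeps_all_wildtype_draws(self):
        pool = pf.mutagenize_orf(pf.from_seq("ATGGGTACCGTT"), scheme="random",
                                 rate=0.05, n=200, prefix="mut")
        n_wt = sum(
            1 for r in pool.iter_results()
            if not r.card["mut.positions"]
        )
        assert n_wt > 0  # Bernoulli(0.05) over 3 codons misses often

    def test_frame_error(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            pf.mutagenize_orf(pf.from_seq("ATGGG"), scheme="single")


class TestDeleteScan:
    def test_window_count(self):
        pool = pf.delete_scan(pf.from_seq("AAA<t>CCCGGG</t>TTT"), "t", 3)
        assert pool.size == 4
        lengths = {len(r.sequence.chars) for r in pool.iter_results()}
        assert lengths == {9}

    def test_full_window_collapses_region(self):
        pool = pf.delete_scan(pf.from_seq("AAA<t>CCCGGG</t>TTT"), "t", 6)
        assert pool.size == 1
        seq = pool.generate(0).sequence
        assert seq.chars == "AAATTT"
        r = seq.region("t")
        assert r.start == r.end == 3


class TestInsert:
    def test_sizes_multiply_and_coordinates_shift(self):
        parent = pf.from_seq("ACGT<ins/>AC<x>GT</x>")
        payload = pf.from_seqs(["TT", "GGG"])
        pool = pf.insert(parent, payload, "ins")
        assert pool.size == 2
        r0 = pool.generate(0).sequence
        assert r0.chars == "ACGTTTACGT"
        assert (r0.region("x").start, r0.region("x").end) == (8, 10)
        r1 = pool.generate(1).sequence
        assert r1.chars == "ACGTGGGACGT"
        assert (r1.region("ins").start, r1.region("ins").end) == (4, 7)

    def test_empty_payload_is_identity(self):
        parent = pf.from_seq("ACGT<ins/>ACGT")
        pool = pf.insert(parent, pf.from_seq(""), "ins")
        assert pool.generate(0).sequence.chars == "ACGTACGT"


class TestShuffle:
    def test_single_character_region_is_identity(self):
        pool = pf.shuffle(pf.from_seq("AC<t>G</t>T"), 5, region="t")
        assert {r.sequence.chars for r in pool.iter_results()} == {"ACGT"}

    def test_multiset_conserved_and_seeded(self):
        pool = pf.shuffle(pf.from_seq("AAACCCGGGTTT"), 20)
        a = [r.sequence.chars for r in pool.iter_results(master_seed=9)]
        b = [r.sequence.chars for r in pool.iter_results(master_seed=9)]
        assert a == b
        assert all(sorted(s) == sorted("AAACCCGGGTTT") for s in a)
        assert len(set(a)) > 1


class TestRecombine:
    def test_zero_crossovers_returns_first_parent(self):
        pool = pf.recombine(pf.from_seq("AAAA"), pf.from_seq("CCCC"), 0, 3)
        assert {r.sequence.chars for r in pool.iter_results()} == {"AAAA"}

    def test_mosaic_property_and_size(self):
        a, b = pf.from_seq("AAAAAAAA"), pf.from_seq("CCCCCCCC")
        pool = pf.recombine(a, b, 2, 10)
        assert pool.size == 10  # n x |A| x |B| with single-member parents
        for r in pool.iter_results(master_seed=2):
            assert set(r.sequence.chars) <= {"A", "C"}
            # two crossovers: at most three maximal segments
            segments = len([k for k, _ in itertools.groupby(r.sequence.chars)])
            assert segments <= 3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pf.recombine(pf.from_seq("AAA"), pf.from_seq("CCCC"), 1, 2)


class TestFlip:
    def test_doubles_pool(self):
        pool = pf.flip(pf.from_seq("AACG"))
        assert pool.size == 2
        assert [r.sequence.chars for r in pool.iter_results()] == ["AACG", "CGTT"]

    def test_state_parity_selects_orientation(self):
        parent = pf.from_seqs(["AAAC", "GGGT"])
        pool = pf.flip(parent, prefix="f")
        results = list(pool.iter_results())
        assert [r.card["f.orientation"] for r in results] == \
            ["fwd", "rev", "fwd", "rev"]
        assert [r.sequence.chars for r in results] == \
            ["AAAC", "GTTT", "GGGT", "ACCC"]

    def test_palindrome_gives_equal_sequences_distinct_names(self):
        pool = pf.flip(pf.from_seq("ACGT"), prefix="f")
        a, b = pool.iter_results()
        assert a.sequence.chars == b.sequence.chars == "ACGT"
        assert a.name != b.name


class TestJoinStack:
    def test_join_concatenates_with_region_offsets(self):
        left = pf.from_seq("<a>AC</a>")
        right = pf.from_seq("G<b>T</b>")
        pool = pf.join(left, right)
        seq = pool.generate(0).sequence
        assert seq.chars == "ACGT"
        assert (seq.region("a").start, seq.region("a").end) == (0, 2)
        assert (seq.region("b").start, seq.region("b").end) == (3, 4)

    def test_join_sizes_multiply(self):
        pool = pf.join(pf.from_iupac("NN"), pf.from_iupac("R"))
        assert pool.size == 32

    def test_stack_sums_and_activates_one_branch(self):
        a = pf.from_seqs(["AA", "CC"])
        b = pf.from_seqs(["GG"])
        pool = pf.stack(a, b, labels=["x", "y"], prefix="stk")
        assert pool.size == 3
        comps = [r.card["stk.component"] for r in pool.iter_results()]
        assert comps == ["x", "x", "y"]

    def test_stack_single_input_is_identity(self):
        a = pf.from_seqs(["AA", "CC"])
        pool = pf.stack(a)
        assert pool.size == 2
        assert [r.sequence.chars for r in pool.iter_results()] == ["AA", "CC"]


class TestInsertMultiscan:
    def test_placements_disjoint_and_inside_region(self):
        template = pf.from_seq("AAAA<cre>" + "A" * 30 + "</cre>TTTT")
        sites = [pf.from_seq("CCCCCC"), pf.from_seq("GGGGG")]
        pool = pf.insert_multiscan(template, *sites, region="cre", n=50,
                                   prefix="var")
        assert pool.size == 50
        for r in pool.iter_results(master_seed=3):
            offs = r.card["var.offsets"]
            iv = sorted((o, o + L) for o, L in zip(offs, (6, 5)))
            assert all(0 <= a and b <= 30 for a, b in iv)
            assert iv[0][1] <= iv[1][0]
            seq = r.sequence.chars
            assert seq[:4] == "AAAA" and seq[-4:] == "TTTT"

    def test_exact_fit_forces_offset_zero(self):
        template = pf.from_seq("<cre>AAAA</cre>")
        pool = pf.insert_multiscan(template, pf.from_seq("CCCC"),
                                   region="cre", n=5, prefix="var")
        for r in pool.iter_results():
            assert r.card["var.offsets"] == [0]
            assert r.sequence.chars == "CCCC"

    def test_infeasible_geometry_raises_with_context(self):
        template = pf.from_seq("<cre>AAAAAA</cre>")
        pool = pf.insert_multiscan(template, pf.from_seq("CCCC"),
                                   pf.from_seq("GGGG"), region="cre", n=2,
                                   max_rejections=20)
        with pytest.raises(pf.GenerationError, match="state"):
            pool.generate(0)


class TestStateOps:
    def test_repeat_identity_and_replication(self):
        base = pf.from_seq("ACGT")
        assert pf.repeat(base, 1).size == 1
        pool = pf.repeat(base, 100, prefix="rep")
        results = list(pool.iter_results())
        assert len({r.sequence.chars for r in results}) == 1
        assert len({r.name for r in results}) == 100

    def test_select_keeps_given_order(self):
        parent = pf.from_seqs(["AA", "CC", "GG"])
        pool = pf.select(parent, [2, 0], prefix="sel")
        assert pool.size == 2
        assert [r.sequence.chars for r in pool.iter_results()] == ["GG", "AA"]
        assert [r.card["sel.parent_state"] for r in pool.iter_results()] == [2, 0]

    def test_reorder_requires_bijection(self):
        parent = pf.from_seqs(["AA", "CC", "GG"])
        with pytest.raises(ValueError):
            pf.reorder(parent, [0, 0, 1])
        pool = pf.reorder(parent, [2, 1, 0])
        assert [r.sequence.chars for r in pool.iter_results()] == \
            ["GG", "CC", "AA"]

    def test_filter_identity_predicate(self):
        parent = pf.from_seqs(["AA", "CC"])
        pool = pf.filter_pool(parent, lambda s: len(s.chars) > 0)
        assert pool.size == 2

    def test_filter_homopolymer_rule_matches_brute_force(self):
        def no_homopolymer4(seq):
            return not any(b * 4 in seq.chars for b in "ACGT")

        parent = pf.from_iupac("NNNN")
        pool = pf.filter_pool(parent, no_homopolymer4)
        # independent oracle over all 256 4-mers
        expected = sum(
            1 for p in itertools.product("ACGT", repeat=4)
            if not any(b * 4 in "".join(p) for b in "ACGT")
        )
        assert expected == 252
        assert pool.size == expected
        assert all(no_homopolymer4(r.sequence) for r in pool.iter_results())


class TestStylize:
    def test_characters_unchanged_styles_visible(self):
        pool = pf.stylize(pf.from_seq("AA<t>CC</t>GG"), "t", "gray")
        seq = pool.generate(0).sequence
        assert seq.chars == "AACCGG"
        assert seq.styles[2] == Style(fg="gray")
        assert "\x1b[" in pf.render_ansi(seq)

    def test_composes_with_downstream_mutation_styling(self):
        styled = pf.stylize(pf.from_seq("AA<t>CC</t>GG"), "t",
                            {"bg": "blue"})
        pool = pf.mutagenize(styled, scheme="single", region="t", prefix="m")
        r = pool.generate(0)
        p = r.card["m.positions"][0]
        assert r.sequence.styles[p] == Style(fg="red")  # replaced char restyled
        other = 3 if p == 2 else 2
        assert r.sequence.styles[other] == Style(bg="blue")
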