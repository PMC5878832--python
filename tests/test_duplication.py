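"""Tandem arrays, collinear chaining, NG86 substitution estimation, dating
and GO tabulation."""

import math
from itertools import permutations

import numpy as np
import pytest

from conftest import brute_force_tandem, make_models, random_genome
from kinomekit import duplication as dup
from kinomekit._codons import AA_OF, SENSE_CODONS, is_stop
from kinomekit.errors import AlignmentError, InvalidParameterError, InvalidSequenceError


class TestTandem:
    def _layout(self, positions, fam="F"):
        """Kinase genes at given starts, interleaved with filler genes."""
        layout = []
        for i, (start, n_fill, kinase) in enumerate(positions):
            layout.append((f"g{i:02d}", "chr1", start))
            for j in range(n_fill):
                layout.append((f"g{i:02d}f{j}", "chr1", start + 100 * (j + 1)))
        models = make_models(layout)
        kin = {g for g, _, _ in layout if "f" not in g}
        return models, kin, {g: fam for g in kin}

    def test_pair_within_rule_detected(self):
        # 2 intervening genes, 50 kb apart
        models, kin, fam = self._layout([(1_000, 2, True), (51_000, 0, True)])
        arrays, _ = dup.detect_tandem_arrays(models, kin, fam)
        assert [a.members for a in arrays] == [["g00", "g01"]]

    def test_six_intervening_genes_break_link(self):
        models, kin, fam = self._layout([(1_000, 6, True), (51_000, 0, True)])
        arrays, _ = dup.detect_tandem_arrays(models, kin, fam)
        assert arrays == []

    def test_gap_over_100kb_breaks_link(self):
        models, kin, fam = self._layout([(1_000, 0, True), (151_000, 0, True)])
        arrays, _ = dup.detect_tandem_arrays(models, kin, fam)
        assert arrays == []

    def test_boundaries_inclusive(self):
        # exactly 5 intervening and exactly 100,000 bp -> linked
        models, kin, fam = self._layout([(1_000, 5, True), (101_000, 0, True)])
        arrays, _ = dup.detect_tandem_arrays(models, kin, fam)
        assert len(arrays) == 1
        # one bp past the limit -> not linked
        models, kin, fam = self._layout([(1_000, 0, True), (101_002, 0, True)])
        arrays, _ = dup.detect_tandem_arrays(models, kin, fam)
        assert arrays == []

    def test_different_families_never_link(self):
        layout = [("a", "chr1", 1_000), ("b", "chr1", 5_000)]
        models = make_models(layout)
        arrays, _ = dup.detect_tandem_arrays(
            models, {"a", "b"}, {"a": "F1", "b": "F2"}
        )
        assert arrays == []

    def test_missing_gene_reported_not_fatal(self):
        models, kin, fam = self._layout([(1_000, 0, True), (5_000, 0, True)])
        kin = kin | {"ghost"}
        fam["ghost"] = "F"
        arrays, missing = dup.detect_tandem_arrays(models, kin, fam)
        assert missing == ["ghost"] and len(arrays) == 1

    def test_matches_bruteforce_oracle_on_random_genomes(self, rng):
        for _ in range(60):
            models, kin, fam = random_genome(rng, max_genes=120)
            arrays, _ = dup.detect_tandem_arrays(models, kin, fam)
            got = sorted(a.members for a in arrays)
            assert got == brute_force_tandem(models, kin, fam)


class TestCollinear:
    def _models(self, n=40):
        layout = [(f"a{i:02d}", "chrA", 1_000 * (i + 1)) for i in range(n)]
        layout += [(f"b{i:02d}", "chrB", 1_000 * (i + 1)) for i in range(n)]
        return make_models(layout)

    def test_perfect_chain_detected(self):
        models = self._models()
        anchors = [(f"a{i:02d}", f"b{i:02d}") for i in range(0, 12, 2)]
        (block,) = dup.detect_collinear_blocks(anchors, models)
        assert len(block.anchors) == 6 and block.orientation == 1

    def test_min_anchor_threshold(self):
        models = self._models()
        anchors = [(f"a{i:02d}", f"b{i:02d}") for i in range(4)]
        assert dup.detect_collinear_blocks(anchors, models, min_anchors=5) == []

    def test_empty_anchor_list(self):
        assert dup.detect_collinear_blocks([], self._models()) == []

    def test_inverted_block_found_with_flipped_orientation(self):
        models = self._models()
        anchors = [(f"a{i:02d}", f"b{(20 - i):02d}") for i in range(0, 12, 2)]
        (block,) = dup.detect_collinear_blocks(anchors, models)
        assert block.orientation == -1 and len(block.anchors) == 6

    def test_planted_block_recovered_among_noise(self, rng):
        # noise anchors live on a different chromosome pair; a handful of
        # same-pair outliers sit against the planted orientation
        layout = [(f"c{i:02d}", "chrC", 1_000 * (i + 1)) for i in range(40)]
        models = self._models() + make_models(layout)
        planted = [(f"a{i:02d}", f"b{i:02d}") for i in range(0, 16, 2)]
        noise = [
            (f"c{int(rng.integers(0, 40)):02d}", f"b{int(rng.integers(0, 40)):02d}")
            for _ in range(20)
        ] + [("a30", "b01"), ("a31", "b00")]
        blocks = dup.detect_collinear_blocks(planted + noise, models)
        assert any(set(b.anchors) == set(planted) for b in blocks)

    def test_gap_constraint(self):
        models = self._models()
        anchors = [(f"a{i:02d}", f"b{i:02d}") for i in (0, 1, 2, 3, 4, 35)]
        (block,) = dup.detect_collinear_blocks(anchors, models, max_gene_gap=25)
        assert len(block.anchors) == 5  # the distant anchor cannot join

    def test_anchor_used_once(self):
        models = self._models()
        anchors = [(f"a{i:02d}", f"b{i:02d}") for i in range(12)]
        blocks = dup.detect_collinear_blocks(anchors, models)
        seen = [a for b in blocks for a in b.anchors]
        assert len(seen) == len(set(seen))


def _oracle_site_counts(codon):
    """Hand enumeration over the 9 single-nucleotide changes."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt_aa = str(Seq(codon[:pos] + nt + codon[pos + 1:]).translate())
            if alt_aa == "*":
                continue
            tot += 1
            syn += alt_aa == aa
        if tot:
            s += syn / tot
    return s


class TestNG86Sites:
    def test_valine_third_position(self):
        assert dup.ng86_site_counts("GTT") == (1.0, 2.0)

    def test_tryptophan_has_no_synonymous_site(self):
        s, n = dup.ng86_site_counts("TGG")
        assert s == 0.0 and n == 3.0

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_normalization_contract(self, codon):
        s, n = dup.ng86_site_counts(codon)
        assert s + n == pytest.approx(3.0)
        assert s == pytest.approx(_oracle_site_counts(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(InvalidSequenceError):
            dup.ng86_site_counts("TAA")


def _oracle_pair_diff(ca, cb):
    """Independent pathway enumeration."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    blocked_results = []
    for order in permutations(diffs):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if is_stop(nxt):
                ok = False
            sd += AA_OF[nxt] == AA_OF[cur]
            nd += AA_OF[nxt] != AA_OF[cur]
            cur = nxt
        (results if ok else blocked_results).append((sd, nd))
    pool = results or blocked_results + results
    return (
        sum(r[0] for r in pool) / len(pool),
        sum(r[1] for r in pool) / len(pool),
    )


class TestNG86Pairs:
    def test_identical_codons(self):
        assert dup.ng86_pair_differences("AAA", "AAA") == (0.0, 0.0)

    def test_single_synonymous_step(self):
        assert dup.ng86_pair_differences("TTT", "TTC") == (1.0, 0.0)

    def test_two_difference_pathway_average(self):
        sd, nd = dup.ng86_pair_differences("TTT", "GTA")
        osd, ond = _oracle_pair_diff("TTT", "GTA")
        assert (sd, nd) == (pytest.approx(osd), pytest.approx(ond))

    def test_symmetry_and_total(self, rng):
        for _ in range(200):
            ca, cb = (SENSE_CODONS[i] for i in rng.integers(0, 61, size=2))
            sd, nd = dup.ng86_pair_differences(ca, cb)
            assert (sd, nd) == dup.ng86_pair_differences(cb, ca)
            n_diff = sum(a != b for a, b in zip(ca, cb))
            assert sd + nd == pytest.approx(n_diff)


class TestEstimate:
    def test_identical_pair(self):
        est = dup.estimate_ka_ks("GTT" * 100, "GTT" * 100)
        assert est.Ka == 0.0 and est.Ks == 0.0
        assert est.ratio is None and est.mode == "undefined"

    def test_worked_example(self):
        est = dup.estimate_ka_ks("GTT" * 10, "GTT" * 9 + "GTA")
        assert est.S_sites == pytest.approx(10.0)
        assert est.Sd == pytest.approx(1.0)
        assert est.Ks == pytest.approx(-0.75 * math.log(1 - 4 / 30), abs=1e-12)
        assert est.Ks == pytest.approx(0.1073, abs=1e-4)
        assert est.Ka == 0.0

    def test_sequence_symmetry(self):
        from kinomekit import synthetic as syn

        a, b, _ = syn.evolve_codon_pair(300, 0.5, 0.4, seed=31)
        ab, ba = dup.estimate_ka_ks(a, b), dup.estimate_ka_ks(b, a)
        assert ab.Ks == pytest.approx(ba.Ks)
        assert ab.Ka == pytest.approx(ba.Ka)

    def test_saturation_flagged(self):
        # ps = 1 >= 3/4: every codon differs synonymously (CTT vs CTC, Leu)
        est = dup.estimate_ka_ks("CTT" * 30, "CTC" * 30)
        assert est.Ks is None and est.saturated and est.ratio is None

    def test_gap_and_stop_codons_excluded_pairwise(self):
        est = dup.estimate_ka_ks("GTT" + "---" + "GTT", "GTT" + "GTT" + "GTT")
        assert est.n_codons_used == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            dup.estimate_ka_ks("GTTGTT", "GTT")
        with pytest.raises(AlignmentError):
            dup.estimate_ka_ks("GTTG", "GTTG")

    def test_parameter_recovery_quick(self):
        from kinomekit import synthetic as syn

        ratios = []
        for s in range(30):
            a, b, _ = syn.evolve_codon_pair(2000, 0.2, 0.3, seed=1000 + s)
            ratios.append(dup.estimate_ka_ks(a, b).ratio)
        assert np.mean(ratios) == pytest.approx(0.2, abs=0.05)


class TestSelectionAndDating:
    @pytest.mark.parametrize("ratio,mode", [(0.3, "purifying"), (1.0, "neutral"),
                                            (1.8, "positive"), (None, "undefined"),
                                            (math.inf, "positive")])
    def test_mode_rule(self, ratio, mode):
        assert dup.classify_selection(ratio) == mode

    def test_neutral_band(self):
        assert dup.classify_selection(0.95, neutral_band=0.1) == "neutral"

    def test_printed_formula(self):
        assert dup.divergence_time(0.13, 6.5e-9) == pytest.approx(10.0)
        assert dup.divergence_time(0.0) == 0.0

    def test_lambda_scaling_and_linearity(self):
        t1 = dup.divergence_time(0.2, 6.5e-9)
        assert dup.divergence_time(0.2, 3.25e-9) == pytest.approx(2 * t1)
        assert dup.divergence_time(0.4, 6.5e-9) == pytest.approx(2 * t1)

    def test_negative_ks_rejected(self):
        with pytest.raises(InvalidParameterError):
            dup.divergence_time(-0.1)


class TestGO:
    META = {
        "GO:1": ("molecular_function", "ATP binding"),
        "GO:2": ("biological_process", "signal transduction"),
        "GO:3": ("cellular_component", "plasma membrane"),
    }

    def test_single_category_is_all(self):
        cat, term, _ = dup.summarize_go({"g1": ["GO:1"], "g2": ["GO:1"]},
                                        self.META, {"g1", "g2"})
        assert cat.iloc[0]["share_pct"] == 100.0

    def test_empty_subset(self):
        cat, term, _ = dup.summarize_go({"g1": ["GO:1"]}, self.META, set())
        assert cat.empty and term.empty

    def test_planted_split_recovered_exactly(self):
        ann = {f"c{i}": ["GO:3"] for i in range(2)}
        ann.update({f"b{i}": ["GO:2"] for i in range(9)})
        ann.update({f"m{i}": ["GO:1"] for i in range(9)})
        cat, _, _ = dup.summarize_go(ann, self.META, set(ann))
        shares = dict(zip(cat["category"], cat["share_pct"]))
        assert shares == {"cellular_component": 10.0, "biological_process": 45.0,
                          "molecular_function": 45.0}

    def test_missing_metadata_reported(self):
        _, _, missing = dup.summarize_go({"g": ["GO:999"]}, self.META, {"g"})
        assert missing == ["GO:999"]


class TestPairTables:
    def test_array_member_pairs(self):
        arr = dup.TandemArray("chr1", ["a", "b", "c"], "F", 1000)
        assert dup.array_member_pairs([arr]) == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_kaks_table_shape(self):
        from kinomekit import synthetic as syn

        a, b, _ = syn.evolve_codon_pair(200, 0.3, 0.2, seed=2)
        df = dup.kaks_table({("x", "y"): (a, b)})
        assert list(df["mode"]) and df.iloc[0]["Ks"] >= 0
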