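import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvarkit.architecture import (
    AIMSProfile,
    build_replichore_model,
    classify_leading,
    expand_aims_motifs,
    find_dnaa_boxes,
    infer_dif,
    infer_oric,
    revcomp,
    scan_aims,
    strand_bias_report,
    windowed_composition,
)
from cvarkit.io_formats import GeneFeature, Replicon

from .conftest import make_table, random_dna

dna = st.text(alphabet="ACGT", min_size=50, max_size=300)


class TestWindowedComposition:
    @pytest.mark.parametrize(
        "seq,window,step,gc_content,gc_skew",
        [
            ("ATATATAT", 8, 8, [0.0], [0.0]),          # G+C = 0 convention
            ("GGGGCCCC", 4, 4, [1.0, 1.0], [1.0, -1.0]),
            ("GGCCGCTA", 8, 8, [0.75], [0.0]),          # hand count: G=3, C=3
        ],
    )
    def test_examples(self, seq, window, step, gc_content, gc_skew):
        prof = windowed_composition(Replicon("t", seq), window, step)
        assert prof.gc_content.tolist() == gc_content
        assert prof.gc_skew.tolist() == gc_skew

    def test_invalid_window(self):
        with pytest.raises(ValueError, match="invalid window"):
            windowed_composition(Replicon("t", "ACGT"), 0, 1)

    def test_circular_windows_wrap(self):
        # window starting at 6 of an 8-mer wraps: covers seq[6:8] + seq[0:2]
        prof = windowed_composition(Replicon("t", "GGAATTCC"), 4, 2)
        wrapped = "CC" + "GG"
        assert prof.gc_content[-1] == (wrapped.count("G") + wrapped.count("C")) / 4

    def test_n_excluded_from_denominator(self):
        prof = windowed_composition(Replicon("t", "GGNNAANN"), 8, 8)
        assert prof.gc_content[0] == pytest.approx(2 / 4)

    @given(dna)
    @settings(max_examples=30, deadline=None)
    def test_reverse_complement_negates_skew(self, seq):
        rep = Replicon("t", seq)
        rc = Replicon("t", revcomp(seq))
        w = len(seq)
        f = windowed_composition(rep, w, w)
        r = windowed_composition(rc, w, w)
        assert r.gc_skew[0] == pytest.approx(-f.gc_skew[0])
        assert r.gc_content[0] == pytest.approx(f.gc_content[0])


class TestAIMSMotifs:
    def test_expansion_is_the_five_octamers(self):
        m = expand_aims_motifs()
        assert set(m.forward_octamers) == {
            "GAGGGGGA", "GTGGGGGA", "GCGGGGGA", "TGGGGGAG", "CGGGGGAG"
        }
        assert set(m.reverse_octamers) == {revcomp(o) for o in m.forward_octamers}

    def test_reverse_complement_of_first(self):
        assert revcomp("GAGGGGGA") == "TCCCCCTC"

    def test_forward_and_reverse_sets_disjoint(self):
        m = expand_aims_motifs()
        assert not set(m.forward_octamers) & set(m.reverse_octamers)


def naive_scan(seq, motifs, circular):
    ext = seq + (seq[:7] if circular else "")
    plus = sorted(i for i in range(len(seq)) for m in motifs.forward_octamers
                  if ext[i:i + 8] == m)
    minus = sorted(i for i in range(len(seq)) for m in motifs.reverse_octamers
                   if ext[i:i + 8] == m)
    return plus, minus


class TestScanAIMS:
    def test_single_exact_motif(self):
        prof = scan_aims(Replicon("t", "GAGGGGGA", circular=False))
        assert prof.plus_positions == [0] and prof.minus_positions == []

    def test_overlapping_motifs(self):
        rep = Replicon("t", "TGGGGGAGAGGGGGA" + "TTTT", circular=False)
        prof = scan_aims(rep)
        assert prof.plus_positions == [0, 7]

    def test_strand_symmetry(self):
        seq = "TGGGGGAGAGGGGGA" + "TTTT"
        fwd = scan_aims(Replicon("t", seq, circular=False))
        rev = scan_aims(Replicon("t", revcomp(seq), circular=False))
        assert len(rev.plus_positions) == len(fwd.minus_positions)
        assert len(rev.minus_positions) == len(fwd.plus_positions)

    def test_wrap_around_match(self):
        # motif split across the origin: last 3 bases + first 5
        seq = "GGGGATTTTTTTTTTTGAG"
        prof = scan_aims(Replicon("t", seq, circular=True))
        assert 16 in prof.plus_positions  # GAG|GGGGA wraps

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        motifs = expand_aims_motifs()
        for gc in (0.4, 0.67):
            seq = random_dna(rng, 5_000, gc)
            rep = Replicon("t", seq)
            prof = scan_aims(rep)
            assert (prof.plus_positions, prof.minus_positions) == naive_scan(seq, motifs, True)

    def test_cumulative_endpoint_is_count_difference(self, toy_replicon):
        prof = scan_aims(toy_replicon, sample_step=100)
        assert prof.cumulative[-1] == len(prof.plus_positions) - len(prof.minus_positions)


class TestInferOric:
    BOX = "TTGTCCACA"

    def _genome_with_boxes(self, rng, offsets, strand="+"):
        """dnaA gene at [1000, 2000); boxes planted at given offsets downstream."""
        seq = list(random_dna(rng, 5_000, 0.5))
        self._wipe_spurious(seq)
        for off in offsets:
            seq[2000 + off : 2000 + off + 9] = self.BOX
        rep = Replicon("t", "".join(seq))
        table = make_table([("dnaA", 1000, 2000, strand)])
        return rep, table

    def _wipe_spurious(self, seq):
        s = "".join(seq)
        for probe in (self.BOX, revcomp(self.BOX)):
            i = s.find(probe)
            while i != -1:
                seq[i] = "A" if seq[i] != "A" else "C"
                s = "".join(seq)
                i = s.find(probe)

    def test_cluster_midpoint(self, rng):
        offsets = [100, 220, 340, 460, 580, 700]
        rep, table = self._genome_with_boxes(rng, offsets)
        pos = infer_oric(rep, table, "dnaA", max_mismatch=0)
        expected = 2000 + (100 + 700 + 9) // 2
        assert abs(pos - expected) <= 9

    def test_fallback_when_no_boxes(self, rng, caplog):
        rep, table = self._genome_with_boxes(rng, [])
        with caplog.at_level("WARNING"):
            pos = infer_oric(rep, table, "dnaA", max_mismatch=0)
        assert pos == 2000  # dnaA downstream boundary

    def test_boxes_on_both_strands_counted(self):
        region = "A" * 20 + self.BOX + "A" * 20 + revcomp(self.BOX) + "A" * 20
        assert len(find_dnaa_boxes(region, self.BOX, 0)) == 2

    def test_one_mismatch_tolerated(self):
        near = "TAGTCCACA"
        assert find_dnaa_boxes("AAAA" + near + "AAAA", self.BOX, 1) == [4]
        assert find_dnaa_boxes("AAAA" + near + "AAAA", self.BOX, 0) == []

    def test_minus_strand_dnaa_scans_upstream_coordinates(self, rng):
        seq = list(random_dna(rng, 5_000, 0.5))
        self._wipe_spurious(seq)
        for off in (100, 300, 500, 700):  # downstream of a - strand gene = before start
            seq[1000 - off - 9 : 1000 - off] = self.BOX
        rep = Replicon("t", "".join(seq))
        table = make_table([("dnaA", 1000, 2000, "-")])
        pos = infer_oric(rep, table, "dnaA", max_mismatch=0)
        assert 200 < pos < 1000

    def test_missing_dnaa_raises(self, toy_replicon):
        with pytest.raises(ValueError, match="dnaA not found"):
            infer_oric(toy_replicon, make_table([("g1", 0, 100, "+")]))


class TestInferDif:
    def test_constructed_extremum(self):
        plus = list(range(0, 5_000, 500))
        minus = list(range(5_000, 10_000, 500))
        prof = AIMSProfile(10_000, plus, minus, 1_000)
        # both estimators: position just after the last plus hit
        assert infer_dif(prof, 0) == 4_501
        assert infer_dif(prof, 0, method="extremum") == 4_501

    def test_rotation_shifts_answer(self):
        plus = [(p + 2_000) % 10_000 for p in range(0, 5_000, 500)]
        minus = [(p + 2_000) % 10_000 for p in range(5_000, 10_000, 500)]
        prof = AIMSProfile(10_000, sorted(plus), sorted(minus), 1_000)
        assert infer_dif(prof, 2_000) == 6_501

    def test_no_signal_raises(self):
        with pytest.raises(ValueError, match="no AIMS signal"):
            infer_dif(AIMSProfile(10_000, [], [], 1_000), 0)


class TestReplichoreModel:
    def test_symmetric_split(self):
        m = build_replichore_model(1_000, 0, 500)
        assert (m.right_size, m.left_size) == (500, 500)

    def test_wrapping_right_replichore(self):
        m = build_replichore_model(1_000, 900, 400)
        assert (m.right_size, m.left_size) == (500, 500)
        assert m.in_right(950) and m.in_right(100) and not m.in_right(500)

    def test_sizes_always_sum_to_length(self):
        for oric, dif in [(0, 1), (999, 1), (123, 877)]:
            m = build_replichore_model(1_000, oric, dif)
            assert m.right_size + m.left_size == 1_000

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_replichore_model(1_000, 5, 5)


class TestStrandBias:
    @pytest.fixture
    def model(self):
        return build_replichore_model(1_000, 0, 500)

    @pytest.mark.parametrize(
        "strand,mid,expected",
        [("+", 100, "leading"), ("-", 700, "leading"),
         ("-", 100, "lagging"), ("+", 700, "lagging")],
    )
    def test_classification_rules(self, model, strand, mid, expected):
        g = GeneFeature("g", mid - 10, mid + 10, strand)
        assert classify_leading(g, model) == expected

    def test_origin_wrapping_gene_uses_circular_midpoint(self):
        model = build_replichore_model(1_000, 100, 600)
        g = GeneFeature("g", 950, 50, "+", wraps_origin=True)  # midpoint 0 -> left
        assert classify_leading(g, model) == "lagging"
        # per-base majority oracle
        bases = [(950 + i) % 1_000 for i in range(100)]
        majority_right = sum(model.in_right(b) for b in bases) > 50
        assert majority_right is False

    def test_toy_fraction(self, model):
        table = make_table([("a", 90, 110, "+"), ("b", 190, 210, "-"),
                            ("c", 690, 710, "-"), ("d", 890, 910, "+")])
        r = strand_bias_report(table, model)
        assert r.n_total == 4 and r.fraction_leading == 0.5
        assert r.n_left + r.n_right == 4

    def test_all_leading(self, model):
        table = make_table([("a", 10, 30, "+"), ("b", 100, 130, "+")])
        assert strand_bias_report(table, model).fraction_leading == 1.0

    def test_subset_selection_and_missing_tags(self, model, caplog):
        table = make_table([("a", 90, 110, "+"), ("b", 690, 710, "-")])
        with caplog.at_level("WARNING"):
            r = strand_bias_report(table, model, subset=["a", "zz"], label="ess")
        assert r.n_total == 1 and r.subset_label == "ess"

    def test_empty_selection_raises(self, model):
        table = make_table([("a", 90, 110, "+")])
        with pytest.raises(ValueError, match="no genes selected"):
            strand_bias_report(table, model, subset=["nope"])


class TestRotationEquivariance:
    """Rotating the genome by k shifts all inferred positions by exactly k."""

    def test_scan_and_dif_shift_with_rotation(self, rng):
        from cvarkit.synthetic_data import SyntheticGenomeSpec, generate_genome

        truth = generate_genome(SyntheticGenomeSpec(length=50_000, n_aims=80,
                                                    n_genes=25, seed=11))
        rep = truth.replicon
        k = 12_345
        rot = Replicon("rot", rep.seq[k:] + rep.seq[:k])
        p0 = scan_aims(rep)
        p1 = scan_aims(rot)
        L = rep.length
        assert sorted((p + k) % L for p in p1.plus_positions) == p0.plus_positions
        d0 = infer_dif(p0, truth.true_oric)
        d1 = infer_dif(p1, (truth.true_oric - k) % L)
        assert (d1 + k) % L == d0
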